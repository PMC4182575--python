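"""Range normalization, pooled Z scores, exclusions and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from hcscreen import (
    HitParams,
    ScreenDesign,
    call_gene_hits,
    call_shrna_hits,
    flag_exclusions,
    fold_change,
    pool_and_zscore,
    range_normalize,
    rank_normalized_table,
    score_screen,
    simulate_screen,
)
from hcscreen.scoring import DegenerateNullError


def _zscore_frame(null_values, test_value):
    rows = [
        ("P01", f"A{i + 1:02d}", "neg_control", "", "", v) for i, v in enumerate(null_values)
    ]
    rows.append(("P01", "B01", "test", "G1_sh1", "G1", test_value))
    df = pd.DataFrame(
        rows, columns=["plate_id", "well_id", "role", "shrna_id", "gene_id", "normalized"]
    )
    df["excluded"] = False
    return df


class TestRangeNormalize:
    def test_control_medians_map_to_zero_and_one(self, toy_plate):
        out = range_normalize(toy_plate)
        neg = out[out.role == "neg_control"]["normalized"]
        pos = out[out.role == "pos_control"]["normalized"]
        assert np.median(neg) == pytest.approx(0.0, abs=1e-12)
        assert np.median(pos) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_values_unclipped(self, toy_plate):
        out = range_normalize(toy_plate).set_index("well_id")
        assert out.loc["C01", "normalized"] == pytest.approx(0.5)
        assert out.loc["C02", "normalized"] == pytest.approx(1.5)  # beyond the range

    # range_normalize copies its input, so reusing the fixture across
    # generated examples is safe.
    @settings(
        max_examples=25,
        derandomize=True,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        a=st.floats(min_value=0.01, max_value=50),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_affine_invariance(self, toy_plate, a, b):
        base = range_normalize(toy_plate)["normalized"].to_numpy()
        shifted = toy_plate.assign(efficiency=a * toy_plate["efficiency"] + b)
        out = range_normalize(shifted)["normalized"].to_numpy()
        assert np.allclose(out, base, atol=1e-9)

    def test_failed_controls_flag_and_downstream_exclusion(self, toy_plate):
        flipped = toy_plate.copy()
        flipped.loc[flipped.role == "pos_control", "efficiency"] = 0.001
        out = range_normalize(flipped)
        assert (out["plate_qc"] == "failed_controls").all()
        assert out["normalized"].isna().all()
        excl = flag_exclusions(out)
        assert excl["excluded"].all()
        assert (excl["exclusion_reason"] == "invalid_well").all()

    def test_insufficient_controls_flag(self, toy_plate):
        short = toy_plate[toy_plate.well_id != "A01"]
        short = short[short.well_id != "A02"]  # one neg control left
        out = range_normalize(short)
        assert (out["plate_qc"] == "insufficient_controls").all()


class TestZScore:
    def test_hand_computed_z(self):
        df = _zscore_frame([-0.1, 0.0, 0.1], 0.3)
        out = pool_and_zscore(df).set_index("well_id")
        assert out.loc["B01", "z"] == pytest.approx(3.0)

    def test_value_at_null_mean_scores_zero(self):
        df = _zscore_frame([0.1, 0.2, 0.3], 0.2)
        out = pool_and_zscore(df).set_index("well_id")
        assert out.loc["B01", "z"] == pytest.approx(0.0, abs=1e-12)

    def test_null_self_standardization(self, default_screen):
        wells, _ = default_screen
        scores = score_screen(wells)
        null = scores[(scores.role == "neg_control") & ~scores.excluded]["z"]
        assert null.mean() == pytest.approx(0.0, abs=1e-10)
        assert null.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_plate_offset_removal(self, default_screen):
        """Adding a per-plate constant to every efficiency leaves pooled Z unchanged."""
        wells, _ = default_screen
        base = score_screen(wells)["z"].to_numpy()
        shifted = wells.copy()
        offsets = {p: 0.01 * (i + 1) for i, p in enumerate(shifted.plate_id.unique())}
        shifted["efficiency"] += shifted["plate_id"].map(offsets)
        out = score_screen(shifted)["z"].to_numpy()
        assert np.allclose(out, base, atol=1e-8, equal_nan=True)

    def test_degenerate_null_raises(self):
        df = _zscore_frame([0.5, 0.5, 0.5], 0.7)
        with pytest.raises(DegenerateNullError):
            pool_and_zscore(df)

    def test_too_few_null_wells_raises(self):
        df = _zscore_frame([0.0, 0.1], 0.3)
        with pytest.raises(ValueError, match="negative-control"):
            pool_and_zscore(df)

    def test_population_sd_estimator(self):
        df = _zscore_frame([-0.1, 0.0, 0.1], 0.3)
        params = HitParams(sd_estimator="population")
        out = pool_and_zscore(df, params).set_index("well_id")
        sd_pop = np.std([-0.1, 0.0, 0.1])
        assert out.loc["B01", "z"] == pytest.approx(0.3 / sd_pop)


class TestExclusions:
    def _wells(self, counts, roles=None):
        n = len(counts)
        roles = roles or ["neg_control"] * 3 + ["test"] * (n - 3)
        rows = []
        for i, (count, role) in enumerate(zip(counts, roles)):
            shrna = f"G1_sh{i}" if role == "test" else ""
            gene = "G1" if role == "test" else ""
            rows.append(("P01", f"A{i + 1:02d}", role, shrna, gene, 0.1, count))
        df = pd.DataFrame(
            rows,
            columns=["plate_id", "well_id", "role", "shrna_id", "gene_id",
                     "efficiency", "cell_count"],
        )
        df["valid"] = True
        df["normalized"] = 0.1
        df["plate_qc"] = "ok"
        return df

    def test_zero_cell_count_is_cytotoxic(self):
        out = flag_exclusions(self._wells([2000, 2000, 2000, 0]))
        row = out.set_index("well_id").loc["A04"]
        assert row["excluded"] and row["exclusion_reason"] == "cytotoxic"

    def test_boundary_is_strict(self):
        # neg-control median 2000, cutoff 1000: exactly 1000 is kept.
        out = flag_exclusions(self._wells([2000, 2000, 2000, 1000, 999]))
        out = out.set_index("well_id")
        assert not out.loc["A04", "excluded"]
        assert out.loc["A05", "excluded"]
        assert out.loc["A05", "exclusion_reason"] == "cytotoxic"

    def test_planted_cytotoxic_wells_all_flagged(self):
        """5% planted cytotoxic wells at 10% counts: all flagged, no false flags."""
        design = ScreenDesign(cytotoxic_rate=0.05)
        wells, truth = simulate_screen(design, seed=17)
        scores = score_screen(wells)
        flagged = set(
            scores.loc[scores.exclusion_reason == "cytotoxic", ["plate_id", "well_id"]]
            .itertuples(index=False, name=None)
        )
        assert flagged == set(truth.cytotoxic_wells)

    def test_expression_filter(self):
        wells = self._wells([2000, 2000, 2000, 2000])
        expr = pd.DataFrame({"gene_id": ["G1"], "expressed": [False]})
        out = flag_exclusions(wells, expression=expr).set_index("well_id")
        assert out.loc["A04", "exclusion_reason"] == "not_expressed"
        # and the excluded hairpin can never be a hit
        out = out.reset_index()
        out["z"] = 9.0
        hits = call_shrna_hits(out)
        assert not hits.set_index("well_id").loc["A04", "hit"]

    def test_missing_expression_table_skips_filter(self):
        out = flag_exclusions(self._wells([2000, 2000, 2000, 2000]), expression=None)
        assert not out[out.role == "test"]["excluded"].any()


class TestHitRules:
    @pytest.mark.parametrize(
        "z, excluded, expected",
        [(3.0, False, True), (2.999, False, False), (5.0, True, False), (10.0, False, True)],
    )
    def test_shrna_hit_boundary(self, z, excluded, expected):
        df = pd.DataFrame(
            {
                "role": ["test"],
                "shrna_id": ["G1_sh1"],
                "gene_id": ["G1"],
                "z": [z],
                "excluded": [excluded],
            }
        )
        assert call_shrna_hits(df)["hit"].iloc[0] == expected

    @pytest.mark.parametrize(
        "zs, expected_positive, expected_hits",
        [
            ([3.2, 3.0, 0.1], True, 2),
            ([5.0, 1.0, 1.0, 1.0, 1.0], False, 1),
            ([2.9, 2.9, 2.9], False, 0),
        ],
    )
    def test_gene_rule_two_or_more_hairpins(self, zs, expected_positive, expected_hits):
        df = pd.DataFrame(
            {
                "role": "test",
                "shrna_id": [f"G1_sh{i}" for i in range(len(zs))],
                "gene_id": "G1",
                "z": zs,
                "excluded": False,
            }
        )
        calls = call_gene_hits(call_shrna_hits(df)).set_index("gene_id")
        assert calls.loc["G1", "positive"] == expected_positive
        assert calls.loc["G1", "n_hits"] == expected_hits

    def test_gene_with_no_tested_hairpins(self):
        df = pd.DataFrame(
            {
                "role": ["test"],
                "shrna_id": ["G1_sh1"],
                "gene_id": ["G1"],
                "z": [5.0],
                "excluded": [False],
            }
        )
        calls = call_gene_hits(call_shrna_hits(df), genes=["G1", "G2"]).set_index("gene_id")
        assert calls.loc["G2", "n_shrnas_tested"] == 0
        assert not calls.loc["G2", "positive"]


class TestRankedTable:
    def test_orders_ascending_with_stable_ties(self):
        df = pd.DataFrame(
            {
                "shrna_id": ["b", "a", "c"],
                "role": "test",
                "normalized": [0.2, -0.1, 1.4],
                "z": [0.0, -1.0, 5.0],
                "excluded": False,
            }
        )
        ranked = rank_normalized_table(call_shrna_hits(df))
        assert list(ranked["shrna_id"]) == ["a", "b", "c"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_ties_broken_by_shrna_id(self):
        df = pd.DataFrame(
            {
                "shrna_id": ["z9", "a1", "m5"],
                "role": "test",
                "normalized": [0.3, 0.3, 0.3],
                "z": 0.0,
                "excluded": False,
                "hit": False,
            }
        )
        ranked = rank_normalized_table(df)
        assert list(ranked["shrna_id"]) == ["a1", "m5", "z9"]

    def test_hits_occupy_top_tail(self, default_screen):
        wells, _ = default_screen
        scores = score_screen(wells)
        ranked = rank_normalized_table(scores)
        test = ranked[(ranked.role == "test") & ranked.z.notna()]
        hit_flags = test["hit"].to_numpy()
        # once the ranking enters the hit region it never leaves it
        first_hit = np.argmax(hit_flags)
        assert hit_flags[first_hit:].all()


class TestFoldChange:
    @pytest.mark.parametrize(
        "ref, treated, direction, expected",
        [
            (0.20, 0.05, "reduction", 4.0),
            (0.05, 0.05, "reduction", 1.0),
            (0.04, 0.14, "increase", 3.5),
        ],
    )
    def test_arithmetic(self, ref, treated, direction, expected):
        assert fold_change(ref, treated, direction) == pytest.approx(expected)

    def test_zero_denominator_yields_inf(self):
        assert fold_change(0.2, 0.0, "reduction") == float("inf")

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.2, 0.1, "sideways")
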