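"""Imageless simulation of arrayed shRNA screens with planted effects.

Produces per-well infection efficiencies directly (no images), at the plate
structure of a 96-well arrayed screen with in-plate negative and positive
controls, for power/false-positive studies and end-to-end pipeline tests.

Model per well:

    efficiency = clamp_[0,1]( baseline * effect * plate_offset + noise )

where ``effect`` is 1 for negative controls and unperturbed hairpins, the
positive-control fold (default 3.5, the knockdown of an IFN-gamma receptor
component) for positive controls, and the planted per-hairpin fold for
effective hairpins of planted positive-regulator genes; ``plate_offset`` is
a per-plate lognormal multiplier and ``noise`` additive Gaussian well noise.
Cytotoxic wells are planted as independent Bernoulli events whose cell
counts drop to a small fraction of normal.

Defaults mirror the screen this package models: 161 genes, 827 hairpins
(about five per gene), baseline infection efficiency 7.5% under IFN-gamma
priming (the 5-10% band), 3.5-fold positive-control effect and 14 planted
positive-regulator genes at a 3-fold effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scoring import HitParams, call_gene_hits, score_screen

__all__ = [
    "ScreenDesign",
    "ScreenTruth",
    "RecoveryResult",
    "simulate_screen",
    "evaluate_recovery",
    "power_curve",
]


@dataclass(frozen=True)
class ScreenDesign:
    """Layout and generative parameters of a simulated arrayed screen."""

    n_genes: int = 161
    n_shrnas_total: int = 827
    wells_per_plate: int = 96
    plate_rows: int = 8
    neg_controls_per_plate: int = 8
    pos_controls_per_plate: int = 8
    baseline_efficiency: float = 0.075
    pos_control_effect: float = 3.5
    plate_offset_sd: float = 0.1
    well_noise_sd: float = 0.01
    cells_per_well_mean: float = 2000.0
    cells_per_well_sd: float = 100.0
    cytotoxic_rate: float = 0.02
    cytotoxic_count_fraction: float = 0.1
    n_positive_genes: int = 14
    effective_shrnas_per_positive: int = 3
    planted_effect: float = 3.0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_shrnas_total < self.n_genes:
            raise ValueError("need >= 1 gene and >= 1 hairpin per gene")
        if self.neg_controls_per_plate < 1 or self.pos_controls_per_plate < 1:
            raise ValueError("controls required on every plate")
        n_ctrl = self.neg_controls_per_plate + self.pos_controls_per_plate
        if n_ctrl >= self.wells_per_plate:
            raise ValueError("controls occupy the whole plate")
        if not 0 < self.baseline_efficiency < 1:
            raise ValueError("baseline_efficiency must be in (0, 1)")
        for name in ("plate_offset_sd", "well_noise_sd", "cytotoxic_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_positive_genes > self.n_genes:
            raise ValueError("more planted genes than genes")

    @property
    def test_wells_per_plate(self) -> int:
        return (
            self.wells_per_plate
            - self.neg_controls_per_plate
            - self.pos_controls_per_plate
        )

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_shrnas_total / self.test_wells_per_plate)

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def shrna_map(self) -> pd.DataFrame:
        """Library table (shrna_id, gene_id); hairpins spread evenly over genes."""
        base = self.n_shrnas_total // self.n_genes
        extra = self.n_shrnas_total % self.n_genes
        rows = []
        for g_idx, gene in enumerate(self.gene_ids()):
            n = base + (1 if g_idx < extra else 0)
            for k in range(n):
                rows.append({"shrna_id": f"{gene}_sh{k + 1}", "gene_id": gene})
        return pd.DataFrame(rows, columns=["shrna_id", "gene_id"])


@dataclass(frozen=True)
class ScreenTruth:
    """Planted ground truth of a simulated screen."""

    shrna_effects: pd.DataFrame  # shrna_id, gene_id, effect (fold over baseline)
    positive_genes: frozenset[str]
    cytotoxic_wells: frozenset[tuple[str, str]]  # (plate_id, well_id)

    def gene_status(self) -> pd.DataFrame:
        genes = sorted(self.shrna_effects["gene_id"].unique())
        return pd.DataFrame(
            {"gene_id": genes, "positive": [g in self.positive_genes for g in genes]}
        )


def _well_id(index: int, plate_rows: int) -> str:
    row = index % plate_rows
    col = index // plate_rows
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def simulate_screen(
    design: ScreenDesign = ScreenDesign(), seed: int = 0
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate one screen; returns (well table, ground truth).

    The well table has the schema consumed by :mod:`hcscreen.scoring`.
    Layout per plate: negative controls fill column 1, positive controls
    column 12, test hairpins the columns between, in library order.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    lib = design.shrna_map()

    # Planted truth: first n_positive_genes genes are positive regulators,
    # with the first `effective_shrnas_per_positive` hairpins effective.
    positive = frozenset(design.gene_ids()[: design.n_positive_genes])
    effects = np.ones(len(lib))
    for gene in positive:
        idx = lib.index[lib["gene_id"] == gene][: design.effective_shrnas_per_positive]
        effects[idx] = design.planted_effect
    lib = lib.assign(effect=effects)

    rows = []
    cytotoxic: set[tuple[str, str]] = set()
    shrna_iter = iter(lib.itertuples(index=False))
    exhausted = False
    for p in range(design.n_plates):
        plate_id = f"P{p + 1:02d}"
        offset = (
            float(rng.lognormal(mean=0.0, sigma=design.plate_offset_sd))
            if design.plate_offset_sd > 0
            else 1.0
        )
        # Column-major fill: negative controls occupy the leftmost wells,
        # positive controls the rightmost (columns 1 and 12 at the default
        # eight controls on an 8-row plate), test hairpins in between.
        for w in range(design.wells_per_plate):
            well_id = _well_id(w, design.plate_rows)
            if w < design.neg_controls_per_plate:
                role, shrna_id, gene_id, effect = "neg_control", "", "", 1.0
            elif w >= design.wells_per_plate - design.pos_controls_per_plate:
                role, shrna_id, gene_id, effect = (
                    "pos_control",
                    "",
                    "",
                    design.pos_control_effect,
                )
            else:
                try:
                    rec = next(shrna_iter)
                except StopIteration:
                    exhausted = True
                    continue
                role, shrna_id, gene_id, effect = "test", rec.shrna_id, rec.gene_id, rec.effect

            noise = rng.normal(0.0, design.well_noise_sd) if design.well_noise_sd > 0 else 0.0
            eff = float(np.clip(design.baseline_efficiency * effect * offset + noise, 0.0, 1.0))
            count = max(
                0.0, rng.normal(design.cells_per_well_mean, design.cells_per_well_sd)
            )
            is_toxic = role == "test" and rng.random() < design.cytotoxic_rate
            if is_toxic:
                count *= design.cytotoxic_count_fraction
                cytotoxic.add((plate_id, well_id))
            rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": well_id,
                    "role": role,
                    "shrna_id": shrna_id,
                    "gene_id": gene_id,
                    "efficiency": eff,
                    "cell_count": int(round(count)),
                }
            )
        if exhausted and p == design.n_plates - 1:
            break

    wells = pd.DataFrame(rows)
    truth = ScreenTruth(
        shrna_effects=lib,
        positive_genes=positive,
        cytotoxic_wells=frozenset(cytotoxic),
    )
    n_test = int((wells["role"] == "test").sum())
    if n_test != design.n_shrnas_total:
        raise RuntimeError(
            f"layout bug: {n_test} test wells for {design.n_shrnas_total} hairpins"
        )
    return wells, truth


def null_calibration_design(min_test_wells: int = 10000) -> ScreenDesign:
    """Null-only design for checking the hit rule's false-positive rate.

    Uses 384-well plates with 96 controls of each type so the plug-in error
    of the per-plate control medians is negligible and the pooled normalized
    null is effectively Gaussian; with sparse controls (e.g. eight per
    plate) the same medians shift each plate's null by a noticeable fraction
    of its sd and the pooled tail runs heavier than the normal tail.  Plate
    offsets and cytotoxicity are off; no genes are planted.
    """
    n_plates = math.ceil(min_test_wells / 192)
    n_total = n_plates * 192
    return ScreenDesign(
        n_genes=n_total // 5,
        n_shrnas_total=n_total,
        wells_per_plate=384,
        plate_rows=16,
        neg_controls_per_plate=96,
        pos_controls_per_plate=96,
        n_positive_genes=0,
        plate_offset_sd=0.0,
        cytotoxic_rate=0.0,
    )


@dataclass(frozen=True)
class RecoveryResult:
    sensitivity: float
    specificity: float
    confusion: pd.DataFrame  # gene_id, true_positive (bool), called_positive (bool)


def evaluate_recovery(
    gene_calls: pd.DataFrame, truth: ScreenTruth
) -> RecoveryResult:
    """Sensitivity/specificity of gene-level calls against planted truth."""
    status = truth.gene_status()
    merged = status.merge(
        gene_calls[["gene_id", "positive"]].rename(columns={"positive": "called_positive"}),
        on="gene_id",
        how="outer",
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        only = merged.loc[merged["_merge"] != "both", "gene_id"].tolist()
        raise ValueError(f"gene sets differ between calls and truth: {only[:5]}...")
    merged = merged.drop(columns="_merge").rename(columns={"positive": "true_positive"})
    tp = int((merged["true_positive"] & merged["called_positive"]).sum())
    fn = int((merged["true_positive"] & ~merged["called_positive"]).sum())
    tn = int((~merged["true_positive"] & ~merged["called_positive"]).sum())
    fp = int((~merged["true_positive"] & merged["called_positive"]).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return RecoveryResult(sensitivity=sens, specificity=spec, confusion=merged)


def power_curve(
    design: ScreenDesign = ScreenDesign(),
    effects: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0),
    n_replicates: int = 20,
    seed: int = 0,
    params: HitParams = HitParams(),
) -> pd.DataFrame:
    """Gene-level sensitivity and shRNA-level FPR across planted effect sizes.

    For each effect the design is re-run ``n_replicates`` times with fresh
    seeds; FPR counts hits among hairpins whose true effect is 1.
    """
    if not effects:
        raise ValueError("effect grid must be non-empty")
    ss = np.random.SeedSequence(seed)
    rows = []
    for e_idx, effect in enumerate(effects):
        d = replace(design, planted_effect=float(effect))
        sens_acc, fp, n_null = [], 0, 0
        for r in range(n_replicates):
            rep_seed = np.random.SeedSequence([int(seed), e_idx, r])
            wells, truth = simulate_screen(d, seed=rep_seed)
            scores = score_screen(wells, params=params)
            calls = call_gene_hits(scores, params=params)
            rec = evaluate_recovery(calls, truth)
            sens_acc.append(rec.sensitivity)
            null_ids = set(
                truth.shrna_effects.loc[truth.shrna_effects["effect"] == 1.0, "shrna_id"]
            )
            test = scores[scores["role"] == "test"]
            null_rows = test[test["shrna_id"].isin(null_ids) & ~test["excluded"]]
            fp += int(null_rows["hit"].sum())
            n_null += len(null_rows)
        rows.append(
            {
                "effect": float(effect),
                "sensitivity": float(np.mean(sens_acc)),
                "shrna_fpr": fp / n_null if n_null else float("nan"),
                "n_null": n_null,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
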