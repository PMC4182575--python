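"""Plate normalization, pooled Z scores and hit calling for arrayed screens.

The statistical core of the screen: per-plate range normalization maps the
median of the irrelevant (negative-control) shRNA wells to 0 and the median
of the positive-control wells to 1, without clipping; all plates' normalized
values are then pooled and converted to Z scores against the distribution of
the pooled normalized negative-control wells.  An shRNA is a hit when its
Z score is greater than or equal to the threshold (default 3, inclusive) and
it is not excluded; a gene is called a positive regulator when at least
``min_hits`` (default 2) distinct hairpins targeting it are hits.

Exclusions: wells whose cell count indicates cytotoxicity (below a fraction
of the plate's negative-control median count), genes annotated as not
expressed in the assayed cell line, and wells without a valid efficiency.

Well tables are pandas DataFrames with columns
``plate_id, well_id, role, shrna_id, gene_id, efficiency, cell_count``
(optional ``valid``); role is one of ``neg_control, pos_control, test``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROLES",
    "EXCLUSION_REASONS",
    "HitParams",
    "DegenerateNullError",
    "validate_wells",
    "range_normalize",
    "flag_exclusions",
    "pool_and_zscore",
    "call_shrna_hits",
    "call_gene_hits",
    "rank_normalized_table",
    "fold_change",
    "score_screen",
]

ROLES = ("neg_control", "pos_control", "test")
EXCLUSION_REASONS = ("none", "cytotoxic", "not_expressed", "invalid_well")

WELL_COLUMNS = [
    "plate_id",
    "well_id",
    "role",
    "shrna_id",
    "gene_id",
    "efficiency",
    "cell_count",
]


class DegenerateNullError(ValueError):
    """The pooled negative-control distribution has zero spread."""


@dataclass(frozen=True)
class HitParams:
    """Thresholds and estimator choices for hit calling.

    z_threshold:
        Inclusive Z cutoff for an shRNA hit (default 3).
    min_hits:
        Distinct hit hairpins needed to call a gene positive (default 2).
    sd_estimator:
        "sample" (n-1 denominator, default) or "population" for the null sd.
    cytotoxicity_fraction:
        A well is cytotoxic when its cell count is strictly below this
        fraction of the plate's negative-control median count (default 0.5).
    """

    z_threshold: float = 3.0
    min_hits: int = 2
    sd_estimator: str = "sample"
    cytotoxicity_fraction: float = 0.5

    def validate(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")
        if self.sd_estimator not in ("sample", "population"):
            raise ValueError(f"unknown sd_estimator {self.sd_estimator!r}")
        if not 0 < self.cytotoxicity_fraction < 1:
            raise ValueError("cytotoxicity_fraction must be in (0, 1)")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_estimator == "sample" else 0


def validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Check the well-table schema and return a working copy.

    Adds a ``valid`` column (efficiency present and finite) if missing.
    """
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    bad_roles = set(wells["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
    out = wells.copy()
    if "valid" not in out.columns:
        out["valid"] = np.isfinite(out["efficiency"].astype(float))
    return out


def range_normalize(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-plate range normalization of infection efficiencies.

    normalized = (efficiency - median_neg) / (median_pos - median_neg),
    computed plate by plate, so the negative-control median maps exactly to
    0 and the positive-control median exactly to 1.  Values are not clipped.

    Plates with fewer than two valid controls of either role, or whose
    positive-control median does not exceed the negative-control median,
    get ``plate_qc`` "insufficient_controls" / "failed_controls" and NaN
    normalized values; such wells are excluded downstream.
    """
    wells = validate_wells(wells)
    wells["normalized"] = np.nan
    wells["plate_qc"] = "ok"
    for plate_id, idx in wells.groupby("plate_id").groups.items():
        sub = wells.loc[idx]
        neg = sub[(sub["role"] == "neg_control") & sub["valid"]]["efficiency"]
        pos = sub[(sub["role"] == "pos_control") & sub["valid"]]["efficiency"]
        if len(neg) < 2 or len(pos) < 2:
            wells.loc[idx, "plate_qc"] = "insufficient_controls"
            logger.warning("plate %s: insufficient controls (%d neg, %d pos)",
                           plate_id, len(neg), len(pos))
            continue
        med_neg, med_pos = float(neg.median()), float(pos.median())
        if med_pos <= med_neg:
            wells.loc[idx, "plate_qc"] = "failed_controls"
            logger.warning("plate %s: failed controls (neg median %.4g >= pos median %.4g)",
                           plate_id, med_neg, med_pos)
            continue
        wells.loc[idx, "normalized"] = (
            sub["efficiency"].astype(float) - med_neg
        ) / (med_pos - med_neg)
    wells.loc[~wells["valid"], "normalized"] = np.nan
    return wells


def flag_exclusions(
    wells: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    params: HitParams = HitParams(),
) -> pd.DataFrame:
    """Mark wells excluded for invalidity, cytotoxicity or lack of expression.

    Reason precedence: invalid_well (invalid efficiency or failed plate) >
    cytotoxic (cell count strictly below cytotoxicity_fraction x plate
    negative-control median count) > not_expressed (gene marked False in the
    ``expression`` table with columns gene_id, expressed).  Without an
    expression table the expression filter is skipped with a logged notice.
    """
    params.validate()
    wells = wells.copy()
    wells["excluded"] = False
    wells["exclusion_reason"] = "none"

    plate_ok = wells.get("plate_qc", pd.Series("ok", index=wells.index)) == "ok"
    invalid = ~wells["valid"].astype(bool) | ~plate_ok
    wells.loc[invalid, ["excluded", "exclusion_reason"]] = [True, "invalid_well"]

    for plate_id, idx in wells.groupby("plate_id").groups.items():
        sub = wells.loc[idx]
        neg_counts = sub[(sub["role"] == "neg_control") & sub["valid"]]["cell_count"]
        if neg_counts.empty:
            continue
        cutoff = params.cytotoxicity_fraction * float(neg_counts.median())
        toxic = (sub["cell_count"].astype(float) < cutoff) & ~sub["excluded"]
        wells.loc[toxic[toxic].index, ["excluded", "exclusion_reason"]] = [
            True,
            "cytotoxic",
        ]

    if expression is not None:
        expressed = dict(zip(expression["gene_id"], expression["expressed"]))
        not_expr = (
            (wells["role"] == "test")
            & ~wells["excluded"]
            & wells["gene_id"].map(lambda g: not bool(expressed.get(g, True)))
        )
        wells.loc[not_expr, ["excluded", "exclusion_reason"]] = [
            True,
            "not_expressed",
        ]
    else:
        logger.info("no expression table provided; expression filter skipped")
    return wells


def pool_and_zscore(
    wells: pd.DataFrame, params: HitParams = HitParams()
) -> pd.DataFrame:
    """Z-score pooled normalized values against the negative-control null.

    The null set is every non-excluded valid negative-control well pooled
    across plates; z = (normalized - null mean) / null sd with the sd
    estimator from ``params``.  Excluded wells keep z = NaN.
    """
    params.validate()
    wells = wells.copy()
    if "excluded" not in wells.columns:
        wells["excluded"] = False
    usable = ~wells["excluded"] & np.isfinite(wells["normalized"].astype(float))
    null = wells.loc[usable & (wells["role"] == "neg_control"), "normalized"].astype(float)
    if len(null) < 3:
        raise ValueError(
            f"need >= 3 pooled valid negative-control wells, got {len(null)}"
        )
    mean_null = float(null.mean())
    sd_null = float(null.std(ddof=params.ddof))
    if sd_null == 0:
        raise DegenerateNullError("negative-control normalized values have zero sd")
    wells["z"] = np.nan
    wells.loc[usable, "z"] = (
        wells.loc[usable, "normalized"].astype(float) - mean_null
    ) / sd_null
    return wells


def call_shrna_hits(
    scores: pd.DataFrame, params: HitParams = HitParams()
) -> pd.DataFrame:
    """Flag hits: z >= z_threshold (inclusive) and not excluded."""
    params.validate()
    scores = scores.copy()
    z = scores["z"].astype(float)
    scores["hit"] = (~scores["excluded"]) & np.isfinite(z) & (z >= params.z_threshold)
    return scores


def call_gene_hits(
    scores: pd.DataFrame,
    params: HitParams = HitParams(),
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene-level calls: positive iff >= min_hits distinct hit hairpins.

    Only test wells count; returns columns gene_id, n_shrnas_tested,
    n_hits, positive.  ``genes`` optionally names the full gene universe;
    genes without tested hairpins then appear with n_shrnas_tested = 0 and
    positive = False.
    """
    params.validate()
    test = scores[scores["role"] == "test"]
    rows = []
    if genes is not None:
        for gene_id in set(genes) - set(test["gene_id"]):
            rows.append(
                {
                    "gene_id": gene_id,
                    "n_shrnas_tested": 0,
                    "n_hits": 0,
                    "positive": False,
                }
            )
    for gene_id, sub in test.groupby("gene_id"):
        n_hits = int(sub.loc[sub["hit"].astype(bool), "shrna_id"].nunique())
        rows.append(
            {
                "gene_id": gene_id,
                "n_shrnas_tested": int(sub["shrna_id"].nunique()),
                "n_hits": n_hits,
                "positive": n_hits >= params.min_hits,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_shrnas_tested", "n_hits", "positive"]
    ).sort_values("gene_id", ignore_index=True)


def rank_normalized_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank wells by normalized value, ascending (the ranked-bar view).

    Stable sort; ties broken by shrna_id lexicographic order.  Adds a
    1-based ``rank`` column.
    """
    cols = ["rank", "shrna_id", "role", "normalized", "z", "hit"]
    out = scores.copy()
    out["_tie"] = out["shrna_id"].astype(str)
    out = out.sort_values(["normalized", "_tie"], kind="stable").drop(columns="_tie")
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out[[c for c in cols if c in out.columns]].reset_index(drop=True)


def fold_change(
    reference_eff: float, treated_eff: float, direction: str = "reduction"
) -> float:
    """Fold change between two infection efficiencies.

    direction "reduction" returns reference/treated (a 4x drop reads 4.0);
    "increase" returns treated/reference.  A zero denominator yields +inf.
    """
    if direction not in ("reduction", "increase"):
        raise ValueError(f"direction must be 'reduction' or 'increase', got {direction!r}")
    if reference_eff < 0 or treated_eff < 0:
        raise ValueError("efficiencies must be non-negative")
    num, den = (
        (reference_eff, treated_eff)
        if direction == "reduction"
        else (treated_eff, reference_eff)
    )
    if den == 0:
        logger.warning("fold_change: zero denominator, returning inf")
        return float("inf")
    return num / den


def score_screen(
    wells: pd.DataFrame,
    params: HitParams = HitParams(),
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full scoring pass: normalize, exclude, Z-score, call hits."""
    wells = range_normalize(wells)
    wells = flag_exclusions(wells, expression=expression, params=params)
    wells = pool_and_zscore(wells, params=params)
    return call_shrna_hits(wells, params=params)
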