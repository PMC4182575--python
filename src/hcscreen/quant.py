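"""Follow-up assay quantification: qPCR relative expression, knockdown-phenotype
correlation, and viability-normalized reporter activity.

Relative expression uses the 2^-ddCt convention with a fixed amplification
efficiency of 2 (perfect doubling per cycle): dCt = Ct_target - Ct_reference
within a sample, ddCt = dCt_sample - dCt_calibrator, relative = 2^-ddCt, so
the calibrator sample is 1 by construction.  Knockdown fraction is
1 - relative expression.  The knockdown-phenotype dose-response uses
Spearman rank correlation, since the claim being checked is ordering, not
linearity.  Reporter activity divides luminescence by viability and rescales
so the untreated reference is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "QpcrMeasure",
    "ExpressionResult",
    "relative_expression",
    "relative_expression_table",
    "knockdown_phenotype_correlation",
    "reporter_activity",
]


@dataclass(frozen=True)
class QpcrMeasure:
    """One sample's target and reference-gene Ct values.

    The reference gene is the internal normalization control (Gapdh in the
    assays this models).  Ct values outside ``ct_range`` are rejected.
    """

    sample_id: str
    ct_target: float
    ct_reference: float
    condition: str = ""
    calibrator: bool = False
    ct_range: tuple[float, float] = (5.0, 40.0)

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"{name} missing or non-finite for sample {self.sample_id!r}")
            lo, hi = self.ct_range
            if not lo <= v <= hi:
                raise ValueError(
                    f"{name}={v} outside validated range [{lo}, {hi}] "
                    f"for sample {self.sample_id!r}"
                )

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class ExpressionResult:
    """2^-ddCt outcome: relative expression (calibrator = 1) and knockdown."""

    relative_expression: float
    knockdown_fraction: float


def relative_expression(
    sample: QpcrMeasure, calibrator: QpcrMeasure
) -> ExpressionResult:
    """Relative expression of `sample` vs `calibrator` by 2^-ddCt."""
    ddct = sample.delta_ct - calibrator.delta_ct
    rel = float(2.0 ** (-ddct))
    return ExpressionResult(relative_expression=rel, knockdown_fraction=1.0 - rel)


def relative_expression_table(
    measures: pd.DataFrame,
    reference_gene: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """2^-ddCt per (condition, gene) from a long Ct table.

    ``measures`` columns: sample_id, condition, gene, ct.  Technical
    replicates (rows sharing condition and gene) are averaged on the Ct
    scale before ddCt.  Returns condition, gene, relative_expression,
    knockdown_fraction; reference-gene rows are consumed, not reported.
    """
    required = {"sample_id", "condition", "gene", "ct"}
    missing = required - set(measures.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    mean_ct = (
        measures.groupby(["condition", "gene"])["ct"].mean().rename("ct").reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("condition")["ct"]
    if calibrator_condition not in set(mean_ct["condition"]):
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent")
    rows = []
    targets = mean_ct[mean_ct["gene"] != reference_gene]
    for gene, sub in targets.groupby("gene"):
        sub = sub.set_index("condition")["ct"]
        if calibrator_condition not in sub.index:
            raise ValueError(f"gene {gene!r} has no calibrator measurement")
        cal_dct = sub[calibrator_condition] - ref[calibrator_condition]
        for condition, ct in sub.items():
            if condition not in ref.index:
                raise ValueError(
                    f"no {reference_gene!r} measurement for condition {condition!r}"
                )
            ddct = (ct - ref[condition]) - cal_dct
            rel = float(2.0 ** (-ddct))
            rows.append(
                {
                    "condition": condition,
                    "gene": gene,
                    "relative_expression": rel,
                    "knockdown_fraction": 1.0 - rel,
                }
            )
    return pd.DataFrame(
        rows, columns=["condition", "gene", "relative_expression", "knockdown_fraction"]
    )


def knockdown_phenotype_correlation(
    pairs: list[tuple[float, float]] | np.ndarray,
    monotone_cutoff: float = 0.8,
) -> tuple[float, bool]:
    """Spearman correlation between knockdown depth and infection efficiency.

    A strong positive rank correlation across a gene's hairpins indicates a
    gene-dosage effect: deeper knockdown, more infection.  Returns
    (coefficient, monotone flag with flag = coefficient >= cutoff).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (knockdown, efficiency) pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("correlation undefined for constant input")
    rho = float(spearmanr(arr[:, 0], arr[:, 1]).statistic)
    return rho, rho >= monotone_cutoff


def reporter_activity(
    luminescence: float,
    viability: float,
    reference_luminescence: float,
    reference_viability: float,
) -> float:
    """Viability-normalized reporter activity, untreated reference = 1.

    (lum/viability) / (lum_ref/viability_ref); viabilities must be > 0.
    """
    for name, v in (
        ("viability", viability),
        ("reference_viability", reference_viability),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v!r}")
    if reference_luminescence <= 0:
        raise ValueError("reference_luminescence must be > 0")
    return (luminescence / viability) / (reference_luminescence / reference_viability)
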