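"""ΔΔCT quantification of ChIP enrichment and relative gene expression.

ChIP fold enrichment at a locus is computed relative to the IgG
non-specific-binding background and normalized for genomic DNA input:

    fold = E^-[(CT_ab - CT_input_ab) - (CT_igg - CT_input_igg)]

with amplification efficiency E = 2 by default, so the IgG background
maps to exactly 1.  Relative expression is per-sample 2^-ΔCT against a
housekeeping gene (ΔCT = CT_target - CT_housekeeping), anchored so the
control-group mean equals 1.  Group comparisons use a two-sample t test
with Bonferroni correction over the family of targets tested together;
the test runs on log2-transformed relative quantities by default because
fold changes are closer to log-normal than normal.

Technical replicates (qPCR is typically run in duplicate) are averaged
on the CT scale before any ΔΔCT arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "EnrichmentResult",
    "ExpressionResult",
    "average_replicates",
    "chip_enrichment",
    "relative_expression",
    "group_test",
    "read_ct_table",
]

ASSAYS = ("chip_ab", "chip_igg", "chip_input", "expression")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: sample, target, assay role, replicate CT."""

    sample_id: str
    target: str
    assay: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"CT must be positive, got {self.ct}")
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Input-normalized antibody enrichment over IgG (IgG == 1)."""

    sample_id: str
    locus: str
    fold_enrichment: float

    @property
    def log10_fold(self) -> float:
        return math.log10(self.fold_enrichment)


@dataclass(frozen=True)
class ExpressionResult:
    """Housekeeping-normalized expression, control-group mean anchored to 1."""

    sample_id: str
    gene: str
    rel_expr: float

    @property
    def log10_rel(self) -> float:
        return math.log10(self.rel_expr)


def read_ct_table(path: str) -> pd.DataFrame:
    """Read a tab-delimited CT table (sample, target, assay, replicate, ct)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "assay", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing column(s): {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return df


def average_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical-replicate CTs per (sample, target, assay)."""
    return (
        df.groupby(["sample", "target", "assay"], sort=False, as_index=False)["ct"].mean()
    )


def chip_enrichment(
    ab_ct: float,
    igg_ct: float,
    input_ct_ab: float,
    input_ct_igg: float,
    efficiency: float = 2.0,
    *,
    sample_id: str = "",
    locus: str = "",
) -> EnrichmentResult:
    """Input-normalized fold enrichment of the antibody pull-down over IgG.

    ``fold = efficiency^-[(ab_ct - input_ct_ab) - (igg_ct - input_ct_igg)]``.
    Equal ΔCTs give fold 1; each cycle the antibody ΔCT sits below the IgG
    ΔCT doubles the fold (at efficiency 2).  Adding a constant to all four
    CTs leaves the fold unchanged.
    """
    for name, v in (
        ("ab_ct", ab_ct), ("igg_ct", igg_ct),
        ("input_ct_ab", input_ct_ab), ("input_ct_igg", input_ct_igg),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if efficiency <= 1:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    ddct = (ab_ct - input_ct_ab) - (igg_ct - input_ct_igg)
    return EnrichmentResult(
        sample_id=sample_id, locus=locus, fold_enrichment=float(efficiency ** -ddct)
    )


def relative_expression(
    target_ct: Mapping[str, float],
    housekeeping_ct: Mapping[str, float],
    control_samples: Sequence[str],
    efficiency: float = 2.0,
    *,
    gene: str = "",
) -> list[ExpressionResult]:
    """Per-sample E^-ΔCT vs housekeeping, anchored to the control-group mean.

    ΔCT = target CT - housekeeping CT per sample; the resulting relative
    quantities are divided by the arithmetic mean over ``control_samples``
    so the control-group mean is exactly 1.
    """
    if not control_samples:
        raise ValueError("control group must not be empty")
    missing = [s for s in target_ct if s not in housekeeping_ct]
    if missing:
        raise ValueError(f"samples missing housekeeping CT: {missing}")
    missing_ctrl = [s for s in control_samples if s not in target_ct]
    if missing_ctrl:
        raise ValueError(f"control samples missing target CT: {missing_ctrl}")
    rq = {
        s: efficiency ** -(target_ct[s] - housekeeping_ct[s]) for s in target_ct
    }
    anchor = float(np.mean([rq[s] for s in control_samples]))
    return [
        ExpressionResult(sample_id=s, gene=gene, rel_expr=rq[s] / anchor) for s in rq
    ]


def group_test(
    values_control: Sequence[float],
    values_case: Sequence[float],
    n_tests: int,
    *,
    log_scale: bool = True,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Two-sample t test with Bonferroni correction over ``n_tests`` targets.

    Returns ``(p_raw, p_bonferroni, significant)`` with
    ``p_bonferroni = min(1, p_raw * n_tests)`` and significance at
    Bonferroni-adjusted P < ``alpha``.  By default values are
    log2-transformed first (they must then be positive); identical groups
    give P = 1.
    """
    if len(values_control) < 2 or len(values_case) < 2:
        raise ValueError("each group needs at least two values")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if log_scale:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log-scale test requires positive values")
        a, b = np.log2(a), np.log2(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        p_raw = 1.0
    else:
        p_raw = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if math.isnan(p_raw):
            p_raw = 1.0
    p_bonf = min(1.0, p_raw * n_tests)
    return p_raw, p_bonf, p_bonf < alpha
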