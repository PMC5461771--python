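"""450k-style methylation array QC and per-CpG differential calling.

The module takes a normalized beta-value matrix (probes x samples) with
per-entry detection P values and bead counts.  QC masks unreliable
entries (detection P > 0.01 or bead count < 3), removes probes with
ambiguous genomic mapping, and drops probes missing in more than 95% of
samples.  Each surviving probe is then tested independently for a group
difference (Welch t test on beta values by default), P values are
adjusted by Benjamini-Hochberg across all testable probes, and a CpG is
flagged differential when FDR < 0.05 and the absolute group beta
difference exceeds 0.05 (5% methylation).

Normalization is upstream of this module; it expects normalized betas.
Grouping differential CpGs into array DMRs is not performed here — only
a convenience re-use of the RRBS interval merger is offered, which is a
different procedure from dedicated array DMR callers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .params import PipelineParams

__all__ = ["ProbeMatrix", "qc_filter_probes", "differential_cpgs", "merge_flagged_cpgs"]


@dataclass
class ProbeMatrix:
    """Beta-value matrix with detection P values, bead counts, and groups.

    ``betas``, ``det_p`` and ``beads`` are probes x samples DataFrames
    sharing index and columns; ``groups`` maps sample id to ``'carrier'``
    or ``'control'``; ``probes`` optionally annotates probe id with
    chrom, 1-based pos and a class label (island/shore/other).
    """

    betas: pd.DataFrame
    det_p: pd.DataFrame
    beads: pd.DataFrame
    groups: pd.Series
    probes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, df in (("det_p", self.det_p), ("beads", self.beads)):
            if df.shape != self.betas.shape:
                raise ValueError(f"{name} shape {df.shape} != betas shape {self.betas.shape}")
            if not df.index.equals(self.betas.index) or not df.columns.equals(self.betas.columns):
                raise ValueError(f"{name} index/columns do not match betas")
        b = self.betas.to_numpy(dtype=float)
        if b.size and not np.all(np.isnan(b) | ((b >= 0) & (b <= 1))):
            raise ValueError("beta values must lie in [0, 1] or be missing")
        p = self.det_p.to_numpy(dtype=float)
        if p.size and not np.all(np.isnan(p) | ((p >= 0) & (p <= 1))):
            raise ValueError("detection P values must lie in [0, 1]")
        if (self.beads.to_numpy(dtype=float) < 0).any():
            raise ValueError("bead counts must be non-negative")
        missing = set(self.betas.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        bad = set(self.groups.loc[list(self.betas.columns)]) - {"carrier", "control"}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.betas.columns if self.groups[s] == group]


def qc_filter_probes(
    matrix: ProbeMatrix,
    det_p_max: float = 0.01,
    min_beads: int = 3,
    max_missing_frac: float = 0.95,
    ambiguous: Iterable[str] = (),
) -> tuple[ProbeMatrix, dict]:
    """Mask unreliable entries and drop failing probes; report counts.

    Entries with detection P > ``det_p_max`` or bead count < ``min_beads``
    are set missing (boundary: det P exactly 0.01 and 3 beads are kept).
    Probes in ``ambiguous`` are removed entirely.  Probes missing in
    strictly more than ``max_missing_frac`` of samples — evaluated *after*
    masking, which creates the missingness it measures — are removed.
    Surviving beta values are never altered (pure masking/removal).
    """
    betas = matrix.betas.copy()
    detp_arr = matrix.det_p.to_numpy(dtype=float)
    beads_arr = matrix.beads.to_numpy(dtype=float)
    mask_detp = detp_arr > det_p_max
    mask_beads = beads_arr < min_beads
    already_missing = betas.isna().to_numpy()
    n_masked_detp = int((mask_detp & ~already_missing).sum())
    n_masked_beads = int((mask_beads & ~mask_detp & ~already_missing).sum())
    betas = betas.mask(mask_detp | mask_beads)

    ambiguous = set(ambiguous)
    amb_idx = betas.index.isin(ambiguous)
    n_ambiguous = int(amb_idx.sum())
    betas = betas.loc[~amb_idx]

    missing_frac = betas.isna().mean(axis=1)
    low_success = missing_frac > max_missing_frac
    n_low_success = int(low_success.sum())
    betas = betas.loc[~low_success]

    keep = betas.index
    report = {
        "n_probes_in": matrix.n_probes,
        "n_entries_masked_detection_p": n_masked_detp,
        "n_entries_masked_beads": n_masked_beads,
        "n_probes_removed_ambiguous": n_ambiguous,
        "n_probes_removed_low_success": n_low_success,
        "n_probes_out": len(keep),
    }
    filtered = ProbeMatrix(
        betas=betas,
        det_p=matrix.det_p.loc[keep],
        beads=matrix.beads.loc[keep],
        groups=matrix.groups,
        probes=matrix.probes.loc[matrix.probes.index.isin(keep)] if matrix.probes is not None else None,
    )
    return filtered, report


def _m_values(betas: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    b = np.clip(betas, eps, 1 - eps)
    return np.log2(b / (1 - b))


def _welch_p(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test P ignoring NaNs (vectorized)."""
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_a = (~np.isnan(x_a)).sum(axis=1).astype(float)
        n_b = (~np.isnan(x_b)).sum(axis=1).astype(float)
        m_a, m_b = np.nanmean(x_a, axis=1), np.nanmean(x_b, axis=1)
        v_a = np.nanvar(x_a, axis=1, ddof=1)
        v_b = np.nanvar(x_b, axis=1, ddof=1)
        se2 = v_a / n_a + v_b / n_b
        t = (m_a - m_b) / np.sqrt(se2)
        # Welch-Satterthwaite degrees of freedom
        df = se2 ** 2 / (
            (v_a / n_a) ** 2 / (n_a - 1) + (v_b / n_b) ** 2 / (n_b - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return p


def differential_cpgs(
    matrix: ProbeMatrix,
    params: PipelineParams = PipelineParams(),
    *,
    value_scale: str = "beta",
) -> pd.DataFrame:
    """Per-probe Welch t test with BH-FDR and the dual flagging criterion.

    A probe is testable when both groups have at least two non-missing
    values.  ``value_scale='mvalue'`` runs the test on logit-transformed
    betas; group means and delta are always reported on the beta scale.
    Probes with zero variance in both groups and equal means get P = 1.
    Untestable probes are reported with missing P/FDR and never flagged.
    The flag is ``fdr < params.array_fdr and |delta| > params.array_delta``.
    """
    if value_scale not in ("beta", "mvalue"):
        raise ValueError(f"unknown value_scale: {value_scale!r}")
    carrier_cols = matrix.group_columns("carrier")
    control_cols = matrix.group_columns("control")
    beta_a = matrix.betas[carrier_cols].to_numpy(dtype=float)
    beta_b = matrix.betas[control_cols].to_numpy(dtype=float)
    n_a = (~np.isnan(beta_a)).sum(axis=1)
    n_b = (~np.isnan(beta_b)).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    if not testable.any():
        raise ValueError("no testable probes (need >= 2 non-missing values per group)")

    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(np.where(np.isnan(beta_a), np.nan, beta_a), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(beta_b), np.nan, beta_b), axis=1)
    delta = mean_a - mean_b

    if value_scale == "mvalue":
        x_a, x_b = _m_values(beta_a), _m_values(beta_b)
    else:
        x_a, x_b = beta_a, beta_b
    p = _welch_p(x_a, x_b)
    # zero variance in both groups: equal means -> no evidence (P = 1);
    # unequal means -> infinitely strong evidence under the t model (P = 0)
    with np.errstate(invalid="ignore"):
        var_a = np.nanvar(x_a, axis=1)
        var_b = np.nanvar(x_b, axis=1)
    zero_var = (var_a == 0) & (var_b == 0)
    p = np.where(zero_var & np.isclose(delta, 0.0), 1.0, p)
    p = np.where(zero_var & ~np.isclose(delta, 0.0), 0.0, p)
    p = np.where(testable, p, np.nan)

    fdr = np.full_like(p, np.nan)
    fdr[testable] = multipletests(p[testable], method="fdr_bh")[1]
    # epsilon guards the strict-> boundary against float rounding of the
    # group-mean difference (a delta of exactly 0.05 is not differential)
    with np.errstate(invalid="ignore"):
        flagged = (
            testable
            & (fdr < params.array_fdr)
            & (np.abs(delta) > params.array_delta + 1e-12)
        )

    return pd.DataFrame(
        {
            "probe": matrix.betas.index,
            "mean_beta_carrier": mean_a,
            "mean_beta_control": mean_b,
            "delta": delta,
            "p_value": p,
            "fdr": fdr,
            "is_differential": flagged,
        }
    ).set_index("probe")


def merge_flagged_cpgs(
    result: pd.DataFrame, probes: pd.DataFrame, merge_bp: int = 5000
) -> pd.DataFrame:
    """Group flagged CpGs into intervals by genomic proximity.

    Convenience only: this is the RRBS-style single-linkage interval
    merge applied to flagged array probes, not a dedicated array DMR
    caller, and is not comparable with DMRfinder-style grouping.
    ``probes`` must carry 'chrom' and 'pos' indexed by probe id.
    """
    flagged = result[result["is_differential"]].join(probes[["chrom", "pos"]], how="inner")
    flagged = flagged.sort_values(["chrom", "pos"])
    rows = []
    for chrom, sub in flagged.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if len(pos) == 0:
            continue
        group_id = np.zeros(len(pos), dtype=int)
        if len(pos) > 1:
            group_id[1:] = np.cumsum(np.diff(pos) > merge_bp)
        for g in np.unique(group_id):
            sel = pos[group_id == g]
            rows.append({"chrom": chrom, "start": int(sel[0]), "end": int(sel[-1]), "n_cpgs": len(sel)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs"])
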