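"""Differentially methylated block (DMB) calling.

Each CpG block is tested for a difference in methylation between the two
conditions with a Pearson chi-square test on the 2x2 table of unconverted
vs converted read counts (counts pooled across the samples of each
condition).  A block is a DMB when the chi-square P value is below
``dmb_p`` (default 0.01) AND the absolute difference in methylation ratios
exceeds ``dmb_delta`` (default 0.1) — both parts of the dual threshold are
required.  No multiple-testing correction is applied at this stage; the
method uses the raw P cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .block_aggregation import CpGBlock
from .meth_io import SampleTable
from .params import PipelineParams

__all__ = ["DMBResult", "chi_square_2x2", "call_dmbs", "condition_map", "dmbs_to_frame"]


@dataclass
class DMBResult:
    """One block's differential test: pooled counts, ratios, P, and call."""

    block: CpGBlock
    unconv_carrier: int
    total_carrier: int
    unconv_control: int
    total_control: int
    ratio_carrier: float
    ratio_control: float
    delta: float  # carrier - control; negative = hypomethylated in carriers
    p_value: float
    is_dmb: bool
    direction: str  # 'hypo' | 'hyper' | 'none'

    @property
    def chrom(self) -> str:
        return self.block.chrom

    @property
    def start(self) -> int:
        return self.block.start

    @property
    def end(self) -> int:
        return self.block.end


def _validate_counts(unconv: int, total: int, label: str) -> None:
    if unconv < 0 or total < 0:
        raise ValueError(f"{label}: negative count")
    if unconv > total:
        raise ValueError(f"{label}: unconverted ({unconv}) exceeds total ({total})")


def chi_square_2x2(
    unconv_a: int,
    total_a: int,
    unconv_b: int,
    total_b: int,
    *,
    correction: bool = False,
) -> float:
    """Pearson chi-square P for a 2x2 unconverted/converted count table.

    The table is ``[[unconv_a, total_a - unconv_a], [unconv_b,
    total_b - unconv_b]]`` with 1 degree of freedom.  The closed form for
    the statistic is ``N (ad - bc)^2 / (r1 r2 c1 c2)`` over the four cells
    and margins.  When any margin is zero the table is degenerate, the
    statistic is defined as 0 and P = 1.  ``correction=True`` applies the
    Yates continuity correction.
    """
    _validate_counts(unconv_a, total_a, "condition a")
    _validate_counts(unconv_b, total_b, "condition b")
    if total_a + total_b == 0:
        raise ValueError("both totals are zero")
    a, b = unconv_a, total_a - unconv_a
    c, d = unconv_b, total_b - unconv_b
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    return float(chi2.sf(stat, df=1))


def _chi_square_vec(
    unconv_a: np.ndarray,
    total_a: np.ndarray,
    unconv_b: np.ndarray,
    total_b: np.ndarray,
    correction: bool = False,
) -> np.ndarray:
    """Vectorized counterpart of :func:`chi_square_2x2` (same conventions)."""
    a = unconv_a.astype(np.float64)
    b = (total_a - unconv_a).astype(np.float64)
    c = unconv_b.astype(np.float64)
    d = (total_b - unconv_b).astype(np.float64)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    degenerate = (np.minimum(np.minimum(r1, r2), np.minimum(c1, c2)) == 0) | (n == 0)
    diff = np.abs(a * d - b * c)
    if correction:
        diff = np.maximum(0.0, diff - n / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(degenerate, 0.0, n * diff * diff / np.where(denom == 0, 1.0, denom))
    p = chi2.sf(stat, df=1)
    return np.where(degenerate, 1.0, p)


def condition_map(samples: Sequence[SampleTable]) -> dict[str, str]:
    """Sample-id → condition mapping from a collection of sample tables."""
    return {t.sample_id: t.condition for t in samples}


def call_dmbs(
    blocks: Sequence[CpGBlock],
    groups: Mapping[str, str],
    params: PipelineParams = PipelineParams(),
    *,
    correction: bool = False,
) -> list[DMBResult]:
    """Test every block and apply the dual DMB threshold.

    ``groups`` maps each sample id in the blocks' ``per_sample`` tables to
    ``'carrier'`` or ``'control'``; counts are pooled within condition.
    Blocks with zero pooled coverage in either condition get a missing
    P value (NaN) and ``is_dmb`` False.  The call is
    ``p < params.dmb_p and |delta| > params.dmb_delta`` (strict on both).
    """
    carriers = [s for s, g in groups.items() if g == "carrier"]
    controls = [s for s, g in groups.items() if g == "control"]
    bad = {g for g in groups.values()} - {"carrier", "control"}
    if bad:
        raise ValueError(f"unknown condition label(s): {sorted(bad)}")
    if not carriers or not controls:
        raise ValueError("need at least one sample per condition")

    n = len(blocks)
    unc_a = np.zeros(n, dtype=np.int64)
    tot_a = np.zeros(n, dtype=np.int64)
    unc_b = np.zeros(n, dtype=np.int64)
    tot_b = np.zeros(n, dtype=np.int64)
    for i, blk in enumerate(blocks):
        for sid in carriers:
            u, t = blk.counts(sid)
            unc_a[i] += u
            tot_a[i] += t
        for sid in controls:
            u, t = blk.counts(sid)
            unc_b[i] += u
            tot_b[i] += t

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_a = np.where(tot_a > 0, unc_a / np.maximum(tot_a, 1), np.nan)
        ratio_b = np.where(tot_b > 0, unc_b / np.maximum(tot_b, 1), np.nan)
    covered = (tot_a > 0) & (tot_b > 0)
    p = np.full(n, np.nan)
    if covered.any():
        p[covered] = _chi_square_vec(
            unc_a[covered], tot_a[covered], unc_b[covered], tot_b[covered], correction
        )
    delta = ratio_a - ratio_b
    # strict > on |delta|: the epsilon keeps a difference that is exactly
    # the threshold in exact arithmetic (e.g. 800/1000 - 700/1000) from
    # sneaking past the cut-off through float rounding
    with np.errstate(invalid="ignore"):
        is_dmb = covered & (p < params.dmb_p) & (np.abs(delta) > params.dmb_delta + 1e-12)

    results = []
    for i, blk in enumerate(blocks):
        d = float(delta[i]) if covered[i] else math.nan
        called = bool(is_dmb[i])
        if called:
            direction = "hypo" if d < 0 else "hyper"
        else:
            direction = "none"
        results.append(
            DMBResult(
                block=blk,
                unconv_carrier=int(unc_a[i]),
                total_carrier=int(tot_a[i]),
                unconv_control=int(unc_b[i]),
                total_control=int(tot_b[i]),
                ratio_carrier=float(ratio_a[i]),
                ratio_control=float(ratio_b[i]),
                delta=d,
                p_value=float(p[i]),
                is_dmb=called,
                direction=direction,
            )
        )
    return results


def dmbs_to_frame(dmbs: Sequence[DMBResult]):
    """DMB table with a fixed column order (tab-delimited on write)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_cpgs": r.block.n_cpgs,
                "unconv_carrier": r.unconv_carrier,
                "total_carrier": r.total_carrier,
                "unconv_control": r.unconv_control,
                "total_control": r.total_control,
                "ratio_carrier": r.ratio_carrier,
                "ratio_control": r.ratio_control,
                "delta": r.delta,
                "p_value": r.p_value,
                "is_dmb": r.is_dmb,
                "direction": r.direction,
            }
            for r in dmbs
        ],
        columns=[
            "chrom", "start", "end", "n_cpgs",
            "unconv_carrier", "total_carrier", "unconv_control", "total_control",
            "ratio_carrier", "ratio_control", "delta", "p_value", "is_dmb", "direction",
        ],
    )
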