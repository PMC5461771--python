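"""Differentially methylated region (DMR) calling.

Uninformative blocks are excluded first: blocks with fewer than
``min_total_reads`` summed reads across all samples, and blocks with more
than ``max_mismatch`` mismatching samples.  Surviving blocks within
``merge_bp`` (default 5000 bp, gap measured end-of-block to
start-of-next, inclusive at exactly ``merge_bp``) are merged into regions,
and a region is called a DMR when it contains at least ``min_dmbs``
qualifying DMBs (P < 0.01 and |delta| > 0.1).

The "mismatch" exclusion is deliberately isolated behind one predicate
because the criterion admits more than one reading:

``discordance`` (default)
    a mismatching sample is one whose own block-level methylation ratio,
    compared against the pooled ratio of the *other* condition,
    contradicts the sign of the pooled between-condition delta, while
    having informative coverage (block total >= 5 reads);
``missingness``
    a mismatching sample is simply one with zero coverage on the block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dmb_calling import DMBResult
from .meth_io import chrom_order
from .params import PipelineParams

__all__ = [
    "Region",
    "DMRCall",
    "Exclusion",
    "filter_blocks",
    "merge_regions",
    "call_dmrs",
    "regions_to_frame",
    "exclusions_to_frame",
]

#: minimum per-sample block coverage for a sample to count as informative
#: in the discordance mismatch predicate
MISMATCH_MIN_COVERAGE = 5


@dataclass
class Region:
    """A merged run of blocks with inter-block gaps <= merge_bp."""

    chrom: str
    start: int
    end: int
    member_blocks: list[DMBResult]

    @property
    def n_blocks(self) -> int:
        return len(self.member_blocks)

    @property
    def n_dmbs(self) -> int:
        return sum(1 for b in self.member_blocks if b.is_dmb)


@dataclass
class DMRCall:
    """A region with its DMR flag, direction, best P and mean delta."""

    region: Region
    is_dmr: bool
    direction: str  # 'hypo' | 'hyper' | 'mixed' | 'none'
    min_p: float
    mean_delta: float


@dataclass
class Exclusion:
    """One excluded block and the single primary reason for its exclusion."""

    block: DMBResult
    reason: str  # 'low_coverage' | 'mismatch'


def _count_mismatches(dmb: DMBResult, groups: Mapping[str, str], mode: str) -> int:
    blk = dmb.block
    if mode == "missingness":
        return sum(1 for sid in blk.per_sample if blk.counts(sid)[1] == 0)
    if mode != "discordance":
        raise ValueError(f"unknown mismatch mode: {mode!r}")
    pooled_delta = dmb.delta
    if not np.isfinite(pooled_delta) or pooled_delta == 0:
        return 0
    pooled_sign = 1.0 if pooled_delta > 0 else -1.0
    mismatches = 0
    for sid, (unc, tot) in blk.per_sample.items():
        if tot < MISMATCH_MIN_COVERAGE:
            continue
        cond = groups.get(sid)
        if cond == "carrier":
            other = dmb.ratio_control
            own_delta = unc / tot - other
        elif cond == "control":
            other = dmb.ratio_carrier
            own_delta = other - unc / tot
        else:
            continue
        if not np.isfinite(own_delta) or own_delta == 0:
            continue
        if (1.0 if own_delta > 0 else -1.0) != pooled_sign:
            mismatches += 1
    return mismatches


def filter_blocks(
    dmbs: Sequence[DMBResult],
    groups: Mapping[str, str],
    params: PipelineParams = PipelineParams(),
    *,
    mismatch_mode: str = "discordance",
) -> tuple[list[DMBResult], list[Exclusion]]:
    """Drop uninformative blocks; log every exclusion with one reason.

    Low coverage (summed reads across all samples < ``min_total_reads``)
    takes precedence over the mismatch rule, so each excluded block has
    exactly one primary reason.
    """
    kept: list[DMBResult] = []
    excluded: list[Exclusion] = []
    for dmb in dmbs:
        if dmb.block.total_coverage < params.min_total_reads:
            excluded.append(Exclusion(dmb, "low_coverage"))
        elif _count_mismatches(dmb, groups, mismatch_mode) > params.max_mismatch:
            excluded.append(Exclusion(dmb, "mismatch"))
        else:
            kept.append(dmb)
    return kept, excluded


def merge_regions(
    dmbs: Sequence[DMBResult], merge_bp: int = 5000
) -> list[Region]:
    """Single-linkage merge of blocks whose end-to-start gap is <= merge_bp.

    Input must already be sorted by (chromosome, start); regions never
    span chromosomes.
    """
    if merge_bp < 1:
        raise ValueError(f"merge_bp must be >= 1, got {merge_bp}")
    order = chrom_order(d.chrom for d in dmbs)
    rank = {c: i for i, c in enumerate(order)}
    keys = [(rank[d.chrom], d.start, d.end) for d in dmbs]
    if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
        raise ValueError("blocks must be sorted by (chrom, start) before merging")

    regions: list[Region] = []
    current: list[DMBResult] = []
    for dmb in dmbs:
        if current and dmb.chrom == current[-1].chrom:
            gap = dmb.start - max(b.end for b in current)
            if gap <= merge_bp:
                current.append(dmb)
                continue
        if current:
            regions.append(_close_region(current))
        current = [dmb]
    if current:
        regions.append(_close_region(current))
    return regions


def _close_region(members: list[DMBResult]) -> Region:
    return Region(
        chrom=members[0].chrom,
        start=min(b.start for b in members),
        end=max(b.end for b in members),
        member_blocks=list(members),
    )


def call_dmrs(
    regions: Sequence[Region], params: PipelineParams = PipelineParams()
) -> list[DMRCall]:
    """Flag regions containing at least ``min_dmbs`` qualifying DMBs.

    Direction is 'hypo'/'hyper' when every qualifying DMB shares the sign
    of its delta, 'mixed' otherwise, 'none' when the region holds no DMB.
    ``min_p`` is the smallest member-block P value; ``mean_delta`` averages
    the signed delta over qualifying DMBs only.
    """
    calls = []
    for region in regions:
        qualifying = [b for b in region.member_blocks if b.is_dmb]
        ps = [b.p_value for b in region.member_blocks if np.isfinite(b.p_value)]
        min_p = min(ps) if ps else math.nan
        if qualifying:
            deltas = [b.delta for b in qualifying]
            mean_delta = float(np.mean(deltas))
            if all(d < 0 for d in deltas):
                direction = "hypo"
            elif all(d > 0 for d in deltas):
                direction = "hyper"
            else:
                direction = "mixed"
        else:
            mean_delta = math.nan
            direction = "none"
        calls.append(
            DMRCall(
                region=region,
                is_dmr=len(qualifying) >= params.min_dmbs,
                direction=direction,
                min_p=min_p,
                mean_delta=mean_delta,
            )
        )
    return calls


def regions_to_frame(calls: Sequence[DMRCall]) -> pd.DataFrame:
    """Full region table: bounds, block/DMB counts, min P, mean delta, call."""
    return pd.DataFrame(
        [
            {
                "chrom": c.region.chrom,
                "start": c.region.start,
                "end": c.region.end,
                "n_blocks": c.region.n_blocks,
                "n_dmbs": c.region.n_dmbs,
                "min_p": c.min_p,
                "mean_delta": c.mean_delta,
                "direction": c.direction,
                "is_dmr": c.is_dmr,
            }
            for c in calls
        ],
        columns=[
            "chrom", "start", "end", "n_blocks", "n_dmbs",
            "min_p", "mean_delta", "direction", "is_dmr",
        ],
    )


def exclusions_to_frame(excluded: Sequence[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": e.block.chrom,
                "start": e.block.start,
                "end": e.block.end,
                "reason": e.reason,
            }
            for e in excluded
        ],
        columns=["chrom", "start", "end", "reason"],
    )
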