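"""CpG-block composition by chaining nearby CpG loci.

Methylation at neighbouring CpGs is highly correlated, so instead of
testing single loci the pipeline aggregates CpG loci within ``gap_bp``
(default 50 bp) of each other into blocks and pools their read counts.
Chaining is single-linkage on adjacent-pair distance: a block is a maximal
run of union CpG positions in which every adjacent pair is at most
``gap_bp`` apart, so a block may span more than ``gap_bp`` in total.

Block membership is defined on the union of positions observed in any
sample, so a per-sample coverage gap does not split a block; a sample with
no coverage on any member CpG gets a zero total and a missing ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .meth_io import SampleTable, chrom_order

__all__ = ["CpGBlock", "aggregate_blocks", "blocks_to_frame"]


@dataclass
class CpGBlock:
    """A chain of CpG loci with per-sample pooled counts.

    ``start``/``end`` are the 1-based positions of the first and last
    member CpG.  ``per_sample`` maps sample id to
    ``(unconverted_sum, total_sum)``.
    """

    chrom: str
    start: int
    end: int
    members: np.ndarray
    per_sample: dict[str, tuple[int, int]]

    @property
    def n_cpgs(self) -> int:
        return len(self.members)

    def counts(self, sample_id: str) -> tuple[int, int]:
        return self.per_sample.get(sample_id, (0, 0))

    def ratio(self, sample_id: str) -> float:
        unc, tot = self.counts(sample_id)
        return unc / tot if tot > 0 else math.nan

    @property
    def total_coverage(self) -> int:
        """Summed coverage over all samples — the low-coverage filter's quantity."""
        return sum(t for _, t in self.per_sample.values())


def _check_sorted(table: SampleTable) -> None:
    df = table.calls
    if len(df) < 2:
        return
    same_chrom = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    pos = df["pos"].to_numpy()
    if np.any(same_chrom & (pos[1:] < pos[:-1])):
        raise ValueError(f"sample {table.sample_id!r}: calls not sorted by position")


def aggregate_blocks(
    samples: Sequence[SampleTable], gap_bp: int = 50
) -> list[CpGBlock]:
    """Chain union CpG positions within ``gap_bp`` into blocks and pool counts.

    Returns blocks ordered by chromosome (order of first appearance across
    samples) then start position.  Counts for strand-duplicated positions
    within one sample are summed into the shared position.
    """
    if gap_bp < 1:
        raise ValueError(f"gap_bp must be >= 1, got {gap_bp}")
    if not samples:
        return []
    for t in samples:
        _check_sorted(t)

    chroms = chrom_order(c for t in samples for c in t.calls["chrom"])
    blocks: list[CpGBlock] = []
    for chrom in chroms:
        per_sample_sub = {
            t.sample_id: t.calls[t.calls["chrom"] == chrom] for t in samples
        }
        union = np.unique(
            np.concatenate(
                [sub["pos"].to_numpy() for sub in per_sample_sub.values() if len(sub)]
            )
        )
        if union.size == 0:
            continue
        # adjacent gap > gap_bp starts a new block
        block_id = np.zeros(union.size, dtype=np.int64)
        if union.size > 1:
            block_id[1:] = np.cumsum(np.diff(union) > gap_bp)
        n_blocks = int(block_id[-1]) + 1

        sums: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for sid, sub in per_sample_sub.items():
            unc_sum = np.zeros(n_blocks, dtype=np.int64)
            tot_sum = np.zeros(n_blocks, dtype=np.int64)
            if len(sub):
                idx = np.searchsorted(union, sub["pos"].to_numpy())
                bid = block_id[idx]
                np.add.at(unc_sum, bid, sub["unconverted"].to_numpy())
                np.add.at(tot_sum, bid, sub["total"].to_numpy())
            sums[sid] = (unc_sum, tot_sum)

        bounds = np.searchsorted(block_id, np.arange(n_blocks + 1))
        for b in range(n_blocks):
            members = union[bounds[b]:bounds[b + 1]]
            per_sample = {
                sid: (int(u[b]), int(t[b])) for sid, (u, t) in sums.items()
            }
            blocks.append(
                CpGBlock(
                    chrom=chrom,
                    start=int(members[0]),
                    end=int(members[-1]),
                    members=members,
                    per_sample=per_sample,
                )
            )
    return blocks


def blocks_to_frame(blocks: Sequence[CpGBlock]) -> pd.DataFrame:
    """Block table: chrom, start, end, n_cpgs, then per-sample counts/ratio."""
    sample_ids = list(blocks[0].per_sample) if blocks else []
    rows = []
    for blk in blocks:
        row: dict = {
            "chrom": blk.chrom,
            "start": blk.start,
            "end": blk.end,
            "n_cpgs": blk.n_cpgs,
        }
        for sid in sample_ids:
            unc, tot = blk.counts(sid)
            row[f"{sid}_unconverted"] = unc
            row[f"{sid}_total"] = tot
            row[f"{sid}_ratio"] = blk.ratio(sid)
        rows.append(row)
    cols = ["chrom", "start", "end", "n_cpgs"] + [
        f"{sid}_{suffix}" for sid in sample_ids for suffix in ("unconverted", "total", "ratio")
    ]
    return pd.DataFrame(rows, columns=cols)
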