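import math

import numpy as np
import pandas as pd
import pytest

from clustermeth.block_aggregation import CpGBlock
from clustermeth.dmb_calling import DMBResult
from clustermeth.meth_io import CALL_COLUMNS, SampleTable


def make_sample(sample_id, condition, rows, sex="U"):
    """rows: iterable of (chrom, pos, strand, unconverted, total)."""
    return SampleTable(
        sample_id=sample_id,
        condition=condition,
        sex=sex,
        calls=pd.DataFrame(rows, columns=CALL_COLUMNS),
    )


def make_block(chrom="chr1", start=100, end=100, per_sample=None, members=None):
    if members is None:
        members = np.array([start]) if start == end else np.array([start, end])
    if per_sample is None:
        per_sample = {"a": (5, 10), "b": (5, 10)}
    return CpGBlock(
        chrom=chrom, start=start, end=end, members=np.asarray(members), per_sample=per_sample
    )


def make_dmb(
    chrom="chr1",
    start=100,
    end=150,
    p_value=0.5,
    delta=0.0,
    is_dmb=False,
    per_sample=None,
    ratio_carrier=None,
    ratio_control=0.5,
):
    """Minimal DMBResult for filter/merge/call tests."""
    if ratio_carrier is None:
        ratio_carrier = ratio_control + delta
    block = make_block(chrom=chrom, start=start, end=end, per_sample=per_sample)
    direction = "none" if not is_dmb else ("hypo" if delta < 0 else "hyper")
    return DMBResult(
        block=block,
        unconv_carrier=0,
        total_carrier=sum(t for _, t in block.per_sample.values()) // 2 or 1,
        unconv_control=0,
        total_control=1,
        ratio_carrier=ratio_carrier,
        ratio_control=ratio_control,
        delta=delta,
        p_value=p_value,
        is_dmb=is_dmb,
        direction=direction,
    )


@pytest.fixture
def two_sample_pair():
    carrier = make_sample(
        "car1",
        "carrier",
        [("chr1", 100, "+", 30, 40), ("chr1", 140, "+", 28, 40), ("chr1", 300, "+", 10, 20)],
    )
    control = make_sample(
        "ctl1",
        "control",
        [("chr1", 100, "+", 10, 40), ("chr1", 140, "+", 12, 40), ("chr1", 300, "+", 11, 20)],
    )
    return carrier, control


def brute_force_chain(positions, gap):
    """O(n^2) oracle: connected components of |pos_i - pos_j| <= gap.

    Union-find over all pairs; because positions lie on a line, the
    transitive closure equals chaining on sorted adjacent gaps — the
    oracle does not rely on sorting and so checks that equivalence.
    """
    positions = list(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= gap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(c) for c in comps.values())
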