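"""Pipeline thresholds, collected in one configurable record.

Every numeric cut-off used by the RRBS block/DMB/DMR stages, the 450k
per-CpG stage, and the qPCR statistics lives here so a run is fully
described by one :class:`PipelineParams` plus the input files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import yaml


@dataclass(frozen=True)
class PipelineParams:
    """All numeric thresholds of the differential-methylation pipeline.

    Attributes
    ----------
    gap_bp
        Maximum distance (bp) between adjacent CpGs chained into one block.
    dmb_p
        Chi-square P-value cut-off for calling a differentially methylated
        block (strict ``<``).
    dmb_delta
        Minimum absolute methylation-ratio difference between conditions
        for a DMB (strict ``>``).
    merge_bp
        Maximum end-to-start gap (bp) between blocks merged into one
        region (inclusive ``<=``).
    min_total_reads
        Blocks with summed coverage across all samples below this are
        excluded before merging.
    max_mismatch
        Blocks with more than this many mismatching samples are excluded.
    min_dmbs
        Minimum number of qualifying DMBs for a region to be a DMR
        (inclusive ``>=``).
    array_fdr
        Benjamini-Hochberg FDR cut-off for array per-CpG calls (strict ``<``).
    array_delta
        Minimum absolute beta difference for array per-CpG calls
        (strict ``>``).
    alpha
        Significance level for Bonferroni-adjusted t tests (strict ``<``).
    """

    gap_bp: int = 50
    dmb_p: float = 0.01
    dmb_delta: float = 0.1
    merge_bp: int = 5000
    min_total_reads: int = 10
    max_mismatch: int = 1
    min_dmbs: int = 10
    array_fdr: float = 0.05
    array_delta: float = 0.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("gap_bp", "merge_bp", "min_total_reads", "min_dmbs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer, got {getattr(self, name)}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        for name in ("dmb_p", "array_fdr", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("dmb_delta", "array_delta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def updated(self, **overrides: Any) -> "PipelineParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
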