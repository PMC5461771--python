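"""Seeded generators for synthetic RRBS counts, 450k matrices, and CT tables.

The RRBS generator emulates the statistical structure the pipeline
assumes: CpGs occur in dense islands (reduced-representation libraries
concentrate coverage at CpG-dense restriction fragments), methylation
levels of nearby CpGs are strongly correlated, baseline methylation is
bimodal (a high-methylation mode near 0.85 and a low mode near 0.10),
per-site coverage is overdispersed, and read counts are binomial draws
from the latent methylation level (bisulfite conversion noise).  Planted
clusters are genomic intervals in which carrier samples are
hypomethylated by a fixed effect size; the defaults sit in the 5-20%
range that clustered hypomethylation shows in SMCHD1 mutation carriers.

Spatial correlation is piecewise-constant: consecutive CpGs share one
latent base level over runs of roughly ``spatial_corr_bp`` bases, with
small per-site jitter, rather than a full Gaussian process — cheap, and
sufficient to make block aggregation meaningful.  Fragment-level
digestion realism (MspI/TaqI size selection) is approximated by the
clustered island placement, not modelled from sequence.

The 450k generator plants a carrier-specific beta reduction at chosen
probes in a bimodal baseline matrix with bounded noise, plus a
configurable fraction of QC-violating detection-P/bead-count entries.
The qPCR generator offsets carrier target CTs by -log2(fold) and builds
ChIP CT quartets with a chosen true enrichment over IgG.

Every generator is a pure function of its :class:`SimulationConfig`
(including the seed): the same config yields byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .array450k import ProbeMatrix
from .meth_io import CALL_COLUMNS, SampleTable, write_methcalls, write_table

__all__ = [
    "SimulationConfig",
    "Array450kSim",
    "QpcrSim",
    "simulate_rrbs",
    "simulate_450k",
    "simulate_qpcr",
    "write_rrbs_files",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generators need; the seed fully determines output.

    RRBS fields
    -----------
    chrom_length_bp : upper bound for CpG placement (bp).
    n_islands : background CpG islands placed outside planted clusters.
    island_size_mean : mean CpGs per background island (1 + Poisson).
    intra_spacing_bp : (lo, hi) spacing between CpGs inside an island;
        kept below the 50 bp chaining gap so islands form blocks.
    inter_island_gap_bp : (lo, hi) gap between background islands; above
        50 bp so separate islands form separate blocks.
    clusters : planted hypomethylation intervals as
        (start, end, effect_delta) with effect_delta the carrier
        methylation reduction in [0, 1].
    cluster_island_size : (lo, hi) CpGs per island inside a planted
        cluster (denser than background, as at CpG-rich repeat arrays).
    cluster_island_gap_bp : (lo, hi) gap between islands inside a planted
        cluster; below the 5000 bp merge distance so a cluster becomes
        one region.
    baseline_meth : mixture of (weight, mean, sd) latent base levels.
    spatial_corr_bp : run length over which consecutive CpGs share one
        latent base level.
    site_jitter_sd : per-CpG jitter around the shared base level.
    coverage_mean / coverage_dispersion : negative-binomial per-site
        coverage (dispersion = NB size; larger = closer to Poisson).
    samples_per_condition : biological samples per condition (the source
        study had one carrier and one control per sex).
    """

    seed: int = 0
    # --- RRBS ---
    chrom: str = "chrS"
    chrom_length_bp: int = 50_000_000
    n_islands: int = 2000
    island_size_mean: float = 5.0
    intra_spacing_bp: tuple[int, int] = (5, 45)
    inter_island_gap_bp: tuple[int, int] = (2000, 12000)
    clusters: tuple[tuple[int, int, float], ...] = ()
    cluster_island_size: tuple[int, int] = (4, 8)
    cluster_island_gap_bp: tuple[int, int] = (500, 3000)
    baseline_meth: tuple[tuple[float, float, float], ...] = (
        (0.7, 0.85, 0.06),
        (0.3, 0.10, 0.04),
    )
    spatial_corr_bp: int = 100
    site_jitter_sd: float = 0.02
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0
    samples_per_condition: int = 1
    sex: str = "F"
    # --- 450k ---
    array_n_probes: int = 20_000
    array_n_carrier: int = 24
    array_n_control: int = 23
    array_noise_sd: float = 0.03
    array_n_planted: int = 0
    array_planted_delta: float = 0.15
    array_detp_fail_frac: float = 0.005
    array_low_bead_frac: float = 0.005
    array_ambiguous_frac: float = 0.002
    # --- qPCR ---
    expr_n_carrier: int = 7
    expr_n_control: int = 4
    expr_folds: tuple[tuple[str, float], ...] = (
        ("g02", 2.0),
        ("g05", 2.0),
        ("g08", 2.0),
    )
    expr_n_genes: int = 14
    housekeeping_ct: float = 22.0
    target_base_ct: float = 26.0
    ct_noise_sd: float = 0.15
    ct_replicates: int = 2
    chip_loci: tuple[tuple[str, float], ...] = (("HS19_20", 8.0), ("HS5_1", 1.0))
    chip_n_samples: int = 4
    chip_input_ct: float = 25.0
    chip_igg_dct: float = 10.0

    def __post_init__(self) -> None:
        if self.chrom_length_bp < 1 or self.n_islands < 0:
            raise ValueError("chromosome length and island count must be positive")
        for start, end, delta in self.clusters:
            if not (1 <= start < end <= self.chrom_length_bp):
                raise ValueError(f"cluster ({start}, {end}) outside [1, {self.chrom_length_bp}]")
            if not 0.0 <= delta <= 1.0:
                raise ValueError(f"effect_delta must lie in [0, 1], got {delta}")
        w = sum(w for w, _, _ in self.baseline_meth)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"baseline mixture weights must sum to 1, got {w}")
        if self.coverage_mean < 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage_mean must be >= 0 and dispersion > 0")
        if self.samples_per_condition < 1:
            raise ValueError("need at least one sample per condition")

    def updated(self, **overrides: Any) -> "SimulationConfig":
        return replace(self, **overrides)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("intra_spacing_bp", "inter_island_gap_bp", "cluster_island_size",
                    "cluster_island_gap_bp"):
            if key in d:
                d[key] = tuple(d[key])
        if "clusters" in d:
            d["clusters"] = tuple(tuple(c) for c in d["clusters"])
        if "baseline_meth" in d:
            d["baseline_meth"] = tuple(tuple(c) for c in d["baseline_meth"])
        if "expr_folds" in d:
            d["expr_folds"] = tuple(tuple(c) for c in d["expr_folds"])
        if "chip_loci" in d:
            d["chip_loci"] = tuple(tuple(c) for c in d["chip_loci"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# RRBS


def _draw_base_level(rng: np.random.Generator, mixture) -> float:
    weights = np.array([w for w, _, _ in mixture])
    k = rng.choice(len(mixture), p=weights / weights.sum())
    _, mean, sd = mixture[k]
    return float(np.clip(rng.normal(mean, sd), 0.005, 0.995))


def _place_positions(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """CpG positions plus a parallel array of planted-cluster effect deltas."""
    positions: list[int] = []
    effects: list[float] = []

    # dense islands inside each planted cluster
    for start, end, delta in cfg.clusters:
        cursor = start
        lo_n, hi_n = cfg.cluster_island_size
        while cursor < end:
            size = int(rng.integers(lo_n, hi_n + 1))
            pos = cursor
            for _ in range(size):
                if pos > end:
                    break
                positions.append(pos)
                effects.append(delta)
                pos += int(rng.integers(cfg.intra_spacing_bp[0], cfg.intra_spacing_bp[1] + 1))
            cursor = pos + int(
                rng.integers(cfg.cluster_island_gap_bp[0], cfg.cluster_island_gap_bp[1] + 1)
            )

    # background islands in the complement of the planted intervals
    sorted_clusters = sorted((s, e) for s, e, _ in cfg.clusters)
    cursor = 1
    made = 0
    while made < cfg.n_islands and cursor < cfg.chrom_length_bp:
        cursor += int(rng.integers(cfg.inter_island_gap_bp[0], cfg.inter_island_gap_bp[1] + 1))
        for s, e in sorted_clusters:  # jump past planted intervals
            if s - 200 <= cursor <= e + 200:
                cursor = e + 201
        if cursor >= cfg.chrom_length_bp:
            break
        size = 1 + int(rng.poisson(max(cfg.island_size_mean - 1.0, 0.0)))
        pos = cursor
        for _ in range(size):
            positions.append(pos)
            effects.append(0.0)
            pos += int(rng.integers(cfg.intra_spacing_bp[0], cfg.intra_spacing_bp[1] + 1))
        cursor = pos
        made += 1

    pos_arr = np.asarray(positions, dtype=np.int64)
    eff_arr = np.asarray(effects, dtype=float)
    order = np.argsort(pos_arr, kind="mergesort")
    pos_arr, eff_arr = pos_arr[order], eff_arr[order]
    keep = np.ones(pos_arr.size, dtype=bool)
    keep[1:] = np.diff(pos_arr) > 0  # drop coincidental duplicates
    return pos_arr[keep], eff_arr[keep]


def _latent_methylation(
    rng: np.random.Generator, cfg: SimulationConfig, positions: np.ndarray, effects: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(control latent m, carrier latent m): shared run levels + jitter."""
    n = positions.size
    m = np.empty(n)
    base = None
    high = max(cfg.baseline_meth, key=lambda t: t[1])
    for i in range(n):
        # correlation chains: CpGs within spatial_corr_bp of their
        # neighbour share one latent base level, so a whole island (and
        # hence a whole <=50 bp block) sits at a common level
        if base is None or positions[i] - positions[i - 1] > cfg.spatial_corr_bp:
            if effects[i] > 0:
                # planted clusters sit at methylated CpG-rich arrays: draw
                # the base from the high-methylation mixture component
                base = float(np.clip(rng.normal(high[1], high[2]), 0.005, 0.995))
            else:
                base = _draw_base_level(rng, cfg.baseline_meth)
        m[i] = base
    m = np.clip(m + rng.normal(0.0, cfg.site_jitter_sd, size=n), 0.0, 1.0)
    m_carrier = np.clip(m - effects, 0.0, 1.0)
    return m, m_carrier


def _draw_coverage(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    mu, k = cfg.coverage_mean, cfg.coverage_dispersion
    if mu <= 0:
        return np.zeros(n, dtype=np.int64)
    return rng.negative_binomial(k, k / (k + mu), size=n).astype(np.int64)


def simulate_rrbs(cfg: SimulationConfig) -> tuple[list[SampleTable], pd.DataFrame]:
    """Generate per-sample methylation-call tables and a planted-truth table.

    Returns ``(samples, truth)``: one :class:`SampleTable` per sample
    (carriers first) and a truth DataFrame with columns chrom, start,
    end, effect_delta — one row per planted cluster.
    """
    rng = np.random.default_rng(cfg.seed)
    positions, effects = _place_positions(rng, cfg)
    m_control, m_carrier = _latent_methylation(rng, cfg, positions, effects)

    samples: list[SampleTable] = []
    for condition, latent in (("carrier", m_carrier), ("control", m_control)):
        for i in range(cfg.samples_per_condition):
            cov = _draw_coverage(rng, cfg, positions.size)
            unc = rng.binomial(cov, latent)
            calls = pd.DataFrame(
                {
                    "chrom": cfg.chrom,
                    "pos": positions,
                    "strand": "+",
                    "unconverted": unc.astype(np.int64),
                    "total": cov,
                },
                columns=CALL_COLUMNS,
            )
            samples.append(
                SampleTable(
                    sample_id=f"{condition}_{i + 1}",
                    condition=condition,
                    sex=cfg.sex,
                    calls=calls,
                )
            )
    truth = pd.DataFrame(
        [
            {"chrom": cfg.chrom, "start": s, "end": e, "effect_delta": d}
            for s, e, d in cfg.clusters
        ],
        columns=["chrom", "start", "end", "effect_delta"],
    )
    return samples, truth


def write_rrbs_files(cfg: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Simulate and write methratio-dialect TSVs plus the truth table."""
    os.makedirs(out_dir, exist_ok=True)
    samples, truth = simulate_rrbs(cfg)
    paths = {}
    for t in samples:
        p = os.path.join(out_dir, f"{t.sample_id}.tsv")
        write_methcalls(t, p)
        paths[t.sample_id] = p
    truth_path = os.path.join(out_dir, "truth_clusters.tsv")
    write_table(truth, truth_path)
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# 450k


@dataclass
class Array450kSim:
    matrix: ProbeMatrix
    truth: pd.DataFrame  # planted probe ids with their beta reduction
    ambiguous_probes: frozenset[str]


def simulate_450k(cfg: SimulationConfig) -> Array450kSim:
    """Bimodal beta matrix with planted carrier hypomethylation and QC noise.

    Planted probes are drawn from the high-methylation mode so the
    subtraction stays inside [0, 1]; carriers at planted probes are
    reduced by ``array_planted_delta``.  A configurable fraction of
    entries violates the detection-P and bead-count QC rules, and a
    fraction of probes is labelled ambiguously mapped.
    """
    rng = np.random.default_rng(cfg.seed)
    n_probes = cfg.array_n_probes
    n_car, n_ctl = cfg.array_n_carrier, cfg.array_n_control
    n_samples = n_car + n_ctl
    probe_ids = pd.Index([f"cg{i:06d}" for i in range(n_probes)], name="probe")
    sample_ids = [f"carrier_{i + 1}" for i in range(n_car)] + [
        f"control_{i + 1}" for i in range(n_ctl)
    ]

    high = rng.random(n_probes) < 0.6
    baseline = np.where(
        high,
        np.clip(rng.normal(0.85, 0.05, n_probes), 0.02, 0.98),
        np.clip(rng.normal(0.15, 0.05, n_probes), 0.02, 0.98),
    )
    if cfg.array_n_planted > n_probes:
        raise ValueError("more planted probes than probes")
    high_idx = np.flatnonzero(high)
    if cfg.array_n_planted > high_idx.size:
        raise ValueError("not enough high-methylation probes to plant in")
    planted = rng.choice(high_idx, size=cfg.array_n_planted, replace=False)
    planted_mask = np.zeros(n_probes, dtype=bool)
    planted_mask[planted] = True

    means = np.tile(baseline[:, None], (1, n_samples))
    means[np.ix_(planted_mask, np.arange(n_car))] -= cfg.array_planted_delta
    betas = np.clip(means + rng.normal(0.0, cfg.array_noise_sd, means.shape), 0.0, 1.0)

    det_p = rng.uniform(0.0, 0.005, size=betas.shape)
    fail = rng.random(betas.shape) < cfg.array_detp_fail_frac
    det_p[fail] = rng.uniform(0.011, 0.5, size=int(fail.sum()))
    beads = 3 + rng.poisson(12.0, size=betas.shape)
    low = rng.random(betas.shape) < cfg.array_low_bead_frac
    beads[low] = rng.integers(0, 3, size=int(low.sum()))

    n_amb = int(round(cfg.array_ambiguous_frac * n_probes))
    ambiguous = frozenset(
        probe_ids[i] for i in rng.choice(n_probes, size=n_amb, replace=False)
    )

    positions = 1 + np.cumsum(rng.integers(100, 10_000, size=n_probes))
    probes = pd.DataFrame(
        {
            "chrom": "chrS",
            "pos": positions,
            "class": rng.choice(["island", "shore", "other"], size=n_probes, p=[0.4, 0.25, 0.35]),
        },
        index=probe_ids,
    )
    groups = pd.Series(
        ["carrier"] * n_car + ["control"] * n_ctl, index=sample_ids, name="group"
    )
    matrix = ProbeMatrix(
        betas=pd.DataFrame(betas, index=probe_ids, columns=sample_ids),
        det_p=pd.DataFrame(det_p, index=probe_ids, columns=sample_ids),
        beads=pd.DataFrame(beads, index=probe_ids, columns=sample_ids),
        groups=groups,
        probes=probes,
    )
    truth = pd.DataFrame(
        {"probe": probe_ids[planted_mask], "planted_delta": -cfg.array_planted_delta}
    ).set_index("probe")
    return Array450kSim(matrix=matrix, truth=truth, ambiguous_probes=ambiguous)


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrSim:
    expression: pd.DataFrame  # sample, target, assay, replicate, ct
    chip: pd.DataFrame
    truth_expression: pd.DataFrame  # gene -> true fold (carrier vs control)
    truth_chip: pd.DataFrame  # locus -> true enrichment over IgG


def simulate_qpcr(cfg: SimulationConfig) -> QpcrSim:
    """CT tables for expression and ChIP with known folds/enrichments.

    Carrier samples at a planted gene have target CTs offset by
    -log2(fold); ChIP antibody CTs sit log2(enrichment) cycles below the
    IgG CT after input normalization, so the recovered fold equals the
    planted enrichment in the noise-free limit.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i + 1:02d}" for i in range(cfg.expr_n_genes)]
    folds = dict(cfg.expr_folds)
    unknown = set(folds) - set(genes)
    if unknown:
        raise ValueError(f"expr_folds names unknown gene(s): {sorted(unknown)}")
    samples = [f"carrier_{i + 1}" for i in range(cfg.expr_n_carrier)] + [
        f"control_{i + 1}" for i in range(cfg.expr_n_control)
    ]

    expr_rows = []
    for s in samples:
        is_carrier = s.startswith("carrier")
        for rep in range(1, cfg.ct_replicates + 1):
            expr_rows.append(
                {
                    "sample": s,
                    "target": "GUS1",
                    "assay": "expression",
                    "replicate": rep,
                    "ct": cfg.housekeeping_ct + rng.normal(0.0, cfg.ct_noise_sd),
                }
            )
        for g in genes:
            fold = folds.get(g, 1.0) if is_carrier else 1.0
            base = cfg.target_base_ct - np.log2(fold)
            for rep in range(1, cfg.ct_replicates + 1):
                expr_rows.append(
                    {
                        "sample": s,
                        "target": g,
                        "assay": "expression",
                        "replicate": rep,
                        "ct": base + rng.normal(0.0, cfg.ct_noise_sd),
                    }
                )

    chip_rows = []
    for i in range(cfg.chip_n_samples):
        s = f"chip_{i + 1}"
        for locus, enrichment in cfg.chip_loci:
            if enrichment <= 0:
                raise ValueError(f"chip enrichment must be positive, got {enrichment}")
            input_ct = cfg.chip_input_ct
            igg_ct = input_ct + cfg.chip_igg_dct
            ab_ct = igg_ct - np.log2(enrichment)
            for assay, ct in (
                ("chip_ab", ab_ct),
                ("chip_igg", igg_ct),
                ("chip_input", input_ct),
            ):
                for rep in range(1, cfg.ct_replicates + 1):
                    chip_rows.append(
                        {
                            "sample": s,
                            "target": locus,
                            "assay": assay,
                            "replicate": rep,
                            "ct": ct + rng.normal(0.0, cfg.ct_noise_sd),
                        }
                    )

    cols = ["sample", "target", "assay", "replicate", "ct"]
    truth_expr = pd.DataFrame(
        {"gene": genes, "fold": [folds.get(g, 1.0) for g in genes]}
    ).set_index("gene")
    truth_chip = pd.DataFrame(
        [{"locus": l, "enrichment": e} for l, e in cfg.chip_loci]
    ).set_index("locus")
    return QpcrSim(
        expression=pd.DataFrame(expr_rows, columns=cols),
        chip=pd.DataFrame(chip_rows, columns=cols),
        truth_expression=truth_expr,
        truth_chip=truth_chip,
    )
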