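# Methods

## Model and procedure

The pipeline tests for differential methylation between two conditions
(labelled *carrier* and *control*) using bisulfite read counts. At a CpG
the data are (unconverted, total) read counts; unconverted cytosines were
protected from bisulfite conversion and therefore methylated, so the
methylation ratio is unconverted/total.

Single-CpG counts are shallow and noisy, while methylation of nearby
CpGs is strongly correlated, so the testing unit is the **CpG block**:
a maximal chain of CpG positions in which each adjacent pair lies within
`gap_bp` (default 50) bases. Chaining is single-linkage on the union of
positions observed in any sample — a per-sample coverage gap does not
split a block, and a block may span more than `gap_bp` in total. Counts
are summed over member CpGs per sample, then pooled per condition.

Each block is tested with a Pearson chi-square (1 df, closed form
`N(ad−bc)²/(r₁r₂c₁c₂)`, no continuity correction by default; Yates
available behind a flag). A degenerate table — any zero margin — is
assigned statistic 0 and P = 1 rather than an error: a block seen only
unmethylated (or only methylated) in both conditions carries no
differential evidence. A block is a **DMB** when P < `dmb_p` (0.01) and
|Δm| > `dmb_delta` (0.1), both strict. No multiple-testing correction is
applied at this stage; the block-level raw-P cut-off combined with the
downstream ≥ 10-DMB regional requirement is the method's false-positive
control, and adding FDR here would change the procedure being
implemented.

Before region building, uninformative blocks are excluded:

* `low_coverage` — summed coverage across **all** samples below
  `min_total_reads` (10);
* `mismatch` — more than `max_mismatch` (1) mismatching samples.

The mismatch criterion admits more than one reading, so it is isolated
behind one predicate with two modes. The default, *discordance*, counts
samples whose own block ratio, compared against the pooled ratio of the
opposite condition, contradicts the sign of the pooled
between-condition delta while the sample has ≥ 5 reads on the block
(the coverage floor keeps one stray read from counting as discordance).
The alternative, *missingness*, counts samples with zero block coverage.
Low coverage is checked first, so each excluded block logs exactly one
primary reason.

Surviving blocks are merged single-linkage when the end-of-block to
start-of-next gap is ≤ `merge_bp` (5000; inclusive at exactly 5000), and
a region is a **DMR** when it contains at least `min_dmbs` (10)
qualifying DMBs — qualifying meaning the DMB dual criterion, not mere
region membership. Region direction is the consensus sign of qualifying
deltas (`hypo`/`hyper`, else `mixed`).

With one carrier and one control per sex, condition is confounded with
individual; the stratified runner therefore analyses each sex
separately and reports DMRs found in both strata (≥ 1 bp interval
overlap), in either, or in one only.

### 450k module

Input is a normalized beta matrix (normalization is upstream and out of
scope). QC masks entries with detection P > 0.01 or bead count < 3
(boundaries kept), removes ambiguously mapped probes from a supplied
list, then removes probes missing in strictly more than 95% of samples —
evaluated after masking, since masking creates the missingness the rule
measures. Masking never alters surviving values.

Per-probe testing uses a Welch t test on beta values (the two-group
design with n = 24/23 needs nothing heavier; an M-value mode —
logit₂(β) — is available since variance is more homogeneous on that
scale), Benjamini–Hochberg FDR across all testable probes (≥ 2
non-missing values per group), and a call at FDR < 0.05 with
|Δβ| > 0.05. Zero-variance probes with equal means get P = 1 (no
evidence) rather than NaN. `merge_flagged_cpgs` offers proximity
grouping of flagged probes, documented as *not* equivalent to dedicated
array DMR callers that model probe-level statistics jointly.

### qPCR module

Technical replicates are averaged on the CT scale first. ChIP
enrichment is `E^−[(CT_ab − CT_input,ab) − (CT_igg − CT_input,igg)]`
with efficiency E = 2.0 by default (plain ΔΔCT; configurable for assays
with calibrated efficiencies); the IgG background maps to exactly 1 and
the quantity is invariant under adding a constant to all four CTs.
Relative expression is `E^−(CT_target − CT_housekeeping)` per sample,
divided by the arithmetic mean over the control group so the control
mean is exactly 1. Group comparisons are Welch t tests on
log₂-transformed relative quantities (fold changes are closer to
log-normal than normal; a raw-scale mode exists), with Bonferroni
correction `min(1, p·n_tests)` where `n_tests` is the number of targets
in the panel — supplied by the caller because the family is a property
of the experiment, not of one test.

## Synthetic data: what it emulates, and what it does not

`simulate_rrbs` emulates the structure the analysis relies on: CpGs
arrive in dense islands (reduced-representation libraries concentrate
coverage at CpG-rich restriction fragments — modelled by clustered
placement, not by sequence digestion); baseline methylation is bimodal
(mixture of 70% mass at 0.85 ± 0.06 and 30% at 0.10 ± 0.04); methylation
is spatially correlated — consecutive CpGs within `spatial_corr_bp`
(100 bp) of their neighbour share one latent level, plus per-site
jitter (SD 0.02); coverage is negative-binomial (mean 30, size 8, i.e.
modestly overdispersed relative to Poisson); and unconverted counts are
binomial in the latent level (conversion/sampling noise). Planted
clusters are intervals of denser islands (4–8 CpGs, inter-island gaps
0.5–3 kb so one cluster merges into one region) whose carrier latent
levels are reduced by an effect size in the 5–20% range the biology
shows, drawn from the high-methylation mode so the subtraction stays in
[0, 1]. Default sample design is one carrier and one control (the per-sex
design of the motivating study).

The piecewise-constant correlation is deliberate: a full Gaussian
process would be slower and would blur the block structure the test
assumes; sharing one level per ≤ 100 bp chain makes whole blocks
homogeneous, which is exactly the regime in which the pooled chi-square
is calibrated. Consequently, passing null-calibration tests here shows
the test is correct *under the stated correlation model*; real data with
within-block heterogeneity or sample-level dispersion would inflate the
chi-square, and the simulator makes no claim to capture that, nor
fragment-level digestion, alignment error, or copy-number variation of
repeat arrays.

`simulate_450k` uses a bimodal probe baseline (60% near β = 0.85, 40%
near 0.15), truncated Gaussian noise (SD 0.03) clipped to [0, 1], group
sizes 24 vs 23, planted carrier reductions at high-methylation probes,
and small fractions of QC-violating entries (0.5% detection-P failures,
0.5% low-bead entries, 0.2% ambiguous probes). `simulate_qpcr` offsets
carrier target CTs by −log₂(fold), and builds ChIP CT quartets whose
recovered enrichment equals the planted value in the noise-free limit;
replicate noise SD defaults to 0.15 cycles.

Every generator draws from one `numpy` Generator seeded by the config,
so identical configs give byte-identical output files.

## Numerical choices

* **Strict thresholds at float boundaries.** The DMB and array delta
  rules are strict (`>`); a difference that equals the threshold in
  exact arithmetic (e.g. 800/1000 − 700/1000 vs 0.1) can exceed it in
  floats, so both comparisons carry a 10⁻¹² guard. Methylation
  differences of that order are physically meaningless, so the guard
  cannot misclassify a real effect.
* **Missing values.** Zero-coverage sites and blocks are retained and
  flagged (ratio/P = NaN), never silently dropped; exclusion is the
  filter stage's job and is logged.
* **Ordering.** Chromosomes keep their order of first appearance in the
  input; blocks with equal starts order by end; all outputs are
  deterministic.
* **BED output.** Internal coordinates are 1-based inclusive (matching
  methratio-style input); BED conversion subtracts 1 from the start.
  Scores are `min(1000, round(−10·log₁₀ min P))`, 1000 at P = 0, 0 when
  undefined.
* **Strand handling.** Opposite-strand calls of one CpG dinucleotide
  are kept separate by default (no collapsing rule is assumed);
  `collapse_strands=True` sums the − call at p into the + call at p − 1.
* **Welch P values** are computed vectorized (nan-aware means/variances
  with Welch–Satterthwaite df) and match `scipy.stats.ttest_ind` to
  machine precision.

## Test and verification scales

Unit and acceptance tests run the generators at reduced scale chosen to
keep the statistics meaningful: null calibration uses ~2200 blocks per
seed over 10 seeds (binomial SE on a 1% rate is then ~0.2%, so a ±3 SD
check is informative); cluster recovery uses 5 planted 50-kb clusters
per seed over 10 seeds; array checks use 8000 probes with 50 planted
over 10 seeds. The acceptance script uses the same designs.

## Known limitations

* The chi-square on pooled counts ignores biological replication; with
  more than one sample per condition a beta-binomial or overdispersion
  correction would be preferable, but is out of scope because the
  implemented procedure *is* the pooled test.
* The mismatch filter's discordance definition is one documented reading
  of an underspecified rule; conclusions sensitive to it should be
  checked under both modes.
* The 450k module stops at per-CpG calls; its convenience interval
  grouping is not a substitute for dedicated array DMR callers.
* Amplification efficiency is assumed, not estimated from standard
  curves; melt-curve and amplification QC are out of scope.
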