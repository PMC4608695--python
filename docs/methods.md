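# Methods

This note records the models, estimators, defaults and design choices
behind `circaqpcr`, and what the synthetic-data validation does and does
not establish.

## Data model and QC

The raw observable is the replicate-level cycle threshold (Ct). Tables are
long-format CSV, one row per technical replicate, with sample metadata
(animal, group, Zeitgeber time, plate). Undetermined wells (no signal) are
parsed from a configurable token into NaN. Group labels are `naive`,
`epileptic`, plus two reserved labels: `calibrator` (the ΔΔCt calibrator
pseudo-sample) and `ntc` (no-template controls).

Technical replicates are averaged per sample × gene. A cell whose replicate
standard deviation exceeds a threshold (default 0.5 cycles, a common qPCR
QC heuristic) is *flagged but retained*, preserving the
mean-of-triplicates convention; undetermined replicates are excluded from
the mean, and a cell with no determined replicate is dropped and counted.
NTC policy defaults to "any determined Ct is a failure", with an optional
numeric bound for tolerating very late stochastic signal. QC is always
reported, never silently applied.

## Amplification efficiency

Standard curves regress Ct on log10 relative input (1/dilution factor)
by OLS; replicate dilution points enter as individual observations.
Efficiency is `E = 10^(−1/slope) − 1`, reported in percent with the
conventional 90–110% acceptance window (inclusive). A non-negative slope
yields an invalid-efficiency sentinel (NaN) rather than an exception, so a
mis-oriented series is visible but non-fatal. Comma-decimal exports are
supported in the reader.

## Relative quantification

Two normalizations, both assuming perfect doubling (base 2) by default:

* **delta-Ct**: per gene, `Q = 2^(minCt − Ct)` (lowest-Ct sample = 1).
  This is the input to both stability algorithms.
* **ΔΔCt**: `ΔCt_i = Ct_target,i − mean(Ct_ref,i)` over the reference
  genes, `ΔΔCt_i = ΔCt_i − ΔCt_cal`, `Q_i = 2^(−ΔΔCt_i)`.

With multiple reference genes the arithmetic mean of reference Cts is used;
at a common amplification factor this is identical to dividing by the
geometric mean of reference quantities, the standard multi-reference
convention. Whether the original workflow averaged Cts or normalized
quantities is not documented anywhere we could rely on; both satisfy the
calibrator-equals-1 identity, and the arithmetic-mean-of-Cts form is used
throughout. An efficiency-corrected base `(1 + E)` is exposed but off by
default. Reference genes are excluded from the output target set; samples
missing a reference gene are dropped with a warning; a calibrator missing
any gene is an error.

## Reference-gene stability

**geNorm.** `M_j` is the mean over partners `k ≠ j` of the sample standard
deviation (ddof = 1 throughout) of `log2(Q_j/Q_k)`. Ranking removes the
highest-M gene iteratively, recomputing M each round, until two genes
remain; those two are the best pair and are mutually unordered. Ties in the
maximum M are broken by removing the lexicographically last gene (the
original algorithm is silent; the tie-break is documented and tested).
Normalization factors `NF_n` are geometric means of the n most stable
genes; `V_{n/n+1} = sd(log2(NF_n/NF_{n+1}))`, and the recommended gene
count is the smallest n with `V < 0.15` (k − 1 if none).

**NormFinder.** On `y = log2 Q`, each sample is centred across genes
(removing the sample effect, hence exact invariance to global per-sample
shifts). Per group g with n_g samples and k genes, the naive per-gene
variance of centred data is bias-corrected via
`σ̂²_jg = (v_jg − Σ_l v_lg/((1 − 1/k)k²))/(1 − 2/k)` (negative estimates
truncated at 0), which inverts the expectation of the centring. Inter-group
deviations `d_jg` (gene-group means about the gene's overall mean) are
shrunk by the empirical-Bayes factor `τ̂²/(τ̂² + σ̂²_jg/n_g)` with
`τ̂² = max(0, Σ d²/((G−1)(k−1)) − mean(σ̂²/n))`. Stability is the mean over
groups of `|shrunk d| + sqrt(σ̂²_jg/n_g)`; without groups it reduces to the
bias-corrected residual sd. The best pair minimizes the analogous score for
the average of two genes, which lets opposite group biases cancel — the
defining advantage of the model-based approach. The grouping variable for
circadian designs defaults to the ZT label; groupless mode is available
since the original study does not state its grouping.

Published stability numbers from the motivating study (M range, V2/3,
NormFinder values) depend on its unreleased raw Cts and are treated as
decision-rule examples only; algorithm fidelity is enforced by exact
small-table oracles and by rank-recovery simulations instead.

## Rhythm detection

The single cosinor fixes the period at 24 h — the design is entrained
(12:12 LD), so a diurnal rhythm at the anticipated period is the estimand;
no period estimation is attempted. OLS on `[1, cos ωt, sin ωt]` gives
mesor m, amplitude `A = sqrt(b² + c²)` and acrophase
`Φ = atan2(c, b)/ω mod 24` (clock time of the fitted maximum, the ZT
convention used for all reported phases). The zero-amplitude test is
`F = ((TSS − RSS)/2)/(RSS/(n − 3))` on F(2, n − 3). 95% CIs: t interval
for the mesor; delta-method propagation of cov(b, c) with t quantiles for
amplitude and acrophase. Coverage of both CIs is asserted by simulation
(93–97% at amplitude/noise ≥ 3, n = 30). Fits default to all individual
animals (n = 30 for the naive design); per-ZT-mean fitting is an option
(`on_means`) since published curve fits are sometimes done on means.

Degenerate inputs are kept total: a constant profile returns amplitude 0,
F = 0, p = 1; a perfect non-constant fit (RSS ≈ 0 relative to scale)
returns a `degenerate` flag and a floor p-value instead of exactly 0, so
downstream logic never divides by a zero residual.

Harmonic regression adds (cos, sin) pairs of order 1, 2, 3 (24 h, 12 h,
8 h) while the added pair's partial F test is significant at α = 0.05,
then reports the overall F of the final model against the flat model;
`is_rhythmic ⇔ p < α`. Order 3 is the cap: higher harmonics are not
identifiable from a 6-point ZT grid.

Pairwise phase relations are signed circular differences in (−12, 12] h,
with an antiphase flag for |Δ| in [10, 14] h.

## ZT-stratified differential expression

For one epileptic ZT, each gene is compared against every naive ZT
separately by a two-sided pooled-variance Student t test on the linear
quantity scale (matching how such bar-plot comparisons are conventionally
run); Welch and Benjamini–Hochberg variants are available by flag, but raw
p-values with α = 0.05 are the default because that is the procedure under
study. Optional pooled comparisons use light = ZT{0,4,8} and
dark = ZT{12,16,20} per the 12:12 cycle. Classification per gene and
epileptic ZT: `consistent_up`/`consistent_down` require the same
significant direction against *every* naive ZT; `phase_dependent` requires
at least one significant comparison with non-identical outcomes; `null`
means nothing significant. Pooled comparisons are reported but excluded
from classification.

## Synthetic-data generator

The generator encodes the study design as its defaults: naive animals at
ZT 0–20 every 4 h (5 per ZT), epileptic animals at ZT8 and ZT12 (4 per
ZT), triplicate wells, six target genes and eight candidate reference
genes. Target profiles are cosines
`Q(t) = mesor + A·cos(2π(t − Φ)/24)` with the published parameters where
available — Per1 (A 0.469, Φ 16), Per3 (Φ 14.8), Bmal1 (Φ 2), Cry1
(Φ 17.6), Cry2 (A 0.201, Φ 7.6), Clock (A 0) — and amplitude 0.30 as a
declared stand-in for the three genes whose amplitudes were never
published (configurable, never used as an acceptance value). Mesors are
1.0 (unpublished; the ΔΔCt scale makes this the natural anchor).

Epileptic effects: all rhythmic genes are flattened at their mesor —
the minimal mechanism that reproduces the qualitative phase-dependent
outcomes (a flat epileptic group sits above the naive trough and below the
naive peak) — and Clock is down-shifted by 0.6 log2 units, producing the
consistent decrease. These are modeling choices, not measured effects.

Noise lives on the Ct (log2) scale, where qPCR measurement error is
approximately additive: a per-sample biological offset shared by all genes
of a sample (sd 0.15 cycles; RNA input / RT variation — exactly what
reference normalization removes), per-well reference-gene instability
(graded 0.02 → 0.30 cycles across the 8 candidates, most stable first so
that the expected best pair is the one the quantification normalizes to),
and technical replicate noise (sd 0.05 cycles). The defaults give the
cosinor power > 0.9 at the smallest published amplitude (0.201) with
n = 30, while leaving the stability ranking a genuinely noisy inference
problem. Multiplicative (log-normal) noise inflates linear-scale means by
`2^(ln2·σ²/2)`; at the default sds this bias is ≪ 1% and is asserted
numerically in the tests.

The calibrator pseudo-sample has true quantity exactly equal to each
gene's mesor and is emitted *without* noise: it is a conceptual anchor
rather than a physical well, and a noisy calibrator would impose a common
per-panel scale factor that no amount of animal averaging removes.

What the generator deliberately omits: plate/batch effects beyond a single
shared calibrator, amplification-efficiency differences between genes,
gene–gene correlation in reference instability, non-sinusoidal waveforms,
and any epileptogenesis dynamics. Passing tests therefore show that the
estimators recover truth under an idealized but realistically noisy
qPCR model — not that real hippocampal data meet these assumptions.

## Validation studies and problem sizes

* Rhythm parameter recovery: 200 simulated naive panels per study
  (`scripts/acceptance.py`, ~30 s); circular-mean acrophases and mean
  amplitudes are compared to the generating values.
* Clock false-rejection rate over the same 200 panels (≈ the 0.05 test
  level, since its amplitude is 0).
* Type-I error of the zero-amplitude test: 10,000 flat-profile
  simulations at n = 30.
* CI coverage: 2,000 simulated profiles at amplitude/noise = 3.
* Stability rank recovery: 100 seeded panels. Adjacent instability grades
  (0.04 cycles apart) are ~1 estimation-sd apart at 30 animals, so exact
  full-order recovery is not a meaningful target; recovery is asserted as
  pairwise concordance with the true ordering (≥ 95%, outside the
  unordered best pair), best-pair recovery (≥ 95%), and NormFinder rank
  correlation with the true sds (mean Spearman ≥ 0.9).
* Phase-sensitivity labels: 100 seeded panels; Clock `consistent_down`
  and Per1 `phase_dependent` in ≥ 90%.

All simulation studies derive their per-panel seeds from a single base
seed via `numpy.random.SeedSequence`, making every reported number
reproducible bit-for-bit.

## Known limitations

* Inter-plate calibration is reduced to a shared calibrator sample; no
  plate-geometry or batch modeling.
* Efficiency-corrected quantification uses a single common base; the
  Pfaffl model with gene-specific efficiencies is out of scope.
* The NormFinder estimator follows the published variance-components
  model; numerical agreement with any specific third-party implementation
  is not asserted, only the model's invariances and recovery behaviour.
* Acrophase CIs are delta-method intervals and degrade near zero
  amplitude, where the phase is unidentifiable; the zero-amplitude test,
  not the phase CI, is the rhythm decision rule.
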