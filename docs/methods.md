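# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators emulate,
and the limits of what the tests demonstrate.

## Expression processing and differential expression

**Quantile normalization.** Each column of the gene × sample log2-intensity
matrix is replaced by the across-column means of the order statistics,
assigned by within-column rank. Ties receive the mean of the target values
for the ranks they jointly occupy, which makes the operation deterministic
and exactly idempotent. Missing values are rejected rather than imputed.

**Technical replicates** are averaged arithmetically into one column per
biological sample before any model fitting. Metadata within a replicate
group must agree exactly; conflicts are errors, not warnings, because a
silent collapse would mis-assign covariates.

**PCA** is computed by SVD of the per-gene-centered matrix, without
scaling: log2 expression values are already on a comparable variance
scale, and scaling would up-weight near-constant probes. Variance
fractions are singular-value energies over the total. The sign of each
component is fixed by making its largest-magnitude gene loading positive,
so results are fully reproducible.

**Differential expression** fits, per gene, an ordinary least-squares
linear model of log2 expression on a group indicator plus dummy-coded
covariates (sex, disease status, and a fixed-effect indicator per
twin/clone pair). The reported effect is the group coefficient (a log2
fold change) with a two-sided t-test; p values are BH-adjusted across
genes. An optional moderated mode shrinks per-gene residual variances
toward their global mean with a prior of 4 degrees of freedom — a simple
empirical-Bayes stabilization for very small designs. The default is
plain OLS because it is exactly calibrated under the generator's Gaussian
noise (the test suite verifies ~5 % of raw p values below 0.05 under the
null) and exactly recoverable on noiseless fixtures. The test suite also
cross-checks the fit against limma (R): coefficients and ordinary-t
p values agree to 1e-8. Full moderated-limma equivalence is not claimed.

**DEG selection** uses strict inequalities: |log2FC| > 1 and adjusted
p < 0.05, both configurable. A gene at exactly the threshold is excluded.

**Degenerate variances.** When residual variance is exactly zero (possible
on noiseless synthetic data), a nonzero effect is assigned p = 0 and a
zero effect p = 1, instead of propagating 0/0.

**Marker panels** (pluripotency core POU5F1/NANOG/SOX2, germ-layer and
fibroblast markers) are tested per gene by one-way ANOVA with Tukey HSD
post-hoc. Genes absent from the matrix are reported as missing rather
than raising, since marker panels are curated independently of the
platform's gene coverage.

## Interaction networks and the PIE score

The reference network is the union of per-category edge lists over gene
symbols (categories: physical, predicted, shared_domain, colocalization,
pathway). Duplicates within a category are dropped, self-loops removed
with a logged count, and a pair present in several categories becomes one
combined edge carrying all its category tags. Modules are connected
components of the combined network, ordered by descending size and then
by lexicographically smallest member; components below `min_size`
(default 2) are reported as singletons.

**PIE.** The score of a query set Q against a background network is

    PIE(Q) = E_obs(Q) / (1/B) Σ_b E(S_b)

with E_obs the number of (optionally category-filtered) edges internal to
Q, and S_b uniform node samples of size |Q| drawn without replacement
from the background node universe, B = 10,000 by default. The p value is
the add-one empirical tail (1 + #{E_b ≥ E_obs}) / (B + 1), so its floor
is 1/(B+1) and it can never be exactly zero. The sampling universe is the
node set of the supplied background network; it is an input, not a
constant, so a genome-scale interactome can be substituted. A
degree-matched stratified null (sampling within degree-decile bins
matching the query's profile) is available but off by default: the
number-matched null is the primary definition, and degree matching is a
stricter robustness check. When the null mean is zero the score is
reported as infinite (observed > 0) or 1 (observed = 0) with a
`degenerate_null` flag.

Per-direction and per-category results (`pie_report`) derive their
bootstrap sub-seeds from the *content* of each gene set, so identical
sets produce identical rows wherever they appear in the table.

The bootstrap is validated three ways in the tests: exhaustive
enumeration of all node subsets on networks of ≤ 12 nodes (null mean and
tail probability within 3 Monte-Carlo standard errors), uniformity of the
empirical p under random queries (3–7 % of 500 null queries at p ≤ 0.05),
and planted-structure recovery (an 8-clique in a sparse background
attains the minimum attainable p).

## Over-representation analysis

Plain upper-tail hypergeometric tests per term: P(X ≥ overlap) with
population |universe|, successes |term ∩ universe|, draws |query|, BH
correction across terms. The universe is a required explicit argument —
typically all genes on the expression platform — because enrichment
p values are meaningless without a stated background. No combined-score
or rank aggregation beyond this is implemented, and no GO-DAG
propagation: terms are flat sets.

## Ca²⁺ trace analysis

Traces are uniformly sampled fluorescence series (the targeted
acquisition is 15 min at 0.5 Hz). ΔF/F uses F0 = 10th percentile of the
full trace by default (median/mean variants provided); the percentile
baseline is robust to sparse transients while remaining deterministic.

**Noise scale** is estimated as 1.4826 × MAD of the first differences
divided by √2 — first-differencing removes slow drift, and the MAD keeps
the transients themselves from inflating the estimate.

**Detection.** Peaks must exceed the trace median by k·σ (default k = 3)
*and* have prominence of at least k·σ; the prominence requirement stops
noise ripples riding on a slowly decaying shoulder from registering as
separate events. Peaks closer than `min_separation_s` (default 4 s, two
samples at 0.5 Hz) merge to the larger one. Onset is the last sample at
or below 20 % of peak amplitude before the peak; fall time ends at the
first sample at or below that level after the peak. Falls that never
recross before the next event or the trace end are right-censored,
flagged, and excluded from kinetic means. With a linear rise the 20 %
convention recovers grid-aligned rise times exactly; for an exponential
decay with constant τ the measured fall time is τ·ln 5, which the tests
use as the analytic reference.

**Stimulus response.** A ROI responds to a depolarization stimulus when
its post-stimulus maximum within the response window (default 60 s)
exceeds the pre-stimulus median by k·σ of the pre-stimulus segment.

**Group tests.** Two groups: Mann–Whitney U. More: Kruskal–Wallis with
Dunn's rank-based pairwise post-hoc (pooled ranks, standard tie
correction, Bonferroni adjustment by default; BH optional). Dunn's test
is implemented in-package because no installed library provides it.
All-tied data returns p = 1 with a note instead of failing. Significance
stars follow the usual convention (*, **, ***, **** at 0.05, 0.01,
0.001, 0.0001).

## qPCR quantification

ΔCt = mean target Ct − geometric mean of the reference-gene Cts (default
GAPDH and TBP) per sample, with technical replicates averaged first.
ΔΔCt = condition-mean ΔCt − control-mean ΔCt; relative expression is
2^−ΔΔCt, assuming factor-2 amplification per cycle (no efficiency
correction). The default compares condition means; a per-sample mode
exponentiates before averaging, preserving replicate spread for group
tests. With constant reference Cts the whole chain is exactly invariant
to adding a constant to every Ct; with noisy references the geometric
mean makes this only approximate, which is why the invariance test uses
the noiseless fixture.

## Synthetic-data generators

Every generator is a pure function of its config including the seed;
per-gene/per-ROI sub-streams come from `SeedSequence` spawn keys, so
enlarging a fixture does not perturb existing entries.

* **Expression studies:** log2-scale Gaussian intensities (baseline
  ~N(8, 1.5) per gene), culture-condition groups with per-sample sex and
  disease covariates, technical replicates, and optional clone/twin pairs
  sharing a donor effect of SD `donor_sd` (default 0 — the magnitude of
  within-donor correlation in real PSC panels is not established, so it
  is exposed rather than fixed). DE genes get a ±`de_log2fc` shift in
  the second group, half up and half down. Defaults (2000 genes, 8
  samples/group, 100 DE genes at |log2FC| = 2, noise SD 1) give a study
  where selection recovers most planted genes while FDR control is
  non-trivial. Probe-level bead-array effects, batch chips and scanner
  artifacts are *not* simulated, so passing tests show correctness of
  the statistical chain, not robustness to platform artifacts.
* **Networks:** per-category Erdős–Rényi backgrounds; inside the planted
  set the first category's edge probability is `planted_edge_prob`
  *instead of* the background value, so planted = background is a true
  null and planted = 1 on an empty background is exactly one clique.
* **Annotation databases:** random term sets within the universe plus
  exact planted terms.
* **Traces:** transient onsets from a Poisson process; each event is a
  linear rise to peak over `rise_s` followed by exponential decay with
  constant `decay_s` — a shape chosen because it makes rise/fall-time
  recovery analytic; real Ca²⁺ transient waveforms vary. Defaults mirror
  the targeted acquisition (900 s at 0.5 Hz, amplitude 0.8 ΔF/F, rise
  4 s, decay 10 s). Stimulus-locked events of amplitude
  `stim_amplitude_dff` go to a `responder_fraction` of ROIs.
* **Ct tables:** reference genes at fixed Cts, targets at base −
  log2(fold), so noiseless recovery is exact by construction.

## Problem sizes in tests and the acceptance script

Stochastic checks use sizes chosen to make their calibration bands
informative at interactive runtimes: 20 seeds × 800 genes for FDR, 500
null queries at B = 2000 for PIE calibration, B = 10,000 wherever a
single PIE score is compared to enumeration or a planted construction,
100–200 ROIs for Poisson-rate and responder-fraction recovery. These are
the package's standard verification conditions; all of them complete in
well under a minute each on one CPU.

## Known limitations

* No probe→gene collapsing, idat import, or PluriTest scoring; the
  expression pipeline starts from a gene × sample matrix.
* PIE is defined here as observed-over-expected internal edges under
  number-matched resampling; other published enrichment scores normalize
  differently (e.g. by degree), which the optional degree-matched mode
  approximates but does not replicate.
* The transient detector is a threshold/prominence peak finder, not a
  template-matching method; equivalence with template-based packages is
  not claimed, and printed statistics from such tools are not
  reproduction targets.
* Enrichment p values depend strongly on the chosen universe; results
  are only comparable across runs using the same universe.
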