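# Methods

This note documents the models behind `replidose`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Replication dosage model

For a circular chromosome replicated bidirectionally from a single
origin in steady-state exponential growth, the expected copy number of
a locus at relative replication distance *d* ∈ [0, 1] along its arm is

> dosage(d) ∝ 2^(c·(1−d)),  c = C/τ,

where C is the time a fork needs to traverse the arm and τ the
doubling time. c = 0 is stationary phase (flat profile); c = 1 means
the origin region is present at exactly twice the terminus copy
number. The identity follows from integrating locus copy number over
the steady-state cell-age distribution 2·ln2·2^(−a); the test suite
confirms it against a brute-force per-cell fork-position simulation.

**Co-termination.** Secondary chromosomes of multi-chromosome bacteria
initiate late so that all replicons finish replication together. With
equal fork speeds this fixes the secondary's effective exponent to
c·(arm₂/arm₁); for a 3.0 Mb / 1.07 Mb pair at c = 1 the secondary's
ori:ter ratio is 2^(1.07/3) ≈ 1.28 and the two ter-proximal dosages
coincide. The initiation delay is recovered from data as the
difference of fitted log2 apex heights on the jointly normalized
profile (times τ for minutes).

**Terminus.** No ter annotation is assumed; it is defined as the point
where the two replication arms meet (antipodal to ori under equal fork
speeds).

## The synthetic-data generator

The generator produces exactly the inputs the analysis consumes, with
ground truth attached. Defaults are the study conditions used
throughout the test suite:

| parameter | default | rationale |
|---|---|---|
| replicons | 3.0 Mb + 1.07 Mb, circular | a two-chromosome *Vibrio*-like genome |
| c_over_tau | 1.0 | fast growth, one overlapping round |
| co_terminate | true | secondary-chromosome timing |
| total_reads | 2×10⁶ per phase | ≈ 500 read starts per 1 kb window |
| dispersion | 0.02 | typical extra-Poisson spread of window counts |
| window_bp | 1,000 | the finer of the two standard window sizes |
| competition generations | log2(400) ≈ 8.64 | a 1:400 dilution regrown to saturation |
| events_per_read | 30,000 | standard cytometer acquisition |

**Count noise.** Counts are multinomial draws of `total_reads` over
windows. With dispersion α > 0 each window's weight is multiplied by a
gamma(1/α, α) bias factor, giving marginally negative-binomial counts
with variance m + α·m². The bias factor is *shared between the
exponential and stationary libraries* of a dataset: it models
window-specific capture bias (mappability, GC, fragmentation), which
is reproducible between libraries prepared against the same reference
— and which is precisely what the stationary normalization exists to
cancel. Sampling noise itself is independent per phase. Under this
structure the normalized profile carries ≈ √(2/m) per-window noise on
the natural-log scale; had the overdispersion been drawn independently
per phase instead, no estimator could localize the origin better than
σ/(b√n) ≈ 8–14 kb at the default depth, and the recovery the tests
demonstrate would be unattainable.

**Other simulators.** Kinetic curves are logistic
(baseline + A/(1+e^(−r(t−t_mid)))) with Gaussian reader noise; the
`lag` argument is the logistic midpoint. Collapsed-repeat artifacts
multiply observed counts in both phases (composing multiplicatively
when overlapping). Deletions zero the expected dosage (reads mapped to
a reference that lacks the region); the mean-1 normalization of the
expected profile is taken over non-deleted windows. Competition
assays draw initial and final strain compositions binomially from the
true proportions at 30,000 events and rescale final counts by the
total co-culture expansion: the fitness formula compares log
fold-changes of *absolute* abundances, and fixed-total cytometry
proportions alone do not carry that information (applied to raw
proportions the formula does not estimate 1+s at all). Kill curves
are biphasic exponentials with Poisson-sampled CFU.

**What the generator does not emulate:** read-level artefacts (GC
bias along the fragment, PCR duplicates, mapping errors beyond the
window-level bias factor), replication-transcription conflicts, fork
stalling, sub-exponential or shifting growth, plate-reader drift and
edge effects, cytometry gating errors. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every pathology of real libraries.

## MFA estimation

**Normalization** (per window, all replicons jointly):
factor_i = stat_i / mean(stat over included windows);
corrected_i = exp_i / factor_i; frequency_i = corrected_i /
mean(corrected over included). Joint (rather than per-replicon)
rescaling preserves the relative dosage of the two chromosomes, which
the initiation-delay estimate needs. The "deviation" of the stationary
sample is taken as a ratio, not a difference: only a ratio cancels
multiplicative mapping bias. Windows with zero stationary counts, and
partial trailing windows, are excluded with reason tags.

**Repeat exclusion.** A window whose stationary count deviates from
the stationary mean by more than a factor of two (|log2| > 1) is
tagged `repeat-like` and the profile is re-scaled to mean 1. The
threshold is deliberately generous: under pure counting noise at ≥ 500
expected reads per window the false-exclusion probability is < 10⁻⁶,
and at the default overdispersion (α = 0.02) it is ≈ 2×10⁻⁵ — about
0.09 clean windows per 4,070-window genome, harmless to the fit. A
mappability mask can be supplied instead where multi-mapping
information exists.

**Inverted-V fit.** The log2 profile is fitted with a continuous
piecewise-linear V: apex (ori) height shared by both arms, arm slopes
sign-constrained (ascending left, descending right), arms closed at
the terminus where the two lines cross on the far side of the circle
(window–arm assignment iterated to the crossing). Continuity and
closure matter: with free per-arm intercepts the total squared error
is almost flat in the apex position (only the kink region, ∝ δ³,
informs it) and apex errors reach tens of kb; the closed V restores
the full shift information. The apex is grid-searched exhaustively
over included window midpoints — arm counts are small enough that
exactness beats iterative optimization — scoring by default the
*symmetric* V (equal |slopes|, terminus antipodal, i.e. equal fork
speeds), which pins both arms and halves the apex standard error
again; slopes are then refit freely at the winning candidate. Set
`symmetric_apex=False` for genuinely asymmetric arms. Ties in the
grid are broken towards the annotated origin, else the lowest
coordinate.

At the default depth this recovers the origin with ≈ 2–3 kb median
error, the ori:ter ratio within a fraction of a percent, and the
initiation delay within a few percent (20-seed medians in the test
suite).

**No-gradient guard.** If both refit arm slopes are below
`slope_floor` (default 0.05 log2/Mb — an order of magnitude below the
≈ 0.67 log2/Mb of fast growth, an order above typical noise slopes),
the profile is declared gradient-free: ratio 1, no origin invented.
On pure-noise data the guard triggers ≈ 90–95% of the time per
two-chromosome dataset; the occasional miss comes from
selection-biased slopes on the smaller chromosome and reports a ratio
within ~2% of 1.

**Gaps and slope breaks.** Deletion candidates are maximal runs of
≥ `min_run` (default 5) zero-count exponential windows, annotated with
whether the stationary phase is also empty (a true missing region vs a
phase artifact). Slope breaks are sliding-span local slopes deviating
from the fitted arm slope by more than `severity_threshold` in units
of the arm slope's standard error, apex spans excluded; because local
slopes are far noisier than the arm slope, the default threshold of 5
is meaningful for smoothed (10 kb) or low-noise profiles — on raw 1 kb
profiles at default noise it will fire liberally, and larger spans or
thresholds should be used. Windows inside detected gaps never reach
the fit (zero frequencies are excluded before the log transform, so no
pseudocount is needed).

## Phenotype microarrays

AUC is the trapezoid of the kinetic trace, by default after
subtracting the well's first reading (plate-reader convention; the raw
integral is a switch away, since dye chemistry sometimes argues for
it). Replicates (≥ 2 per strain, as assays are run in duplicate)
give mean, sd and se per strain. The difference flag requires (i)
ratio of means ≥ 2 and (ii) |mean_wt − mean_mut| > e_wt + e_mut, the
exact condition for the axis-aligned error cross to miss the bisector
(verified against a geometric oracle). Whether e is sd or se is a
user choice (`error_bar`, default `sd`): both conventions circulate
and the flag is sensitive to it, so the package refuses to resolve the
ambiguity silently. No multiple-testing correction is applied in the
flag — it is a screening rule whose hits are meant for experimental
verification, and correcting would change its published semantics.

## Fitness, growth, expression, survival

* **Vmax** is the maximum least-squares slope over sliding windows of
  5 consecutive readings (proprietary reader software does something
  equivalent but undocumented; a reproducible definition replaces it).
  5 points ≈ 1 h at 15 min sampling: short enough to track the
  exponential phase, long enough to average reader noise.
* **Fitness** is computed per assay and aggregated as mean ± sd across
  biological replicates. Zero counts and an unchanged tagged
  reference are errors, not NaNs.
* **ΔΔCt**: 2^(−ΔΔCt) with ΔCt = Ct(target) − Ct(reference gene),
  sample vs control condition; gene identity is checked.
* **Survival**: fractions vs t0 per replicate; a replicate reaching
  zero CFU is censored at the plating detection limit (default
  10 CFU/ml ≈ 100 µl of undiluted culture plated) and reported as
  "at least" that reduction.
* **Endpoint tests**: unpaired two-sided t (2 groups, pooled
  variance) or one-way ANOVA (≥ 3); all-identical observations return
  p = 1 rather than 0/0; batch mode attaches Benjamini–Hochberg
  adjusted p-values.

## Numerical and I/O conventions

* Coordinates 0-based half-open throughout; GenBank's 1-based closed
  coordinates converted at the boundary; circular arithmetic modulo
  length with signed ori offsets in (−L/2, L/2], the antipode mapping
  to +L/2.
* Profile means are restored to 1 ± 1e−9 after every exclusion pass;
  scale and shared-bias invariance of the normalization hold to
  1e−12/1e−9 and are property-tested.
* TSV output uses 12 significant digits (lossless round-trip at that
  precision); JSON reports are key-sorted so identical configs yield
  byte-identical artifacts.
* Slope-break severity divides by max(SE, 1e−9·max(1, |slope|)) so a
  numerically perfect fit cannot turn rounding error into infinite
  severity.
* All simulators are pure functions of their arguments including the
  seed (numpy `default_rng`).

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the full two-chromosome
genome at 2×10⁶ reads per phase and 1 kb windows — 4,070 windows per
dataset — with 10–20 seeds per property, 100 simulated competition
assays per selection coefficient, 10–20 simulated 96-well PM plate
sets, 10⁴ random flag-geometry configurations, 2×10⁶ windows for the
false-exclusion bound and 5,000 null datasets for the t-test
calibration. These sizes give comfortable statistical resolution for
every tolerance tested while keeping a full run in the low minutes on
a single CPU.

## Known limitations

* The MFA fit assumes a single bidirectional origin per replicon and
  piecewise-log-linear dosage; multi-origin plasmids, fork stalling
  or runout protocols are out of scope.
* The default symmetric apex search slightly biases the origin
  estimate if fork speeds are truly unequal (use
  `symmetric_apex=False` there, at the cost of localization power).
* The repeat filter is a statistical proxy; genuinely duplicated
  regions whose stationary coverage happens to stay within two-fold
  will pass it.
* `detect_slope_breaks` reports signals, not breakpoint coordinates
  with confidence intervals; it is a screening aid.
* The PM flag inherits the arbitrariness of its two-fold rule; with
  duplicates the sd-based error cross is a rough instrument, and hits
  are to be verified experimentally.
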