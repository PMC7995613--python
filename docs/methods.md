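# Methods

## The flip model and its algebra

At saturating agonist, binding steps are complete and gating reduces to

```
resting (R)  <-- gamma / delta -->  flipped (Fl)  <-- alpha / beta -->  open (O)
```

with equilibrium constants `F = delta/gamma` (flipping) and
`E = beta/alpha` (opening).  The equilibrium open occupancy among the three
active states is `E·F/(E·F + F + 1)`, which factors as `Eff/(Eff + 1)` with
`Eff = E·F/(F + 1)` — formally the same saturation curve as the two-state
del Castillo–Katz scheme, with `Eff` playing the role of the single gating
constant.  All algebra in `chanpopen.mechanism` is exact and returns full
precision; rounding (two significant figures for `Eff`, two or three
decimals for P_open) happens only at the presentation layer
(`report.round_sig`), matching how such values are conventionally
reported.

Boundary open probabilities (exactly 0 or 1, which short clusters can
produce) are rejected by `eff_from_popen` rather than clamped: the
inversion `p/(1−p)` is undefined there, and clamping would bias group
means.  Group efficacy is computed as the mean of per-cluster P_open values
first, then inverted — not as a mean of per-cluster `Eff` — because the
mapping is nonlinear and cluster means are the field's reporting unit.

## The synthetic-data generator

The simulator adds a desensitized state `D` to the flip scheme, entered
from the open state at `d_plus` and left to `R` at `d_minus`.  Because
`d_plus` (2 s⁻¹) is orders of magnitude below the closing rate and
`d_minus` (0.25 s⁻¹) is slower still, activity appears as clusters of
openings lasting ~0.5–1 s separated by ~4 s silent periods — the structure
cluster analysis exploits.  Entering desensitization from the open state is
a modelling choice: only the cluster phenomenology, not the pathway, is
constrained by single-channel observations, and a single `D` state is used
although real desensitized sojourns are better described by several
long-lived states.  With desensitization entered from `O`, open sojourns
are exponential with mean `1/(alpha + d_plus)`; the stationary open
fraction among active states differs from `E·F/(E·F+F+1)` only at
`O(d_plus/alpha)` ≈ 0.1%, far below measurement noise (the test suite
checks both the perturbed value via an eigenvector oracle and the exact
`d_plus → 0` limit).

The equilibrium constants fix only rate ratios.  Backward rates anchor the
time scale: `gamma = 1,000 s⁻¹`, `alpha = 2,000 s⁻¹` by default, placing
open and shut dwells in the tens of µs to ms range so that they are
resolvable — though not fully — after 3 kHz filtering.  All rates are
overridable.

Simulation is an exact trajectory simulation of the continuous-time Markov
chain (exponential sojourns, successors proportional to outgoing rates),
started in `D`.  Rendering follows the acquisition chain: piecewise-
constant current sampled at 100 kHz, convolution with a truncated
(±4σ, renormalized) Gaussian kernel parameterized by its −3 dB cutoff
(σ_t = 0.1325/fc; 3 kHz default), decimation to 33.3 kHz, then additive
white Gaussian baseline noise (0.5 pA SD default).  Full openings render at
5 pA; 2% of openings are tagged as ~1 pA subconductance events, emulating
the rare partial-amplitude openings seen in ICD-modified receptors.  One
master seed fans out deterministically (via `numpy.random.SeedSequence`
spawning) to the chain, subconductance and noise streams, so identical
configurations are bit-reproducible.

The whole-cell generator produces per-cell application tables: a 10 mM
glycine standard first and last and after every third test application,
test concentrations following Hill curves with human-α1-GlyR-like defaults
(glycine EC50 240 µM/n_H 1.57, β-alanine 0.73/860/1.5, taurine
0.25/2000/1.30, GABA 0.017/61000/1.32 as (I_rel, EC50 µM, n_H)), a
log-normal per-cell maximal current (13.2 nA mean, 30% CV), multiplicative
log-normal response noise (10% CV default) and a linear run-down across the
application sequence (10% default; configurable to construct cells that
violate the QC rule).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: baseline drift and seal instability, multi-channel
patches, agonist-concentration-dependent binding kinetics, correlated
(filtered) instrumentation noise, solution-exchange artefacts, and
multi-state desensitization.  Recovery results on synthetic data
demonstrate the correctness of the analysis chain, not robustness to these
real-world complications.

## Idealization

Threshold crossing at 50% of the full open amplitude (the half-amplitude
criterion) after optional Gaussian filtering; crossing times are linearly
interpolated between bracketing samples to reduce quantization bias at
33.3 kHz.  Amplitude can be estimated from the all-points histogram: the
dominant smoothed mode is the shut baseline, and the most populated
secondary mode that is both ≥10% of the data range away and separated by a
valley dipping below half its height is the open level; records failing
this bimodality test require an explicit amplitude.

A dead time of 60 µs (≈0.18/fc at 3 kHz) is imposed symmetrically on open
and shut dwells: scanning left to right, any dwell shorter than the dead
time is absorbed into its neighbours (an interior short dwell merges its
flanking pair into one dwell of their shared class), repeating until
stable.  Total duration is conserved exactly.  Filter rise time
(0.3396/fc ≈ 113 µs at 3 kHz) means sub-rise-time events may fail to reach
threshold at all; at intermediate P_open these misses are roughly balanced
between open and shut classes, which is why pipeline recovery lands within
~0.01 of the generating value rather than exactly on it.  Subconductance
events (~1 pA against a 2.5 pA threshold) are classified as shut by
construction; `subconductance_fraction` provides a diagnostic that counts
sample runs in a 0.5–2 pA band lasting at least the dead time.

## Cluster analysis

Shut or desensitized intervals ≥100 ms split the record; candidates are
trimmed to run from their first opening to their last closing (so a fully
open cluster can reach P_open = 1), and only clusters strictly longer than
100 ms are accepted.  Ties break conservatively: a gap of exactly 100 ms
splits, a cluster of exactly 100 ms is rejected.  P_open is open time over
trimmed duration.  Summaries report mean ± SD over clusters (patch counts
carried as metadata), quartiles by linear interpolation between order
statistics (type-7, the convention of common plotting software) and
whiskers at the most extreme points within 1.5·IQR of the quartiles.

## Dose–response analysis

Cells pass QC when |last − first| standard response is below 30% of the
first.  Responses are normalized to the standard interpolated linearly in
application order between bracketing standards (dividing out slow
run-down; the interleaving protocol motivates interpolation, though no
particular correction rule is canonical).  Hill fits are unweighted
nonlinear least squares (`scipy.optimize.curve_fit`) with initialization
y_max = max response, EC50 = log-interpolated half-max concentration,
n_H = 1.5, and bounds n_H ∈ [0.2, 10], EC50 within two decades of the
tested range; fits pinned at bounds or with undefined covariance are
flagged rather than silently accepted, and n_H/y_max are otherwise
unconstrained.  For pooling, each cell's responses are divided by that
cell's fitted maximum and the pooled points refitted — the display-oriented
two-stage procedure standard for heterogeneous cell sizes.  I_rel is the
fitted maximum on the standard-normalized scale, i.e. I_agonist/I_glycine
within the same cell.

## Randomization statistics

The two-sample comparison uses the absolute difference of group means as
statistic (the test family leaves the statistic open; the mean difference
is the simplest choice and the absolute value gives a two-tailed test) and
permutes group labels without replacement.  When the number of distinct
assignments C(n, n_A) is within the iteration budget the test enumerates
them all and reports the exact tie-inclusive p; otherwise it draws 10,000
Monte-Carlo assignments and applies the add-one convention
p = (count + 1)/(n_iter + 1), which cannot report p = 0.  Comparisons
across agonist/construct pairs use the Bonferroni-style per-test threshold
alpha_family/n_comparisons; the default 0.05/10 = 0.005 corresponds to the
ten pairwise comparisons natural to a four-agonist, multi-construct study.
The sampling unit is the cluster (matching how group sizes are reported),
with optional patch-level aggregation.  Calibration is verified directly:
under an exact null the empirical rejection rate at 0.005 matches the
nominal level within binomial error.

## Problem sizes and numerical choices

The pipeline-recovery computations simulate 300–500 s of single-channel
recording (50–90 accepted clusters, ~10⁵ dwells, ~10⁷ trace samples),
which makes the cluster-mean standard error a few thousandths of a P_open
unit while keeping each run in seconds.  Null calibration uses 1,000
replicates of n = 10 + 10 with 2,000 permutations each.  Dwell-boundary
sample alignment rounds cumulative times (not durations) to the sample
grid, so rendering introduces at most one sample of jitter per transition
without accumulating drift.  Tolerances asserted in tests derive from
analytic standard errors (2–3 SE) or closed-form filter properties, not
from tuning.

## Known limitations

- The idealizer is a plain half-amplitude detector; it has no missed-event
  correction, so recovered P_open carries a small (≈1–2% here) bias that
  grows as dwell durations approach the filter rise time.
- The flip algebra covers saturating agonist only; concentration-dependent
  activation (binding steps) is out of scope.
- `Eff` estimation treats the mechanism as agonist-wise independent; no
  global fit of rate constants to dwell distributions is attempted.
- Cluster segmentation assumes one active channel per cluster; overlapping
  channels are not detected.
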