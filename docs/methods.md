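# Methods

## Model

`txnsim` simulates transcription at a single gene copy in a prokaryotic
cell, tracking every mRNA molecule at submolecular resolution.

**Promoter.** A two-state telegraph switch: the gene activates at rate
`k_on` (1/min) and deactivates at `k_off` (1/min). While active, polymerases
initiate at `k_ini` (1/min). Rates are time-homogeneous except for the
scheduled step changes of `k_on` that model induction/repression
experiments.

**Elongation.** A transcript of gene length `L` (nt) is synthesized in `N`
discrete steps of length `L/N` nt. Each step is an independent exponential
event at the per-molecule step rate

    r_step = v_el * 60 * N / L   (1/min),

so the mean traversal time of the gene is `N / r_step = L / (v_el * 60)`
minutes with a coefficient of variation `1/sqrt(N)`. The elongation speed
`v_el` is supplied in nt/s (its customary unit) and converted exactly once
on ingestion; all internal computation is in minutes. Completing a
transcript takes exactly `N` step events: a new molecule occupies step 1 at
initiation, `N-1` events extend its 3' end, and the final event releases it
from the locus (clears its polymerase-bound flag). A nascent molecule whose
3' index has reached `N` is "release pending" until that last event fires.

**Degradation.** An RNase binds the 5'-most intact step of any molecule —
nascent or mature — at rate `k_deg` (1/min) per unbound molecule; at most
one RNase per molecule. A bound molecule is consumed 5'→3' in steps at the
same rate `r_step` (the model assumes degradation proceeds at the average
elongation speed), so degradation can chase an still-elongating transcript
(co-transcriptional degradation). When the last intact step is consumed the
molecule — and, if nascent, its polymerase — is removed. The degradation
front never overtakes the elongation front: the consuming event that would
empty a nascent molecule's span removes it instead.

**State.** Each molecule is four numbers: 5'-most and 3'-most intact step
indices (1-based, inclusive) and two Booleans (polymerase-bound,
RNase-bound). The cell adds the time and the gene Boolean. Propensities
depend on the state only through the gene Boolean and the counts of
nascent, unbound and degrading molecules, which is what makes the compiled
event loop O(1) per channel selection.

**Probe signal.** Fluorescent oligo probes cover the fraction `[P5, P3]` of
the gene. A step is probe-covered iff its midpoint lies in `[P5, P3]`
(binary per-step coverage; sub-step weighting is not modeled, consistent
with the discrete state space). A molecule's signal is the covered fraction
of its intact span divided by the probe's total coverage, so a fully intact
molecule scores exactly 1 — the readout is in molecule equivalents. Signals
are reported per cell in three channels: nascent (polymerase-bound),
mature (released), total = nascent + mature.

## Simulation engine

The engine is an exact Gillespie algorithm: no tau-leaping, no hybrid
approximations. Piecewise-constant `k_on` schedules are handled by
restarting the clock at each boundary, which is statistically exact because
all waiting times are exponential. Two implementations exist and are tested
against each other: a pure-Python reference built from explicit
`propensities` / `draw_next_event` / `apply_event` operations (also the
path that exposes molecule-level snapshots), and a numba-compiled kernel
used for ensembles (~10^6 events/s on one core).

**Protocols.** Turn-on: empty cell, gene off, `k_on` steps up at t=0.
Turn-off: the steady-state initial condition is realized by simulating an
empty cell under the pre-step parameters for a burn-in placed at negative
times, so the step down lands at t=0. The default burn-in is ten times the
slower of `1/k_deg` and the traversal time; adequacy is checked by a
doubling test (doubling the burn-in leaves the signal distribution
statistically unchanged).

**Reproducibility.** Every cell's random stream derives from
`SeedSequence(seed, spawn_key=(cell_index,))`, so an ensemble is
byte-identical for any worker count and execution order. The kernel
releases the GIL; thread workers give real parallelism on independent
cells.

**Limits checked against independent oracles.** With `N=1` and a step rate
far above all kinetic rates, the count of RNase-unbound molecules is
exactly the two-state telegraph birth-death process (binding is the death
event); its stationary law is compared against a truncated master-equation
solve (itself validated against the closed-form confluent-hypergeometric
expression). With the promoter effectively always on, the stationary count
is Poisson (Fano factor 1).

## Summary statistics and distance metrics

Histograms of per-cell signals use unit-width bins anchored at 0 (signals
are molecule equivalents); the bin width is configurable. The distance
between two histograms on a shared grid is the sum over bins of the
absolute CDF difference times the bin width — for one-dimensional
distributions this equals the Wasserstein (earth mover's) optimal-transport
cost, which the tests verify against an explicit linear program.
Histograms with the same width and anchor are zero-padded onto a common
grid. Kullback–Leibler divergence is deliberately not offered: empirical
histograms have limited, disjoint support and the CDF-based metric is
robust to that sparsity. Mean traces are compared by mean squared error on
identical time grids. Per-timepoint distances are aggregated uniformly or
with exponential weights `w_t = exp(-t/tau)` that emphasize early times.

## Parameter inference

The inverse problem — recover `{k_ini, k_on, k_off, k_deg, v_el}` from
per-cell nascent and total signals at a series of timepoints — is
likelihood-free: each trial vector is scored by simulating an ensemble and
comparing summary statistics against the target. The search works in
log10 space over a domain spanning several decades per parameter
(defaults: `k_on, k_off, k_deg` in 10^-2..10^2 /min, `k_ini` in
10^-1..10^3 /min, `v_el` in 1..10^3 nt/s).

**Stages.** Five stages with different objectives, each narrowing the
consistent region:

1. *Screening filter*: Wasserstein distance of nascent-signal histograms
   over the first three sample times, exponentially weighted
   (`tau` = span of those times). A large uniform sample over the full
   domain is evaluated once and the best tenth kept — no evolution. This
   preserves the sample's spread along the directions this metric cannot
   resolve (most importantly the effective-initiation-rate degeneracy
   line `k_i^obs = k_ini * k_on / (k_on + k_off)`), which the later
   penalty regions rely on. It also discards the computationally explosive
   corners (maximal initiation, negligible degradation) cheaply, since its
   simulations stop at the third sample time.
2. MSE of the total-signal mean trace over all timepoints — pins `k_deg`
   and `k_i^obs`.
3. Wasserstein distance of the total-signal distribution at the final
   timepoint (a steady-state proxy for turn-on data) — separates `k_on`
   from `k_off` through burst statistics.
4. MSE of the nascent-signal mean trace — pins `v_el`.
5. High-precision rerun of the nascent-distribution metric over all
   timepoints with a larger trial ensemble.

**Genetic algorithm.** Tournament selection (size 3), uniform crossover
(rate 0.8), per-gene Gaussian mutation (rate 0.3, sd 0.15 log10 units,
with at least one gene mutated so no child is an exact clone), 5% elitist
survival, bounds enforced by clipping. Trial ensembles are re-seeded every
generation (common random numbers within a generation): survivors are
re-scored under fresh noise, so the population cannot fixate on one noise
realization's optimum and its final spread reflects the genuine flatness
of the objective. Trials whose cells exceed a per-cell event budget
(default 16,000, roughly twice what plausible-region cells need) score
+inf and are culled.

**Inter-stage consistency.** Stages after the first add a quadratic
penalty for leaving the previous stage's region, defined per parameter as
center ± (radius + previous-elite standard deviation); treating the region
as an extent rather than a point keeps axes that the previous metric left
unresolved open to the next stage. The penalty weight defaults to the
median raw objective of the stage's initial population, so one squared
log-decade of excursion costs about a typical generation-zero error. Each
stage's population is initialized by resampling the previous elite with
Gaussian jitter.

**Estimates.** The final trial population is summarized per parameter by
the mean and standard deviation of its log10 values; the one-sigma
interval is `10^(mean±sigma)`. The full population summarizes better than
its elite subset because, along degenerate directions, the elite clusters
wherever selection drifted while the population spread reflects how weakly
the data constrain the axis. Replicate searches with different seeds can
be pooled; disagreement between replicates is the practical signature of
the `k_i^obs` degeneracy (`k_ini` and `k_off` are the hard parameters;
`k_on`, `k_deg` and `v_el` are well-behaved).

**Problem sizes.** The full-scale schedule uses a 5,000-trial screen and
500-trial refinement stages (generations 15/15/15/25, trial ensembles of
500–1,000 cells). The desk-scale schedule used by the tests and the
acceptance script — a 2,000-trial screen, 100-trial stages, generations
(0, 6, 8, 6, 8), trial ensembles of 100–300 cells against a 2,000-cell
target — runs in minutes on one core. In this regime the typical outcome
is recovery of `k_on`, `k_deg` and `v_el` within one sigma while `k_ini`
and `k_off` land elsewhere on the `k_i^obs` line (product constraint
satisfied); but individual desk-scale runs are stochastic and can commit
early to a compensation ridge (e.g. fast RNase binding with slow stepwise
consumption mimicking slow binding with fast consumption) that later
stages cannot fully unwind. Replicate searches with different seeds,
pooled, are the recommended guard — the same practice that diagnoses the
`k_i^obs` degeneracy.

## Synthetic targets

The generator wraps the simulator: a target is a per-cell, per-timepoint
table of nascent and total signals, structurally identical to what a
fixed-cell smFISH experiment yields after spot quantification, and the
search cannot distinguish the two. The standard validation configuration
is a bursty promoter (`k_ini=95`, `k_on=1`, `k_off=10` /min — active ~9%
of the time), `k_deg=0.5` /min, `v_el=41.5` nt/s, `L=5300` nt, a coarse
`N=15` resolution, and a 15-minute turn-on sampled once per minute.
What the generator does *not* emulate: microscopy noise (background,
spot-detection error, partial-probe photophysics), cell-to-cell parameter
variability, cell-cycle gene-copy-number changes, and multi-copy
correlation. Passing recovery tests therefore demonstrate the method's
self-consistency on the model class, not robustness to those real-data
effects.

## Numerical choices and degenerate inputs

- Probe spans that cover no step midpoint at the chosen resolution are a
  configuration error, raised at discretization.
- Histogram comparisons require equal bin width and anchor; grids are
  padded, never interpolated.
- The Fano factor is undefined (NaN) at timepoints with zero mean.
- With `N=1`, a transcript is born, then released by a single step event;
  the telegraph limit is exact for the unbound-molecule count.
- Zero total propensity (e.g. a silent gene in an empty cell) advances
  time directly to the next schedule boundary or sample time.
- GA ties are broken by stable sort; all stochastic components draw from
  generators seeded from the user seed, so every search is reproducible.

## Known limitations

- Single gene copy, two promoter states, sequence-independent rates, no
  polymerase exclusion or congestion, no cell growth or division.
- Inference consumes distribution (fixed-cell-style) data only; temporal
  correlations of live-cell traces are not used.
- The staged heuristic is not a posterior: one-sigma intervals are
  population spreads of a stochastic optimizer, not credible intervals,
  and the search is not guaranteed to find the global optimum.
- Steady states are reached by burn-in simulation, which becomes expensive
  when kinetic timescales are widely separated.
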