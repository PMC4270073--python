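# Methods

This note documents the models behind `clumpclock`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data can
and cannot say about real experiments.

## The phase-gated adhesion oscillator

No mechanistic model of the evolved aggregation clock is known, so the
simulator uses the minimal construction that reproduces the observed daily
cycle between single cells and lineage-based clumps: a **phase oscillator
with phase-gated adhesion and fragmentation**.

Each cell carries a phase θ ∈ [0, T) advancing at 1 hr/hr, modulo the period
T (default 24 hr). The cycle has two regimes:

- **Adhesive window**, θ ∈ [0, w) with w = 10 hr: a dividing mother retains
  her daughter through a mother–daughter bond, so a single cell grows into a
  clump of her own descendants (a tree in the bond graph, rooted at the
  founder).
- **Dispersal**, θ ∈ [w, T): daughters bud off as new singleton clumps, and
  every bond whose mother-side cell is in dispersal breaks independently
  with hazard λ_f per hour. Clumps split into the connected components of
  the surviving bond graph.

The window length w = 10 hr mirrors the 10-hr single-cell-to-clump arm of
the twice-daily selection schedule. λ_f = 0.3 hr⁻¹ (bond half-life ≈ 2.3 hr)
makes a clump decay to mostly singletons within the 14-hr dispersal arm,
which is the qualitative requirement the cycle imposes; no quantitative
clump-size distributions at peak aggregation are available to calibrate
against, so the size histogram bins (1–4, 5–10, >10 cells) should be read
as qualitative.

**Division.** In the default hazard mode a cell divides in a step of length
dt with probability 2^(dt/τ) − 1, so the expected population size is exactly
N₀·2^(t/τ); τ = 2 hr gives roughly six divisions in the shorter growth
interval and stays above the T/16 floor (at most 16 divisions per day). A
deterministic mode (division at fixed multiples of a per-cell interval,
optionally lognormal with CV `doubling_cv`) exists for exact-count tests.

**Phase inheritance.** A daughter inherits her mother's phase plus Gaussian
jitter (SD 0.75 hr per division). This value makes an untreated population
decohere over about a week (phase SD grows as 0.75·√(divisions) ≈ 2.6 hr per
day) while letting a synchronized one free-run for several cycles —
the two qualitative behaviors the system must show. The wall label
(covalent dye) marks only cells present at labeling time and is never
inherited, because a daughter's wall is newly synthesized.

**Time stepping.** Default dt = 0.25 hr; a precondition dt ≤ τ/4 keeps the
one-division-per-step discretization valid. All draws come from a single
`numpy.random.Generator` owned by the population, so a run is a pure
function of its seed. Density is tracked via an implied culture volume;
crowding is ignored because every protocol dilutes cultures to stay in
exponential phase (16 doublings from 10 cells/ml end at 6.6×10⁵ cells/ml,
more than 40-fold below the 3×10⁷ cells/ml end of mid-log growth).

Deliberate omissions: no spatial structure, no hydrodynamics of sonication
(it simply deletes all bonds), no metabolic state, no explicit adhesin-gene
regulation, no diploid life cycle.

## Instrument model

One FACS event per clump. For a clump of n cells:

- intensity = n · (per-cell mean) · lognormal noise (CV 0.15), identically
  for the selected-on and the bystander fluorophore; per-cell intensity is
  independent of phase and time, so all cyclical variation in event
  intensity comes from cell association;
- pulse width = pw_scale · n^(1/3) · lognormal noise (CV 0.05) — a
  diameter-like size proxy;
- imaged two-dimensional area = area_scale · n^(2/3), the projected area of
  a compact three-dimensional clump.

All lognormal noises have mean exactly 1. Doublet/coincidence artifacts,
instrument drift, and spectral compensation are not modeled, and FCS binary
I/O is out of scope (tables are CSV).

**Gating.** A tail gate keeps the ⌈fraction·N⌉ lowest (dim) or highest
(bright) events on a channel, ties broken by event id so gates are
deterministic. Gating is rank-based and therefore invariant to any monotone
rescaling of the channel.

## Protocols

**Selection synchrony.** The schedule alternates a 10-hr growth interval
ending in selection of the brightest events with a 14-hr interval ending in
selection of the dimmest (intervals sum to the 24-hr period). The run is
primed by an unrecorded dim selection at time zero; thereafter the event
table is recorded immediately before each scheduled action, giving exactly
two tables per day. The unsynchronized control passes all events and merely
dilutes at the same times; free run synchronizes for a set number of days
and then switches to dilution only. After every action the culture is cut
back to `keep_cells` whole clumps. Desk-scale defaults are 10⁴ events
measured per timepoint and 10³ cells kept per selection — scaled down from
the ~5×10⁵ cells a sorter collects, and configurable.

Synchronization emerges rather than being imposed: bright selection strongly
enriches for cells whose phase sat at the start of the adhesive window when
the previous dim selection happened (only they have built large clumps 10 hr
later), and coherence then persists because phases advance deterministically
between selections.

**Scoring scale.** The F75/F25 statistic min–max scales each channel and
counts joint quartile tails. On raw linear intensities the top-quartile
threshold is pinned by the single largest clump, leaving F75 a count of a
few outlier events; FACS distributions are displayed and analysed on log
scale, so the protocol driver scores log10-transformed intensity and pulse
width by default (`score_log_scale=True`). The `f75_f25` function itself is
scale-agnostic: it applies linear min–max to whatever values it receives.
When either tail count is zero, a pseudo-count of 0.5 is added to both
before the log ratio (log base 10; both configurable). Quartile membership
uses closed intervals [0, 25] and [75, 100].

**Cycle detection.** The unsynchronized control defines the noise envelope.
Because the asynchronous baseline of the score is a nonzero constant and the
unequal 10/14-hr intervals add a systematic slot asymmetry, detection works
on daily amplitudes: amplitude = score before the bright slot minus score
before the dim slot; envelope = 95th percentile of the control's absolute
amplitudes; a free-run day with amplitude above the envelope is one
detectable cycle. With defaults, free-run amplitudes run ~1.0–2.5 against an
envelope of ~0.4 for at least three days after selection ends.

**Single-lineage protocol.** One founder cell per microtiter well, mean
clump area recorded every 3.5 hr, and every 24 hr three objects (cells or
whole clumps, chosen uniformly) founding child wells — 1 + 3 + 9 wells over
three days, seven imaging points per well, 21 along each root-to-leaf path.
At least 50% of objects are sampled per imaging point. Founder phase is
drawn uniformly; no FACS synchronization is ever applied.

**Period estimation** smooths a series with a centered 3-point moving
average (ends dropped), keeps local maxima above the smoothed median, and
returns the mean peak-to-peak spacing. With 3.5-hr sampling the resolution
of a single spacing is one sampling interval, hence the ±4 hr band used when
checking recovery of the 24-hr period; the method needs at least two peaks
and raises on constant or single-peak series. Spectral estimation
(Lomb–Scargle) was deliberately left out — three cycles of 21 points do not
support it better than peak spacing, and peak spacing matches how such
traces are read.

## Segregant genetics

Loci are modeled as unlinked (each spore inherits each evolved allele with
probability ½ independently), appropriate for a handful of mutations spread
across chromosomes; a linkage map would slot into `cross_and_sporulate` but
is off by default. The default selection predicate is fully conjunctive —
a spore oscillates iff it carries *every* causal allele — the strictest
reading of reconstruction experiments; alternative predicates are accepted
as callables because deletion/add-back results show real architectures are
not strictly conjunctive. Sequencing draws per-locus depth from
Poisson(mean depth) and evolved-allele reads from Binomial(depth, f), with
an optional symmetric error rate (default 0: reference bias and mapping
artifacts are not modeled). Zero-depth loci are flagged uncallable, never
dropped.

The causal filter is freq ≥ 0.95. At depth ~100 a truly neutral locus
(f = 0.5) crosses it with probability ~10⁻²¹, so recovery of a planted
8-causal/20-neutral set at 10⁴ spores and depth 100 is effectively
deterministic — exactly zero false calls were observed over thousands of
simulated neutral loci. `binom_dev_p` computes the exact one-sided tail
P(X ≥ k | n, ½) by log-space summation of binomial coefficients (no normal
approximation), stable to n = 10⁶. Subtrait selection is formalized as a
three-way call per locus: selected for/against when the exact
Clopper–Pearson interval (level 0.99) around the selected-pool frequency
lies wholly above/below the starting frequency, else neutral.

The historical two-round mapping procedure (a first cross finding most
mutations, a second cross mopping up the rest) is not special-cased; it is
reproducible by composing `cross_and_sporulate`/`select_pool` twice.

## Allele trajectories and Sanger measurement

A discrete-generation haploid Wright–Fisher model with constant population
size (default 10⁵) and 6 generations per day. Oscillator lineages are
classes alongside a wild-type background; a lineage is founded (one
individual unless `initial_freq` is given) at its first mutation's arrival
time, acquires later mutations at their arrival times, and carries relative
fitness 1+s only once its causal set is complete. Each generation resamples
class counts multinomially with fitness-weighted probabilities, so neutral
dynamics are a martingale and the large-N limit of a selected lineage is
logistic, p' = p(1+s)/(1+ps) — both verified against closed forms in the
tests.

Sanger measurement multiplies true mutant and wild-type "peak heights"
(∝ f and 1−f) by independent lognormal noise calibrated so the measured
frequency has SD 0.05 at f = 0.5, and reports mut/(mut+wt); "roughly 10%
accuracy" is interpreted as an absolute ±0.10 envelope (≈ 2 SD),
consistent with the absolute 10% detection floor. Any measured value below
0.10 is censored to not-detected — censoring acts on the measured value,
so reported values are never below 0.10 while a true frequency slightly
under the floor can occasionally be detected, as in a real electropherogram.
The independent-origin count over shared-locus allele classes sums distinct
classes per population (wild type counts as a class) and never merges
identical-by-state alleles across populations, making it a lower bound.

## What the synthetic data does not show

The generator emulates the *logic* of the experiments — phase-gated
aggregation, tail selection, pooled segregant sequencing, peak-height
measurement — not their biology. Passing tests demonstrate that the
statistics and callers behave correctly on data generated under their own
assumptions (unlinked loci, memoryless fragmentation, lognormal instrument
noise, a single well-mixed culture). They say nothing about linkage, about
epistatic penetrance of real causal sets, about FACS artifacts such as
coincident events, or about whether a real population's oscillation is
phase- rather than amplitude-limited. Headline transcriptomic results and
absolute allele-frequency histories of any real population depend on
unreleased sequencing data and are not reproduced here.

## Problem sizes

Defaults throughout are desk-scale choices: 10⁴ events per timepoint, 10³
cells kept per selection, 2×10³-cell starting stocks grown 24 hr before a
protocol, 10⁴ spores and depth 100 per segregant replicate, 20 replicate
seeds for the neutral baseline, and 10 replicate lineages for period
recovery. The full test suite runs in well under a minute of simulation
time for every module except the 6-day free-run comparison, which dominates
at ~25 s.
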