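# Methods

## The haploid retention model

A radiation hybrid panel is modelled as follows. Irradiation breaks each
donor chromosome according to a Poisson process with rate `breakage_rate`
(expected breaks per Mb); the chromosome's induced partition is its fragment
set. Each fragment is retained in a hybrid independently with probability
r, which depends on chromosome class (microchromosomes retain better than
macrochromosomes in avian panels) and is boosted multiplicatively near
centromeres. A marker is truly present in a hybrid iff a retained fragment
covers its position.

Two markers are separated by a break with probability θ = 1 − exp(−ρx) for
physical gap x and breakage rate ρ. Conditional on separation their
retentions are independent, giving the two-point cell probabilities

    P11 = (1−θ)r + θr²,  P10 = P01 = θr(1−r),  P00 = (1−θ)(1−r) + θ(1−r)².

Distance is d = −100 ln(1−θ) centirays, labelled with the dose (cR_6000).
Along an ordered set of markers the hidden presence indicator follows a
stationary, reversible two-state Markov chain with P(1→1) = 1 − θᵢ(1−r),
P(0→1) = θᵢ r per interval; the two-marker marginal of this chain is exactly
the two-point model, and reversibility makes the likelihood invariant to
reversing the order, so orders are only identified modulo reversal.

## Estimation

**Two-point.** The (θ, r) likelihood is maximised by profiling: for fixed r
the optimal θ solves a quadratic stationarity equation in closed form, and
the one-dimensional profile in r is bracketed on a 101-point grid and
polished with bounded scalar minimisation (tolerance 1e-10). The LOD is
log10 L(θ̂, r̂) − log10 L(1, r̂): the null fixes θ = 1 and *shares* the
fitted r̂, which makes LOD ≥ 0 by construction; an `independent_null` flag
instead lets the null fit its own retention (the marginal rate), which can
only lower the LOD. Tables with all calls present (or absent) leave r on the
boundary and θ unidentified; they return a flagged degenerate result with
LOD 0. Unit tests and the reproduction script verify the fit against a
1000 × 999 grid-search oracle (agreement within 1e-3 log10 units).

**Multipoint.** For a fixed order, interval θᵢ's and the shared r are fitted
by EM: the E-step is a scaled forward–backward pass (observed calls pin the
chain state; unknown calls leave both states admissible), and the M-step
updates every θᵢ with the same closed-form quadratic applied to expected
transition counts, while r is profiled by bounded 1-D optimisation of the
expected complete-data log-likelihood (with θ's re-profiled at each trial
r, so the M-step is exact). Convergence is declared when the observed
log-likelihood gains < 1e-6 (natural log); 500 sweeps is the budget and
exceeding it raises. Duplicate adjacent markers correctly fit θ = 0; an
interval fitted at θ = 1 yields an infinite cR gap, which only occurs if a
linkage group was formed below the recommended LOD thresholds.

**Order search.** Groups of ≤ 8 markers are searched exhaustively over all
orders modulo reversal (n!/2). During search the retention is held at the
group's marginal estimate — retention is essentially order-invariant, and
this turns candidate scoring into a pure θ problem; the search runs in two
stages (coarse EM at tolerance 1e-2 for every order, tight refit of the 40
best) and the returned map is refitted with r free at 1e-6. Larger groups
use greedy best-insertion seeded by the highest-LOD pair, refined by 2-opt
(all segment reversals) and sliding-window (all permutations of 4
consecutive markers) passes until no gain exceeds 1e-6. All ties break on
the lexicographically smallest reversal-invariant order, making every search
deterministic.

**Framework and comprehensive maps.** The framework starts from the marker
triple whose best internal order beats its runner-up by the largest log10
margin (exhaustive over triples) and grows by repeatedly inserting the
marker with the largest placement margin — the gap between its best and
second-best insertion log-likelihoods — while that margin stays ≥ 3 log10
units (`delta_lod`). The comprehensive map then places each remaining marker
at its maximum-likelihood insertion point in the fixed framework order,
recording the margin; markers with two-point LOD < 3 against every framework
marker are reported unplaced. Placement can extend the map beyond the
framework ends.

**Comparative and robust maps.** The comparative score is
log10-likelihood − λ × breakpoints(order, reference), where a breakpoint is
an adjacency of the candidate order absent (in either orientation) from the
reference order restricted to the same markers. λ defaults to 3 log10 units
per breakpoint, on the same scale as the framework margin; the search is the
order search initialised at (and, for small groups, exhaustively compared
against) the reference. Robust flags come from bootstrap: hybrids are
resampled with replacement B times (default 100), the comparative map is
rebuilt by local search from the reference order each time, and the robust
set is the largest marker subset whose relative order (mod reversal) equals
the base map's in ≥ 95% of bootstrap maps, found by greedily removing the
marker whose removal most improves agreement. Markers with byte-identical
call rows carry no information about their mutual order, so at most one per
identical group can be robust (the deterministic search would otherwise
never expose their interchangeability).

**Retention analysis.** A marker's retention f is positives / informative
hybrids; unknown calls never enter the denominator. Class and genome-wide
summaries are unweighted means over markers (not pooled over calls) — the
two conventions differ slightly and the marker-weighted one matches how
per-marker retentions are usually plotted; this is a documented choice, not
an inference. Genotyping methods are compared with paired two-sided t-tests
on per-marker retentions, reported raw with a Bonferroni column added but
not used for gating. Hybrid selection scores each clone by
w·(macro fraction present) + (1−w)·(micro fraction present) and keeps the
top n, ties broken by id — favouring macrochromosome retention while keeping
microchromosome values, as in the panel's construction.

**Genotype calling.** A well is *present* iff it amplifies no later than the
negative control (Ct ≤ neg Ct − margin, margin default 0) *and* its product
melts at the marker-specific temperature (|ΔTm| ≤ 1.5 °C). Early Ct with a
shifted Tm, or late Ct with a matching Tm, is *unknown*; a ΔTm beyond twice
the tolerance marks a non-specific product and, with no other support, the
call is *absent*, as is no amplification. 1.5 °C is the only published
number for "close"; the non-specific cutoff at 2× is this package's choice
and both are configurable. Markers whose duck positive control fails to
amplify or lands outside Ct 10–16 are discarded. Duplicate wells agree or
become unknown on a present/absent conflict; a decisive call overrides an
unknown partner unless `strict_replicates` is set (how the original
duplicates were resolved is not published, so the rule is config-exposed).

## The synthetic panel

Defaults are the study conditions: 90 hybrids; retention 0.202 (macro) /
0.281 (micro); false-positive 0.005, false-negative 0.01 and unknown 0.01
call rates (small, plausible genotyping-error levels — the study reports
~10% of markers discarded for quality, not per-call error rates); WGA
dropout off unless a WGA scenario is simulated, in which case it removes a
marker's region in *all* hybrids (region-wise amplification failure, the
pattern seen for the smallest microchromosomes). The breakage rate default,
0.35 breaks/Mb, is a calibration chosen so a ~7 Mb microchromosome carrying
~24 markers spans roughly 200–300 cR of true breakage (224 cR over the 6.4
Mb marker span), bracketing the published 170–283 cR maps; fitted maps run
longer than that under the default genotyping-error rates, since false
calls masquerade as extra breaks (~340 cR at 24 markers). No per-interval
calibration for duck at 6,000 rads exists, so this is an order-of-magnitude
default, not a fit. The centromere boost is a
rectangular kernel (default width 1 Mb, factor 1.5, clipped below 1) — only
the existence of a centromeric retention peak is documented; the shape is
ours. Randomness uses one seed with per-hybrid spawned substreams, so
results are byte-identical across runs and independent of execution order.

The qPCR layer gives positives Ct ~ Normal(12, 1) at the marker's Tm and
negatives late amplification (Ct ~ Normal(26, 1)) at an off-target Tm
(+4 °C) or none at all; the WGA condition shifts positives ~10 cycles later
and loses 30% outright, reproducing the observed ~22-cycle positive controls
and the method's lower sensitivity. With all noise at zero, calling the
simulated readouts returns exactly the simulated truth (a closure test of
generator and caller together).

What the generator does *not* emulate: diploid donors, selectable-marker
retention gradients (e.g. around HPRT), culture-passage fragment loss,
cross-amplification structure beyond a single off-target Tm, and
position-dependent WGA bias within a chromosome. Passing tests therefore
show the estimators are correct under the stated model, not that the model
captures every artefact of a real panel.

## Scaffold integrity

Scaffolds whose alignment segments hit two reference chromosomes are chimera
candidates; the breakpoint is the scaffold-coordinate gap between the
chromosome blocks. A marker pair close together on the scaffold (≤ ~100 kb)
but spanning the junction decides the case: LOD ≥ 6 refutes the chimera;
LOD < 6 with ≥ 30 doubly-informative hybrids supports it; fewer informative
hybrids are *inconclusive*, because missing data must never be read as
misassembly. A scaffold flagged by alignment but supported by linkage is
annotated as a possible evolutionary rearrangement or segmental duplication
rather than an assembly error. The LOD threshold matches the microchromosome
grouping threshold (6) and is configurable; simulation puts sensitivity at
~1.0 and the false-positive rate at ~0 under the panel's conditions
(200-scaffold experiment in the reproduction script).

## Numerical and design notes

- Coordinates are 1-based inclusive bp; cR positions are 0-based from the
  first map marker. Genotype files use `1/0/?` tokens (configurable); the
  CarthaGene-dialect export uses `1/0/-`.
- Two-point estimation excludes hybrids unknown in either row; multipoint
  marginalises unknowns instead. Both conventions use all available data
  without imputation at their respective granularities.
- LOD-graph linkage grouping is single-linkage on pairwise LOD ≥ threshold
  (11 or 6 being the published choices), groups ordered by size then
  smallest id.
- The centromere hint is the argmax of a 3-marker moving average of
  retention along the map, reported only when it exceeds the map's median
  retention by > 0.05; flat or uniformly high profiles (as on a chromosome
  with ~46% retention everywhere) return nothing.
- Problem sizes in tests and the reproduction script — 1,000 random tables
  for the grid cross-check, 100 seeded panels for order/inversion recovery,
  200 scaffolds for chimera performance, 7 markers per exhaustive search —
  are the package's validation configuration, chosen to estimate each rate
  with useful precision while keeping a full run in minutes.

## Known limitations

- Equal retention per linkage group: no per-marker or fragment-endpoint
  retention models, no diploid model, no interference.
- The framework growth schedule and the exact penalty of the original
  comparative tooling are not published; this package's schedule (margin-
  greedy insertion, λ = 3) follows the published contracts and thresholds
  but is its own construction, as is the bootstrap definition of robustness.
- Heuristic search above 8 markers is local; 2-opt plus window-4 passes can
  in principle stop at a local optimum, though it matched exhaustive search
  on every tested 7-marker panel.
- Map lengths inflate with genotyping error (spurious breaks), as for any
  RH mapping tool; the simulator's defaults include that effect.
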