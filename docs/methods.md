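# Methods

## Replication model

Each simulated cell replicates a fixed genome from an annotated origin set.

**Origin firing.** Origin *i* is competent in a cell with probability
`p_i × competence_scale` (independent Bernoulli draws per cell).  A
competent origin draws a firing time from `Normal(μ_i, σ_fire)` truncated
at zero, with `μ_i` the origin's characteristic replication time `T_rep`
(minutes).  Only relative timing matters for everything downstream; the
truncated normal is chosen for two-parameter control of mean and
cell-to-cell jitter.  Cells in which no origin is competent anywhere are
rejected and redrawn — a conditioning step mirroring the fact that every
sampled viable genome replicates.

**Fork progression.** Forks move bidirectionally at constant speed *v*
(default 1500 bp/min).  A position is replicated by the earliest-arriving
fork.  With constant speed, the earliest-arrival lower envelope over
competent origins is *exactly* equivalent to explicit passive suppression:
if a fork reaches origin *j*'s locus before `t_j`, then by the triangle
inequality `t_k + |x−x_k|/v ≤ t_j + |x−x_j|/v` for all *x*, so the
suppressed origin's cone never appears anywhere in the envelope.  The
per-cell program is stored as piecewise segments (breakpoints, fork
direction, source origin and firing time), giving O(origins) construction
and O(log n) position queries.  An origin "fires actively" in a cell when
its own position is replicated by its own cone; the fraction of cells in
which this happens is the ground-truth efficiency used in recovery tests.

**Replication barriers.** Each stall locus arrests replication with
probability *s* per cell (one draw per cell and site).  An arrested site
becomes a hard boundary at the locus midpoint: the chromosome is
partitioned there and each side replicates from its own origins, so the
first fork to arrive terminates and the region beyond is replicated from
the other side.  A partition with no fired origin stays unreplicated in
that cell (it yields no fragments and copy number 1); configurations
should place origins on both sides of potential barriers.  Pausing without
arrest is not modelled.

**Lagging-strand priming.** Within each fork territory, Okazaki-fragment
junction positions form a renewal process with exponential spacings of mean
`priming_mean / pol_alpha_level` (defaults 165 bp and 1.0).  Because
exponential spacings are memoryless, junctions are drawn as a single
Poisson process per chromosome and cut at territory boundaries — exactly
the per-territory renewal process, in one vectorised draw.  With
probability `snap_prob` a junction relocates to its nearest nucleosome dyad
plus `Normal(0, snap_sd)` noise (defaults 0.9 and 15 bp), truncated to stay
inside its own territory; this models chromatin-coupled positioning of
fragment termini.  Consecutive junctions tile each territory exactly, so
with subsampling rate 1 every base is covered by exactly one fragment per
cell — Watson under leftward forks, Crick under rightward — which the test
suite asserts at base resolution.

**Two Pol α arms, deliberately separable.** `competence_scale` multiplies
every origin's firing competence (the origin-firing arm);
`pol_alpha_level` divides the priming rate (the lagging-strand arm).
Global Pol α depletion moves both; a Ctf4-uncoupled replisome is modelled
by lowering only the priming arm, which lengthens fragments while leaving
the OEM distribution unchanged.  The simulator deliberately does not
distinguish reduced primer synthesis from reduced primer utilisation: only
the effective inter-priming distance is exposed.

**WGS pools.** Each cell is frozen at a sampled S-phase time *t* (uniform
over `[0, T]` with `T = 45` min, a fixed time, or per-cell times); copy
number at *x* is 2 if *x* is replicated by *t*, else 1.  Binned read counts
are Poisson with mean `wgs_depth × copy` per cell per bin; the G1 control
has copy 1 everywhere.

**Reproducibility.** Every cell uses an independent RNG stream derived from
`SeedSequence(seed, spawn_key=(cell_index,))`, so results are independent
of execution order and byte-identical across reruns.

## Analysis definitions

* **Counting.** OEM and all strand-fraction statistics use midpoint
  counting (one fragment, one vote) by default; base-coverage mode is
  provided.  Midpoint counting avoids over-weighting long fragments, which
  matters precisely in Pol α-depleted regimes.
* **OEM.** `WF(left 10 kb) − WF(right 10 kb)` around the origin midpoint;
  flanks truncated at chromosome ends; a flank with fewer than `min_count`
  (default 50) fragments renders the record undefined rather than noisy
  (the depth floor is a package choice).  Orientation: positive for firing
  origins under the Watson-equals-leftward-fork convention.  Replicate
  tables are combined by averaging per-origin OEMs (pooling fragments first
  is available by pooling upstream).
* **End conventions.** 0-based half-open intervals; Watson 5′ = `start`,
  Watson 3′ = `end − 1`; Crick mirrored.  The dyad meta-analysis is a
  metagene sum over *all* dyads within ±200 bp of an end (not
  nearest-dyad), matching standard OK-seq practice; counts and per-total
  density normalizations are both available.
* **Meta profiles.** Equal-weight averaging across origins (a deep locus
  does not dominate); origins with zero counts in an offset bin are omitted
  from that bin's mean; optional division by the profile maximum.
* **Group comparisons.** Two-sided unpaired t-test, Welch
  (unequal-variance) by default with a pooled-variance option; schemes:
  early/late split at the median `T_rep`, Forkhead classes
  (activated/repressed/independent), and earliest-`T_rep < θ` vs the rest
  (θ = 18 min reproduces an earliest-22-of-283 style split on genome-scale
  annotations).
* **Fork-direction profiles.** Transcription-oriented (minus-strand loci
  reflected before aggregation), pooled counts across loci because
  individual loci are shallow; `stall_score = mean(codirectional fraction
  downstream) − mean(upstream)` over ±2 kb.  A helper excludes loci within
  10 kb of annotated origins (origin-distal pre-selection).
* **Copy number.** Pipeline order: mask exclusion-list bins → scale each
  sample to reads-per-million → divide each sample by its own median
  unmasked bin → ratio S/G1; bins with zero G1 coverage are masked.  This
  order makes the ratio invariant to sequencing depth; RPM and
  median-normalisation commute, so the ratio equals
  `(S/median S)/(G1/median G1)`.  "Smoothed to 1 kb" for meta-origin
  coverage means block-mean re-binning of 100 bp bins, not loess at 1 kb
  bandwidth.
* **Loess.** Local linear regression with tricube weights over a window of
  `span_fraction` (default 2%) of the chromosome's bins, per chromosome;
  masked bins carry no weight; the fit is reported only where ≥ 10 unmasked
  bins fall in the window, with a weighted-mean fallback for degenerate
  windows.  Implemented as convolutions of the distance kernel against
  masked moment sequences (O(n·window), exact for linear data); tests
  verify agreement with direct per-window weighted least squares to 1e-9.

## Synthetic study conditions

The fixture emulates a scaled-down budding-yeast genome: 3 chromosomes of
500 kb, origins every ~45 kb (33 origins) with competences in [0.1, 0.95]
and `T_rep` spread over 10–38 min, nucleosome repeat 165 bp, fork speed
1500 bp/min, S-phase length 45 min.  The origin table is keyed by its own
`table_seed` (default 0), independent of the run seed: like a published
origin annotation, it stays fixed while libraries vary.  Presets differ
only in documented knobs:

| preset     | pol_alpha_level | competence_scale | snap_prob | stall_prob |
|------------|-----------------|------------------|-----------|------------|
| baseline   | 1.0             | 1.0              | 0.9       | 0.0        |
| depleted   | 0.4             | 0.5              | 0.3       | 0.0        |
| ctf4_like  | 0.5             | 1.0              | 0.9       | 0.0        |
| stall      | 1.0             | 1.0              | 0.9       | 0.6        |

Problem sizes in the test suite and acceptance script (2,000–5,000 cells
for OEM recovery and depletion, ~10⁵ fragments for length scaling, 400–800
cells elsewhere) were chosen as the smallest sizes at which the sampling
error of each statistic is comfortably below the effect being measured.

### Benchmark geometries

Two dedicated geometries isolate estimator properties from neighbourhood
effects:

* **Recovery benchmark** (`recovery_config`): 20 variable-competence test
  origins, each 35 kb from a fully competent anchor origin in its own
  100 kb unit, all sharing one mean firing time.  When a test origin stays
  passive, the anchor forks sweep *through* its locus, so its ±10 kb flanks
  report firing polarity; OEM then recovers true efficiency with Pearson
  r > 0.99 and mean absolute deviation ~0.015 at 2,000 cells.  On
  realistically staggered annotations, passive cells instead place fork
  *convergence* near the origin, and the termination signal biases OEM
  below true efficiency by up to ~0.1 — a genuine property of
  fork-polarity metrics, visible in the package and documented here rather
  than hidden.  For the same reason, halving all competences lowers every
  OEM pairwise on the benchmark geometry, but on staggered annotations a
  small minority of origins dominated by an early neighbour's termination
  zone can move against the trend.
* **Stall benchmark** (`stall_benchmark_config`): one oriented locus 25 kb
  downstream of an always-firing origin, with the termination zone ~15 kb
  beyond the profiled window, so the codirectional fraction is flat at the
  locus without arrest (score 0 up to sampling noise) and drops by ≈ *s*
  with arrest probability *s*.  Loci placed midway between co-timed
  origins sit in termination zones and score negative even without
  stalling; stall detection on real data presumes origin-distal loci in
  predominantly unidirectional territory.

## What the simulator does and does not emulate

It reproduces: strand polarity set by fork direction, passive-replication
suppression and its competence dependence, priming-rate-dependent fragment
lengths, nucleosome-phased fragment termini, pooled pan-S copy-number
contrast and its flattening under global depletion, and polarity switches
at replication barriers.  It does not model sequences or reads (no
mappability, GC or PCR bias — exclusion masks must come from the user),
replisome biochemistry (Ctf4 appears only as an effective priming knob),
fork-speed changes, checkpoint feedback, or pausing-without-arrest.
Passing tests therefore validate the analysis stack's correctness and
sensitivity under these idealised conditions, not robustness to alignment
artefacts in real libraries.

## Numerical choices and degenerate inputs

Zero-length territories yield no fragments; junctions colliding after dyad
snapping are deduplicated; fragment boundary coordinates are floored to
integers (sub-bp effects only).  Interval queries select bins by bin
midpoint, so flank windows partition exactly when windows are multiples of
the bin size.  `watson_fraction` and profile bins with zero counts are NaN
(undefined), never 0.  Ties in earliest arrival (exactly simultaneous
forks) resolve to the leftmost origin's cone via stable sorting — a
measure-zero event under continuous firing times.
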