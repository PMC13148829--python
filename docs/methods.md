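# Methods

`clunio` is an individual-based, forward-in-time simulator of allochronic
(reproductive-timing) divergence in the intertidal midge *Clunio marinus*.
The organism's circalunar clock fixes the lunar day of adult emergence
`T ∈ {1..30}`; adults live only hours, mate on the day they emerge, and
oviposit at the low-tide waterline of that day.  Because low-tide height
varies over the lunar month, emergence timing determines where on the
bathymetric axis the offspring start life — and therefore with whom they
compete as larvae.  Competition for space then generates
frequency-dependent disruptive selection on `T`, and, because same-day
mating makes `T` a magic trait, the population can split into reproductively
isolated chronotypes without any geographic separation.

## Environment

Depth `D` is measured in tidal-range units: 0 is the mean tide level, +1
the upper and −1 the lower edge of the intertidal.  The low-tide waterline
on lunar day `T` is

    D(T) = ½ [ sin(2πT/15 − 5) − 1 ]  ∈ [−1, 0],

with period 15 (two spring/neap cycles per lunar month); the phase offset
is a pure radian constant.  Spring tides (lowest low water, D ≈ −1) fall on
days 8 and 23, neap tides (D ≈ 0) on days ~1 and ~16.

Environmental fitness over depth, `Fe(D)`, defaults to the sigmoid
`1/(1 + e^{6D+1})` — high below the neap low-water line, low above it.
Four alternatives (flat, linear, unimodal, bimodal) probe sensitivity to
this assumption.  The unimodal/bimodal Gaussians use the denominator
`(2σ)²` (0.36 and 0.16), exposed as module constants so the conventional
`2σ²` reading is a one-line switch.  The bimodal curve exceeds 1 by
≈ 0.0055 at D = −1 because its two peaks overlap; this is documented and
left unclamped — offspring counts are floored downstream, so a fitness
marginally above 1 is harmless.

## Competition and total fitness

The load on larva j is a Gaussian kernel sum over all other larvae of the
generation, `I_j = Σ_{i≠j} exp(−(D_j−D_i)²/(2 Cw²))` (self excluded; the
kernel exponent is negative — the kernel is a similarity-decaying Gaussian,
with `Cw` the interaction range).  The density-dependent fitness component
is `Fc = K/(e^{10I/K} + K)`, evaluated in the overflow-safe form
`K e^{−x}/(1 + K e^{−x})`.  Total fitness is the product `Ftot = Fe·Fc`.
The O(n²) pairwise sum is the reference implementation (computed in row
blocks to bound memory); a naive double-loop oracle pins it in the tests to
1e−12.

## Clonal model (simple version)

Non-overlapping generations; each generation executes, in order: larval
dispersal (depth += Normal(0, σ_dispersal)); `Fe` from the post-dispersal
depth; `I` over all larvae at once, then `Fc` and `Ftot`; emergence (adults
move to `D(T)`); reproduction — each adult leaves
`floor(Ftot · max_offspring)` clonal offspring born at the parent's
oviposition depth; parents die.  The phenotype mutates at birth by adding
`Normal(0.5, μ)` and flooring, so it changes (±1 day, rarely more) only
when the draw leaves [0, 1); with μ = 0.18 that happens with probability
2Φ(−0.5/0.18) ≈ 0.55 %.  Days wrap mod 30 (31→1, 0→30).  One seeded
generator drives a run; sweep replicate r uses seed base+r.

Reference parameters: μ = 0.18, Cw = 0.1, σ_dispersal = 0.25, K = 100,
max 5 offspring, founders: 10 individuals at depth 0 with T = 15, 500
generations.

### Depth boundary

The dispersal boundary is deliberately **unbounded** by default (`boundary
= "none"`; `clamp`, `reflect` and `truncate` i.e. truncated-normal redraw
are available).  Any policy that confines larvae to [−1, 1] folds dispersal
mass back onto the bottom edge and roughly doubles the local density felt
at D ≈ −1.  That artificial crowding makes the spring-tide niche
uninvadable: pairwise invasion assays under clamp/reflect/truncate show a
day-11 resident blocking every deeper mutant, so the characteristic
spring-tide chronotype can never establish and the model loses its central
behaviour.  With unbounded dispersal the lower intertidal/shallow subtidal
— where *C. marinus* larvae in fact live — remains accessible, and the
spring + off-neap branching, the extinction corner and the
multiple-branching region all emerge as expected.  `Fe` extends smoothly
beyond the nominal band (the sigmoid saturates), so no special casing is
needed.

## Genetic extension

Individuals are diploid with two 1-Mb haplotypes, separate sexes (exact
1:1 per generation by alternating assignment; Bernoulli(½) available) and
sexual reproduction.  Per gamete, mutation and crossover counts are
Poisson(rate·L) with rate 1e−7/bp for both (mean 0.1 each).  A new
mutation is phenotype-affecting with probability `P_effecting` (effect ~
Normal(0, σ_effect), additive across loci and chromosomes) and neutral
otherwise.  The emergence day is

    T = wrap( floor( Σ effects + noise + initial_T ) ),

where `noise ~ Normal(0, σ_emergence)` is drawn once at birth and stored,
so an individual's day is stable through its life — emergence and mate
matching use one value.  Increasing σ_emergence lowers heritability.

Mating: mothers are matched only with males sharing their exact emergence
day; a female (or male) with no same-day partner leaves no offspring.
Fathers are drawn uniformly with replacement (polygyny allowed).  Brood
size is `floor(mean(F_mother, F_father) · 10)`; offspring are born at the
waterline of the parents' shared day.

Reference parameters double the demographic scale of the clonal model
(K = 200, max 10 offspring per pair — still 5 per parent) and run 1500
generations.

### Haplotype representation

Haplotypes are sparse sorted arrays of mutation ids referencing a global
append-only mutation table; a dense 1-Mb array per chromosome would be
intractable at 0.1 mutations/gamete/generation.  Recurrent mutation at an
occupied position creates a new, independently tracked allele (stacking,
not overwriting).  Gametes with zero crossovers and zero new mutations —
(e^{−0.1})² ≈ 82 % of meioses — share the parental array by reference;
haplotype arrays are treated as immutable.  Per-haplotype effect sums are
cached, so a fast-path gamete costs O(1).  Mutations fixed on every
chromosome are consolidated every 250 generations into a scalar background
added to the genetic value; phenotypes are invariant under consolidation
(tested), and equality of the sparse phenotype computation with a dense
per-base oracle is tested on toy genomes (L = 100).

## Observables

* **Chronotype count** — the number of peaks of the 30-bin circular
  phenotype histogram.  The histogram is smoothed with a wrapped Gaussian
  (s.d. 0.5 day) and a peak is a circular local maximum with height at
  least 5 % of the census; plateaus count once; an empty histogram has 0
  peaks and a perfectly uniform one counts as a single undifferentiated
  chronotype.  The light smoothing agrees with raw peak counting on all
  realistic outputs (counts are unchanged across s.d. 0.25–0.75 and
  threshold 0.025–0.075) while suppressing single-day noise in small
  populations; a heavier 1-day smoothing was rejected because it merges
  genuinely distinct branches two days apart.  Both knobs are exposed.
* **Pairwise invasibility** — burn a mutation-free resident to generation
  250, insert one mutant at the waterline of its own day (as if its egg
  had been laid by a mutant parent; the model is silent on this and the
  choice is config-visible), run to 500, classify by the surviving
  phenotypes (coexistence / mutant invaded / resident persisted / both
  extinct).  The diagonal is degenerate and skipped in grids.
* **Intermediate-frequency allele fraction** — among mutations segregating
  in the living population (0 < frequency < 1 over 2N chromosomes), the
  fraction with frequency in [0.3, 0.7]; the genomic signature of a split
  population.  Zero when nothing segregates; undefined (raised) for an
  empty population.
* **Genotype matrix** — sampled individuals × sample-variable sites with
  0/1/2 copy counts plus site metadata, ready for standard PCA (the PCA
  itself is delegated to any standard implementation).

## Experiments

`run_sweep` executes grid × replicate tasks serially with derived seeds
`base + point_index · replicates + replicate` (collision-free; results are
independent of execution order and resumable from a partial CSV).  Default
grids mirror the reference experiments: 40 linear values in [0.025, 1] for
the ecological axes, 21 values in [0, 1] × [0, 0.5] × [0, 3] for the
genetic axes, 25 per axis for the fitness-function scan.  Full-scale grids
with 1000 replicates are cluster-sized; the desk-scale default is 20
replicates, which stabilises modal outcomes.

## Problem sizes used by the test suite and acceptance script

Replicate counts are desk-scale choices: 20 clonal or 10 genetic
replicates for modal chronotype counts, 4–6 genetic replicates per
heritability point (2000–2500 generations instead of the full 3000), 5
replicates per initial phenotype, and single-figure replicates for CLI and
property tests.  Modal statistics stabilise quickly at these sizes; mean
heatmap values at full grid resolution require the cluster-scale runs
described above.

## Known limitations

* **Demographic cycles and marginal coexistence at the clonal reference
  parameters.**  The steep density dependence (`Fc` falls e-fold per
  `ΔI = K/10`) combined with floored offspring counts produces strong
  boom–bust census cycles (~100 ↔ ~450 at the reference parameters).
  These cycles are intrinsic — the extinction corner of the ecological
  parameter space is their direct fingerprint (a wide kernel synchronises
  everyone's offspring counts, so a bust overshoots to zero).  One
  consequence: after branching, the off-neap chronotype — competitively
  viable but with lower environmental fitness than the spring branch —
  undergoes occasional whole-branch extinction during booms and later
  re-forms by mutation.  Branching itself occurs in essentially every run,
  but both branches are simultaneously present at generation 500 in only
  ~50–55 % of clonal runs, so the *final-snapshot* chronotype count at the
  reference parameters is marginal rather than clean.  The genetic model,
  with its doubled demographic scale, holds its two branches more reliably
  (both present at the final snapshot in roughly two-thirds to
  three-quarters of runs), but individual seed streams can still return a
  modal count of 1 at small replicate numbers.
* The tide has one low tide per lunar day (no semidiurnal structure) and
  the tide curve is a stylised sinusoid, not a calibrated tide table.
* Non-overlapping generations: cohort staggering between chronotypes is
  deliberately not modelled.
* No dominance, epistasis, sex linkage, or linked-selection summaries; the
  trait is strictly additive.
* The synthetic data are the model itself; nothing here calibrates to
  field measurements, so passing tests demonstrate internal reproduction
  of the model's behaviour, not fit to wild populations.
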