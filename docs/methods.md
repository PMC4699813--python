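# Methods

This note documents the modeling conventions, parameter choices and design
decisions behind `fuzzyhep`, and what the synthetic benchmarks do and do not
demonstrate.

## Steady-state fuzzy logic

The model is a steady-state constrained fuzzy-logic network.  Species states
live in [0, 1]; 0 is inactivity, 1 maximal activity.  There is no time axis:
feedback loops are removed up front (a feedback requires a time scale to
mean anything at steady state) and the remaining acyclic graph is evaluated
once, in topological order.

Each gate input passes through the normalized Hill transfer
f(x) = x^n (1 + k^n) / (x^n + k^n).  The (1 + k^n) factor pins f(1) = 1, so
a fully active input transmits full activity regardless of gain; k is the
half-activation point of the unnormalized curve and n its steepness.
Conventions:

- **Inhibition inverts after transfer**: an inhibiting input contributes
  1 − f(x).  Consequence: a species whose only inputs are inhibitions from a
  silent pathway rests at 1.  This is deliberate — it reproduces the control
  state of downregulated detoxification genes without extra baseline
  machinery.
- **AND = min, OR = max** (standard Gödel fuzzy algebra).  Multiple gates on
  one target OR together; a candidate AND gate is a separate hypothesis from
  its single-input parts.
- **Clamps**: stimuli are fixed at their condition level, chemical
  inhibitors fix their target to 0 (inhibition is modeled as total; the
  inhibitors this design emulates were verified near-complete).  Clamps
  override gates.
- **Species with no active gate** fall back to a constitutive baseline: 0 by
  default, 1 for species flagged `constitutive` (basally active regulators
  such as hepatocyte nuclear factors).  The flag is explicit in the species
  annotations because activation-only genes must be ON at control.

In the Boolean limit (steep transfer, binary clamps) the engine reduces
exactly to AND/OR/NOT logic; the test suite exploits this with a brute-force
Boolean oracle.

## Network preprocessing

- `flatten_boolean_gates` turns a gated description into simple signed
  transitions (gate structure is re-hypothesized later by AND expansion).
- `remove_feedback` deletes either an explicit transition list (the bundled
  hepatic network ships one, covering its SOCS-type feedbacks) or, under the
  `auto` policy, greedily deletes the transition lying on the most simple
  cycles, ties broken lexicographically — deterministic, but a curated list
  is preferable when domain knowledge identifies the feedback arcs.
- `compress` removes species that are neither measured, perturbable,
  stimulus, nor constitutive: unobserved sinks are dropped; pass-through
  species are rewired (U→S, S→V) ⇒ (U→V) with the product sign.  A species
  is retained when removal is not provably safe: fan-in > 1 with fan-out > 1,
  fan-in > 1 feeding an inhibiting edge (OR does not distribute through the
  negation), or when rewiring would create contradictory duplicate edges.
  On top of the rule, each removal is verified against Boolean-limit
  steady-state equivalence at the measured species over all exhaustive clamp
  patterns (up to 256 patterns; beyond that the rule alone decides) and
  reverted if equivalence fails.  Correctness therefore rests on the
  simulation oracle, not only on the structural rule.
- `expand_and_gates` emits, per target with d inputs, d one-input gates plus
  all AND combinations of 2..`max_and_size` inputs with distinct sources.
  `max_and_size` defaults to 2: pairwise ANDs keep the hypothesis space near
  a hundred parameters for a ~35-species network, and higher-order
  conjunctions are rarely identifiable from single/double-perturbation
  designs.

## Normalization

ΔΔCt: ΔCt = Ct(target) − Ct(reference gene) per sample; ΔΔCt differenced
against the calibrator (control) sample; FC = 2^(−ΔΔCt).  The calibrator
column is exactly 1 by construction.  A sample with a missing reference Ct
is flagged missing, never imputed.  Reference-gene choice is a configuration
input (stability screening is out of scope).

Hill normalization v = fc^h / (m^h + fc^h) with h = 4 for all genes.  The
midpoint is class-specific, classified on the mean fold change of the
IL-6-alone condition across donors (inhibitor conditions do not enter the
classification):

| class | rule | m | control (fc = 1) maps to |
|---|---|---|---|
| downregulated | mean < 1 | 0.5 | 0.941 |
| weakly induced | 1 ≤ mean < 4 | 2 | 0.059 |
| strongly induced | mean ≥ 4 | mean / 2 | ≈ 0 |

The strong/weak boundary (default 4) generalizes the hand-assignment used
for acute-phase versus CYP2E1-like genes; a per-gene override map reproduces
any manual assignment exactly.  h = 4 spreads control values close to the
Boolean resting states while leaving the mid-range sensitive; raising the
down-gene midpoint (e.g. m = 0.7) shifts control values toward 0.8 where a
saturated model cannot follow, which measurably worsens the fit — the test
suite asserts that direction on the benchmark.

Missing cells propagate as missing through normalization and are excluded
from both numerator and denominator of the training MSE.  Control columns
are included as data points: their normalized values anchor each gene's
resting state.

## Training

Genome: one integer locus per candidate gate — 0 = off, otherwise an index
into the discrete grid k ∈ {0.2, …, 1.0}, n ∈ {1, 2, 3, 4, 6} (45 pairs; one
pair per gate, applied to each of its inputs; parameters are counted as
scalars, two per active gate input).  Fitness is the negative MSE pooled
over all donors' cells — a single "mean" model over donors, each non-missing
cell weighted equally.  The GA uses tournament selection (size 3), uniform
crossover, per-locus mutation 0.05, elitism 1, population 50, and stops
after 100 stall generations or 500 generations (tests and the acceptance
script use a 60-generation stall with the family sizes stated there; the
fitted problems are small enough that convergence is reached well before
these caps).  The GA result is then polished by a deterministic
single-locus descent — each locus is moved to its best value while that
strictly improves the fit — because switching one gate off is a
1-in-|grid| mutation proposal the GA alone can miss, and a residual
spurious gate would hand the subsequent reduction step unearned budget.
Fitness evaluation is vectorized across conditions and memoized per genome;
identical seeds give identical results, and family run r uses seed
`base + r`.

Reduction is greedy: repeatedly delete the active gate whose removal yields
the smallest MSE, while MSE(reduced) − MSE(optimized) ≤ threshold (default
0.01).  This guarantees the reduction bound by construction, is
deterministic (ties by gate order), and does not re-optimize transfer
parameters after removals.  Because a larger budget only extends the same
greedy removal sequence, the reduction curve (mean MSE and mean parameter
count versus threshold, over a shared set of GA runs) is monotone.

Consensus: element frequencies are counts over family runs; the consensus
network keeps transitions with frequency ≥ 0.30 (inclusive), weighted by
frequency.

## Statistics

- Hierarchical clustering of log2 fold changes: average linkage (UPGMA) on
  Euclidean distances, rows and columns independently.  Missing cells are
  handled pairwise-complete with the squared distance rescaled by
  total/shared column counts; all-missing rows/columns are dropped with a
  warning.  Dendrograms export to Newick.
- Spearman validation: midranks for ties; two-tailed p by exact permutation
  for n ≤ 8 (full enumeration; beyond that the enumeration buys nothing over
  the approximation) and by the t-approximation
  t = r_s √((n−2)/(1−r_s²)) otherwise.
- Prediction-versus-data tables average the family's simulated states per
  (gene, condition) against donor means ± SD, sorted by absolute deviation
  to surface systematic misfits.
- Grouped t-test: pooled-variance two-sample two-tailed t (Welch by flag);
  degenerate zero-variance inputs raise instead of fabricating a p-value.

## Synthetic benchmarks

`make_benchmark_pkn` builds two annotated networks: a 10-species toy and a
43-species paper-scale network — one stimulus, three perturbable pathway
branches of depth 2–3 (JAK/STAT-like, MAPK-like, PI3K/NF-κB-like), a
transcription-factor layer (RXR/NR-like hub carrying 20 of 30 genes,
NF-κB-like, GR-like, HNF-like), and 30 measured genes: mostly downregulated,
three strongly induced acute-phase genes, none weakly induced (a weak
inducer normalized at m = 2 maps its saturated state to ≈ 0.5, which a
Boolean-valued truth cannot emit consistently; the m = 2 class is exercised
in unit tests instead).  Gene–regulator wiring was chosen so that no two
candidate gates of one target produce identical response patterns across
the 9 conditions — without that, consensus frequencies split arbitrarily
between behaviorally equivalent hypotheses and recovery is undefined rather
than hard.

`sample_truth` draws one active gate per target and grid transfer
parameters (so the fitter's space always contains the truth), then assigns
each gene a true emission midpoint: 0.5 for down-genes, 8 for induced genes,
jittered by a per-gene log2-normal factor (SD 0.5, clipped at ±1.2) so genes
carry individual effect sizes as real panels do.  The experiment design is
the 9-condition inhibitor panel: control; IL-6; IL-6 plus single STAT3/PI3K/
MAPK inhibition; the two tolerated double inhibitions (STAT3+PI3K is absent
by design — it was not experimentally viable); and two inhibitor-only
vehicle controls.

`emit_dataset` clips states to [1e−3, 1−1e−3], inverts the Hill curve at
the gene's true midpoint, multiplies in a per-(donor, gene) log2-normal
random effect (SD 0.25) and per-cell multiplicative lognormal noise
(CV 0.2, σ = √ln(1+CV²)), masks cells missing independently (rate 0.05),
and pins the control column to exactly 1 (it is its own calibrator, so it
carries no noise).  `emit_ct` converts fold changes back to Ct values with a
flat reference gene, so the ΔΔCt stage is exercised end to end.

What the generator does **not** emulate: amplification-efficiency artifacts,
donor-specific network rewiring (all donors share one truth), structured
missingness (real designs measure different condition subsets per donor),
partial inhibitor efficacy, and secondary/feedback dynamics.  Passing the
recovery benchmark therefore shows the estimator is correct and well-posed
under its own assumptions — not that those assumptions hold in any given
wet-lab dataset.  The optional `leaky_stat3_residual` truth variant (STAT3
targets keep 20% output under the STAT3 clamp) reproduces the
characteristic misfit pattern of strongly induced STAT3 targets under
"complete" inhibition.

## Problem sizes used in tests and the acceptance script

Boolean-limit and compression equivalence run on 200 random DAGs of ≤ 10
species with exhaustive clamp enumeration.  GA-versus-exhaustive-search uses
genome spaces up to 46²; topology recovery fits a 20-run family on the
paper-scale benchmark (seed-determined truth, 5 donors, noise CV 0.2) plus a
5-run noise-free family; the sensitivity and curve checks use 4-run
families.  These sizes make the entire suite run in a few minutes on one
CPU while leaving every assertion at full strength.

## Known limitations

- Steady-state only; no ODE or time-course semantics, no feedback.
- One (k, n) pair per gate rather than per input; the discrete grid bounds
  resolution of transfer-function estimates.
- Reduction never re-adds or re-parameterizes gates; it only removes.
- The reduction-curve monotonicity is a property of the greedy prefix
  structure; with pathological data where removals strictly improve the MSE
  mid-sequence, the mean-MSE curve could locally dip.
- The bundled hepatic network is an approximate, curated transcription of a
  published pathway figure and should be treated as an example input.
- Consensus frequencies quantify stability of the optimizer across seeds on
  one dataset, not biological confidence intervals.
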