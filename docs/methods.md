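# Methods

## Model

`nemus` implements a mutation-selection codon substitution model on the 61
sense codons of the universal genetic code (stop codons are excluded from the
state space).  Substitution rates factor into a mutation term and a fixation
probability:

    q_ab = 2 N_p mu * HKY(a -> b) * P_fix(s_ab)        (codon b a single-nucleotide
                                                        neighbour of a; otherwise 0)
    HKY(a -> b) = theta_target * kappa^[transition]
    s_ab = f_b / f_a - 1

with `f` a vector of 20 amino-acid Darwinian fitnesses (19 free, the 20th —
tyrosine in our fixed alphabetical ordering — anchored at 1), `theta` the
nucleotide frequencies, `kappa` the transition/transversion ratio, `mu` the
per-individual mutation rate and `N_p` the effective diploid population size
(default 1e5, fixed across the tree).

The fixation probability is the full diffusion result for a new mutant in a
Wright–Fisher population,

    P_fix = (1 - exp(-2 s)) / (1 - exp(-4 N_p s)),

evaluated **without** the usual log-linearisation of the numerator.  This
makes the generator asymmetric and the substitution process
non-time-reversible, which is the point of the model: a reversible process
cannot represent directional episodes, and its equilibrium dN/dS is bounded
above by 1.  For `|s| < 1e-12` the exact neutral limit `1/(2 N_p)` is used
(the formula is 0/0 there).

A reversible comparison form is provided behind the same interface:
`2 s~ / (1 - exp(-4 N_p s~))` with the antisymmetric log selection
coefficient `s~ = log(1 + s)`.  With the raw ratio-based `s` this shape is
only reversible to O(s^2); the log form satisfies detailed balance exactly
(its stationary distribution is the mutational equilibrium tilted by
`f^(4 N_p)`), which is what the classical linearised-numerator models assume.
The two forms agree to O(s^2), i.e. to ~1e-9 at the fitness scales below.

### Numerical domain

All `1 - e^(-x)` terms go through `expm1`; the naive form loses all precision
at `x ~ 4e-5`.  Fixation probabilities agree with 50-digit arithmetic to
relative error < 1e-8 across the supported band.  Selection coefficients with
`|s| > s_max` (default 2.5e-4) are rejected with an explicit range error:
fitness profiles are drawn and fitted inside `|f - 1| <= 1e-4`, giving
`|s| <= ~2e-4`, and the band is deliberately wider than the simulation draw
width (±5e-5) so that every model the study conditions can produce evaluates
cleanly.  Both bounds are configurable.

The generator is scaled so that one unit of time equals one expected
substitution per site under the *neutral* counterpart model (same `kappa`,
`theta`, `mu`, `N_p`, all fitnesses 1) at its stationary distribution; `mu`
cancels in the scaling.  Branch lengths are therefore in expected neutral
substitutions per site.

Stationary distributions of the (non-symmetric) generator are computed as the
null left eigenvector via a direct linear solve with one equation replaced by
the normalisation, plus one iterative-refinement step.  Under strong
selection the stationary vector spans many orders of magnitude and the chain
is nearly reducible (entry rates into an unfit amino acid scale like
`e^(-4 N_p |s|)`); if the solve leaves negative mass beyond 1e-9 the code
falls back to propagating `exp(Q t)` to large `t`, which is non-negative by
construction.  The public matrix exponential uses scaling-and-squaring Padé
(safe for non-diagonalisable generators).  Inside the likelihood engine,
where the same generator is exponentiated for every branch of a profile at
each optimiser step, a per-profile eigendecomposition propagator is used
instead (one `eig` per profile, one complex matrix product per branch) with a
`cond(V) < 1e8` guard that falls back to Padé.

## Likelihood and fitting

The likelihood is the standard pruning recursion over compressed site
patterns, with per-node rescaling and accumulated log factors against
underflow.  Each branch uses the transition matrix of its *own* model, so
fitness profiles may change along the tree: a shift on branch `b` applies to
`b` and all its descendants until another shift intervenes, and shifts on
both basal branches are disallowed (the root process must persist somewhere).
Root codon frequencies are either the stationary distribution of the root
(base) model or a free 61-vector with 60 free parameters.

Node partials are cached with per-profile version counters: a fit that moves
only one clade's profile recomputes only that clade and its root-ward path.
This is what makes the greedy search's per-branch provisional fits cheap.

Maximisation is bounded quasi-Newton (L-BFGS-B) with finite-difference
gradients — the contract is a derivative-free bounded optimiser, and a Powell
fallback is provided — over transformed coordinates: `log kappa`, additive
log-ratio `theta` (3 free), and fitnesses as `(f - 1) / 1e-5` so a unit step
is a realistic selection increment.  Starting values: fitnesses neutral,
`kappa = 2`, `theta` at observed nucleotide frequencies, root frequencies at
observed codon frequencies.  A fit is reported as failed only when no finite
log-likelihood is found; hitting an iteration cap returns the best recorded
point (the optimiser's terminal point is discarded if a failed line search
left it worse).

Free root frequencies are never handed to the outer optimiser.  For fixed
substitution parameters the log-likelihood is concave in the root
frequencies (each site is a mixture over 61 root states), so they are
profiled out by EM to tolerance 1e-10 inside every objective evaluation,
warm-started from the previous optimum.  A floor of 1e-16 per frequency
keeps every site's mixture likelihood positive.

### Identifiability under weak selection

At `N_p = 1e5` and fitness draws of ±5e-5, population-scaled coefficients
`4 N_p s` reach ±40: amino acids more than a few scaled units below the
fittest are essentially absent at equilibrium.  Their fitness parameters are
then only bounded above by the data — the profile likelihood is flat below
the identifiability threshold — and their estimates remain wherever the
optimiser leaves them (near the neutral start).  Correlation-based recovery
metrics are depressed by exactly these coordinates; this is a property of
the model in this regime, not of the optimiser, and pushing such
coordinates further (longer runs, different optimisers) changes the
log-likelihood by < 1e-3 while moving the estimates arbitrarily within the
flat region.

## Greedy shift search

Starting from the fitted single-model tree, each round proposes a shift on
every branch not already carrying one (and never on the second basal
branch when its sibling is shifted).  For each candidate, the 19 provisional
fitnesses of the new profile are fitted with everything else frozen, and
candidates are ranked by AICc,

    AICc = -2 logL + 2 k + 2 k (k + 1) / (n - k - 1),

with `n` the number of codon columns (the only sample size the likelihood
sees) and `k` the number of free parameters of the whole model: 19 per
profile plus the shared parameters actually freed (`kappa`: 1, `theta`: 3,
free root: 60) counted once.  The shared terms cancel in AICc differences
except through the small-sample correction, so the convention is fixed and
stated.  The best candidate is re-optimised jointly (all free parameters of
the augmented model — a flag restricts this to frequency-type parameters
plus the new profile instead) warm-started at its provisional profile, and
accepted only if the re-optimised AICc beats the incumbent.  Ties break to
the smallest post-order branch id.  The loop stops at the first rejection or
at the shift cap.  Per-branch optimisation failures are excluded from
selection; if every candidate fails the search reports
`optimisation_failure` as its outcome.  A per-parameter penalty coefficient
(default 2, the AICc value) is exposed so sanity checks can drive the search
into never accepting a shift.

Provisional fits run with a reduced iteration budget: they only rank
branches, and the winner is re-polished jointly.  The gap between the best
and second-best branch is typically hundreds of log-likelihood units at
these signal sizes, so the ranking is insensitive to this budget.

## Simulator

The simulator generates the full study designs end to end.

**Trees** come from a pure-birth process in which a lineage that has
undergone `d` speciation events splits at rate `birth_rate * exp(-balance *
d)`.  `balance = 0` is the constant-rate Yule process (verified against the
exact Colless-index recursion); positive values slow much-split lineages
(more balanced trees), negative values accelerate them (more imbalanced).
The named regimes map BAL -> +0.5, BDP -> 0.0, IMB -> -0.5.  Only the three
qualitative regimes are meaningful — the knob's scale is this package's own
and is not comparable to other tree simulators' balance parameters.  The
clock runs one further exponential waiting time after the target tip count
is reached, so pendant branches are positive and tree age is not fixed.

**Fitness profiles** draw their 19 free entries i.i.d. Uniform(1 - 5e-5,
1 + 5e-5).  **Shift placement** is two-stage uniform: first a node level
(edge distance from the root) among occupied levels, then a node uniformly
within the level; the branch above the node carries the shift.  This spreads
shifts over time depths rather than over branches.  **Root frequencies** for
the non-equilibrium design are symmetric Dirichlet over the 61 codons with
concentration 1 (uniform on the simplex) by default — the least-informative
choice, configurable.

**Sequences** evolve site-independently: the root codon is drawn from the
configuration's root frequencies (the base model's stationary distribution
in equilibrium mode), then each branch evolves every site under its own
scaled generator by exact CTMC (Gillespie) simulation; an `exp(Q t)`-row
sampling mode is provided and the two are statistically indistinguishable at
the tips.  Blocks are archived as FASTA + Newick + truth JSON + a manifest
TSV, with per-replicate streams spawned from one master `SeedSequence` so an
archive is byte-reproducible from (spec, seed).

What the simulator does *not* emulate: indels, rate variation across sites,
site-specific fitness profiles, multi-nucleotide mutations, non-ultrametric
trees.  Passing tests therefore demonstrate recovery when the inference
model matches the generating process (the study's own design), not
robustness to these violations.

## Evaluation

Outcome labels against simulation truth: `correct_only`,
`correct_plus_false`, `incorrect_only`, `optimisation_failure`,
`none_returned` (and `true_negative` / `false_positive` when the truth has
no shift).  "Correct branch" means exact identity of the child-node branch
id; adjacent branches count as incorrect.  Fitness recovery is the Pearson
correlation over the 19 free relative fitnesses (anchor excluded), on the
natural scale; root-frequency recovery drops the constrained 61st
coordinate (n = 60).  The error fold change is
`RMSE(fit ignoring root frequencies) / RMSE(fit modelling them)`, both
against the true free fitnesses.  Shift ages are measured at the shift
branch's child node as (max root-to-leaf path) - (root-to-node path), a
convention that stays defined on non-ultrametric trees.

## Problem sizes in the shipped checks

The full study (12 blocks x 20 replicates at up to 900 codons, plus 15
co-estimation cells x 10 replicates) is many CPU-hours.  The test suite and
`scripts/acceptance.py` run scaled-down versions chosen to finish in minutes
on one CPU while keeping each check's logic identical to the full protocol:

- shift detection / parameter recovery: 5 replicates (tests; 4 in the
  script) of the 10-taxon, 300-codon, one-shift condition, greedy search
  with a cap of two shifts.  The detection threshold scales the
  full-design 14-of-20 recovery rate to the integer floor at n = 5 (>= 3).
- false positives: 3 replicates (2 in the script) of the 20-taxon no-shift
  condition; at a 1-in-20 false-positive rate, two or more false positives in
  three replicates would be a < 1% event.
- root-frequency co-estimation: 3-replicate cells (20 taxa, 300 codons) at
  birth rates 0.5 and 10, birth-death balance.
- the exact-numerics checks (fixation oracle, pruning vs dense enumeration,
  stationarity, detailed balance, simulator stationarity) run at full
  precision; they are cheap.

## Known limitations

- One fitness profile for all sites; the method is not meant for data where
  site-specific selective histories dominate.
- The weak-selection identifiability floor described above: fitnesses of
  effectively-absent amino acids are one-sided, and correlation metrics
  treat their estimates as point values.
- Free-root co-estimation here profiles the 60 frequencies by EM at every
  step, which is a stronger optimiser than general-purpose boxed search in
  60 dimensions; root-frequency recovery is therefore stronger than what
  general-purpose boxed optimisation over the 60 frequencies achieves,
  particularly on short (high birth-rate) trees.
- The balance knob reproduces regimes, not any published parameter scale;
  tree ages at a given birth rate follow the plain pure-birth expectation.
- Branch lengths and topology are taken as given; no rescaling, rerooting
  or branch-length estimation (a global branch-length multiplier is exposed
  on the CLI for trees calibrated in other units).
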