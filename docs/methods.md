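# Methods

This note records the precise definitions the package implements, the
conventions chosen where the framework leaves freedom, and what the test
fixtures do and do not establish.

## Causal model

A universe is a complete interventional causal model of n binary units:
a state-by-node TPM of conditional probabilities p(u′_i = 1 | do(u)),
2^n rows in little-endian state order (first listed unit varies fastest —
the convention used by the established IIT software, kept for
interoperability).  Conditional independence of unit updates is assumed
(no instantaneous causation), so the state-by-state TPM is the per-unit
product; expansion and per-unit marginal extraction are exact inverses.
Probabilities are stored only as p(u′_i = 1 | u): for binary units this
is lossless.  Row-stochasticity is checked at absolute tolerance 1e-12,
appropriate because all fixture inputs are exact decimals.

Non-binary micro units, continuous time, and non-stationary TPMs are out
of scope.

## Micro-grain conditioning

For a candidate system S with background W = U \ S, conditional on the
current universe state u:

* effects: the background is clamped at its current state (a point-mass
  background distribution);
* causes: the past background state is inferred by Bayes' rule with a
  uniform marginal over prior universe states,
  q_c(w|u) = Σ_s̄ p(u | s̄, w) / Σ_ū p(u | ū).

Per-unit transition probabilities are averaged over background states
first and then recombined as a product over system units, which restores
conditional independence.  A current state that is unreachable from every
prior state makes the cause side undefined; this raises an error rather
than falling back to a uniform distribution, because the intended inputs
all carry indeterminism (every probability strictly inside (0,1)) and a
zero denominator signals a modeling mistake.

## System integrated information

Both directions start from the selected cause/effect state of the intact
system.  Intrinsic information is selectivity × informativeness:

* effect: ii_e(s, s′) = p_e(s′|s) log₂[p_e(s′|s) / p_e(s′)], where
  p_e(s′) is the unconstrained probability of s′ — the column mean of
  𝒯_e, i.e. the system perturbed uniformly into all its states;
* cause: selectivity is the Bayesian posterior p_c(s′|s) =
  𝒯_c[s′,s]/Σ_s̄ 𝒯_c[s̄,s]; informativeness compares the forward
  probability 𝒯_c[s′,s] with its unconstrained counterpart (the column
  mean of 𝒯_c).

Ties in the selected state break toward the lowest state index.  Logs are
base 2; φ values are bits.  0·log 0 is 0.

**Partitions.**  A directional system partition splits S into k ≥ 2 parts
and, for each part, severs its inputs from the rest, its outputs to the
rest, or both; severed connections are noised by uniform marginalization
of the severed sources, per target unit.  Duplicate severed-edge sets are
enumerated once.  A single unit has exactly one partition — complete
noising of its self-input — so single units can still be irreducible.

**Minimum partition and φ_s.**  For each partition, the integrated
information per direction is the intact selectivity times the log-ratio of
intact to partitioned probability of the selected state, floored at zero,
and the partition's value is the minimum over the two directions.  The
minimum partition minimizes this value *per severed connection*; among
partitions with equal normalized value the one severing the most
connections is taken (the union of tied minimal cuts), and the reported
φ_s is the unnormalized value there.  This normalization and tie rule is
part of the package's definition of φ_s: with it, a symmetric two-unit
system's φ_s equals the value at the full bipartition rather than at
either single-edge cut, and the same holds for the symmetric four-unit
fixtures.  Exact φ comparisons elsewhere use absolute tolerance 1e-10;
comparisons against three-decimal published values use 5e-4.

φ_s ≥ 0 always, and φ_s = 0 exactly when some partition leaves both TPMs
unchanged, as for a system whose TPM factorizes.

## Units and mappings

A unit is the 5-tuple (U^J, V^J, τ′, g′, W^J).  Constituents may be micro
units or finer-grain units; their micro constituents must be disjoint and
their apportionments must nest inside the parent's.  Mappings are complete
binary truth tables over sequences of constituent states, earliest state
least significant, enumerated in truth-table-integer order; constant
tables are rejected (a unit must be able to attain both its states).  The
micro update grain τ multiplies down the hierarchy, and the composed
micro-grain mapping is obtained by evaluating each level on its trailing
windows.  Constituents with unequal micro grains are rejected rather than
resampled: the sequence machinery indexes all units of a system with a
single τ, and supporting heterogeneous unit *sizes* but a common τ covers
every fixture of interest.  Mapping enumeration refuses more than 16
input sequences unless explicitly overridden (the table count is
2^(2^(τ′·k)) − 2).

## Macro cause/effect TPMs

Four steps per unit J of the system, at the system's common grain τ:

1. **Discounting.**  Modified per-unit probabilities p̂_J: constituents of
   J keep all inputs; other system constituents and unapportioned
   background are fully noised (uniform average over all states); a
   micro unit apportioned to unit K keeps inputs from U^K ∪ W^K only.
   This prevents one unit's micro constituents from mediating another
   unit's effects, and prevents a background unit from mediating for two
   different units.  Full noising is idempotent.
2. **Sequences.**  The modified TPM is chained into probabilities of
   sequences of τ micro updates (Markov products).
3. **Background marginalization.**  Effects condition on the current
   background state; causes weight the background state τ updates back by
   Bayes from the earliest state in the current τ-window (uniform prior),
   which by the Markov property is the only state that matters.  The
   current macro state therefore requires a trailing history of at least
   τ micro states, enforced with an error naming the required length.
4. **Compression.**  Sequence probabilities are summed into per-unit
   macro outcome probabilities; rows are re-expressed over macro states by
   perturbing the system uniformly over all micro-state sequences mapping
   to each macro state (the occupancy weights r count sequences, not
   dynamical frequencies); per-unit results recombine as a product.

With τ = 1 and identity mappings, steps 1, 2 and 4 are trivial and the
macro TPMs equal the micro TPMs entrywise (verified at 1e-12 over seeded
random universes).  Sequence spaces above 2^20 states are refused.

## Admissibility and complexes

A candidate unit's constituent system must be *maximally irreducible
within*: φ_s > 0 and strictly greater than φ_s of every valid competitor
system over subsets of its micro constituents, at grains up to its own,
with backgrounds drawn from non-overlapping subsets of its apportionment.
Candidate systems are enumerated recursively (micro units → systems →
admissible constituent sets → new units with every non-constant mapping →
new systems) until convergence or the depth cap.  Complexes are selected
greedily by maximal φ_s with overlap exclusion; strict inequalities use
tolerance 1e-10, and exact ties are broken canonically (larger
micro-constituent set, then label order) and flagged in the report, since
the framework itself does not define tie handling.

Search defaults are deliberately conservative: universes up to 6 micro
units, update grain τ = 1, one level of macro units, at most 4
constituents per unit.  All caps are overridable.  The default sweep stays
at τ = 1 because mapping tables over two constituents at τ′ = 2 already
number 2^16 − 2, i.e. tens of thousands of φ evaluations per constituent
set; the scientific scenarios the package ships (and their published
values) are all τ = 1 sweeps, while τ > 1 analyses are supported through
explicit unit definitions.

Background apportionment is found by exhaustive assignment of each
background unit to one system unit or to none, maximizing φ_s.  At τ = 1
apportionment cannot change the result (one micro update gives background
units no opportunity to mediate), which the optimizer's canonical
tie-break (all-unapportioned first) respects.

## Example fixtures and what they show

The bundled universes are exact parametric reconstructions of published
didactic systems: the two-unit noisy-AND pair, the 2×2 grid with weak
self/horizontal couplings and a strong vertical-AND drive, and the grid
family with tunable vertical coupling (0, 0.01, 0.25).  Additive rules
reject any parameter set that would leave [0,1] — clipping would silently
change the model.  The eight-unit mirror-symmetric OR/COPY network is a
*synthetic structural stand-in*: its wiring follows the published
topology but its numeric strengths are free parameters, so it is used
only for structural and symmetry tests, never for numeric checks.

Seeded random universes draw every probability uniformly from
[floor, 1 − floor] (default floor 0.05), guaranteeing indeterminism and
reachability.  They emulate nothing about real neural data — no sparsity,
no modularity, no degeneracy structure — so passing property tests
establishes internal consistency of the computations, not behavior on
realistic substrates.

Problem sizes in the test suite and reproduction script: universes of 1-4
units, grains τ ≤ 2, 100-seed property sweeps; every check is exact
enumeration, no sampling.

## Known limitations

* The expectation that a single unit's φ_s can never peak at a coarser
  update grain holds for 98 of 100 seeded random one-unit universes but
  fails for rare cases (margins around 5%), where a sequence-detector
  mapping ("on iff the unit just switched off") yields a sharper macro
  TPM than the one-step unit.  The compounding-indeterminism argument
  behind the expectation implicitly assumes mappings that track the
  unit's final state; arbitrary sequence mappings can evade it.  The
  corresponding acceptance test asserts the expectation as stated and
  currently fails on those seeds; the construction itself has been
  cross-checked against an independent hand enumeration to machine
  precision.
* The search is exhaustive and doubly exponential; it is a desk-scale
  instrument, not a scalable screen.
* Systems mixing units of different update grains are rejected rather
  than approximated.
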