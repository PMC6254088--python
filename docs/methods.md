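# Methods

This note documents the semantics implemented by `mvlogic`, the
numerical and design choices that were genuinely open, what the random
fixture generator does and does not emulate, and the known
limitations.

## Model semantics

A model is an ordered list of components, each with an activity range
`[0, m]` (`m ≤ 9`, so states serialise as digit strings) and one
logical function given as rows `(target_level, condition)`. Conditions
are expression trees over threshold literals: `c:t` holds iff
`level(c) ≥ t`, a bare `c` abbreviates `c:1`, and `!c:t` negates the
whole literal. The target value in a state is the target level of the
unique satisfied row, or 0 when none holds. Row conditions of one
component must be pairwise mutually exclusive; this is checked
symbolically at construction time (conjunction of row-condition
diagrams), and overlap is a hard error — the formalism defines no row
precedence, so accepting overlaps would silently change semantics.

**Unit steps.** A called multi-valued component moves exactly one
level toward its target per transition. This is forced by the
synchronous dynamics of the bundled p53-Mdm2 model, whose printed
trace climbs p53 through 0 → 1 → 2 over two transitions even though
the target is 2 throughout.

**Canonical form.** Every function is also normalised to a reduced
ordered multi-valued decision diagram (MDD, `_mdd.py`), with variables
ordered by component declaration. The diagrams drive validation,
regulator inference, fixed points, trap spaces, and reduction; the
original expression text is retained so that serialisation round-trips
preserve hand-written rules.

**Regulator inference.** `r` regulates `i` iff the target diagram of
`i` depends on `r`; the sign is `+`/`−` when the target is monotone
non-decreasing/non-increasing across every adjacent pair of `r`
levels, `±` otherwise. A brute-force dependency scan over state pairs
is kept as the test oracle.

## Updating modes

* *Synchronous*: all called components step at once.
* *Sequential*: one pass in a fixed order, each rule evaluated on the
  evolving state. Note that a state with a single called component is
  **not** generally mapped to its synchronous successor: the lone step
  can trigger further calls later in the same pass. The identity holds
  exactly when the called component is ordered last.
* *Block-sequential*: ordered blocks, synchronous within a block,
  evaluated on the state left by the previous block. One block ≡
  synchronous; singleton blocks ≡ sequential.
* *Synchronous priority*: calls are evaluated once, on the original
  state; the first class containing a called component fires
  synchronously. Whether calls should be re-evaluated between classes
  within one step is not fixed by the formalism; evaluating once was
  chosen for determinism and simplicity.
* *Asynchronous*: one successor per called component; *complete*: one
  successor per non-empty subset of the called set, deduplicated
  (a state-transition graph is a set of transitions, so two subsets
  reaching the same state contribute one arc); *priority classes*:
  per-class synchronous or asynchronous mode.
* *Stochastic*: uniform over the base updater's successors. Weighted
  selection is defined only over the asynchronous base — an
  asynchronous successor's probability is proportional to its stepped
  component's positive rate; no published scheme covers
  multi-component transitions, so other bases stay uniform. All
  randomness flows through one explicit seed (default 0, never
  wall-clock), making every run reproducible.

Traces stop at a stable state, on the first revisit of a previous
state (the repeated state is not re-appended; the cycle entry index
and hence the cycle length are recorded), or at the step limit
(default 1000 for deterministic traces, 10,000 for random walks —
generous for desk-scale models while bounding runaway simulations).
The STG builder explores the reachable closure of an initial set (or
the full state space) with a configurable cap of 2^16 states; it is an
explicit-state oracle for the symbolic analyses, not a scalable
engine.

## Static analyses

**Fixed points.** Per component the stability condition
`f_i(x) = x_i` is built as a Boolean-valued MDD and all conditions are
conjoined; satisfying states are enumerated lexicographically from the
diagram. No state sweep is involved, so the method scales with diagram
size rather than state count. An exhaustive sweep (cap 2^20 states) is
the independent oracle.

**Trap spaces.** Computed on the booleanized model and reported over
booleanized component names (multi-valued levels decompose into
sub-components, so a pattern can pin part of a component's range). A
pattern is a trap space iff for each of its fixed literals `(v, b)`
the rule of `v` restricted to the pattern is constantly `b`. The
search is a constraint-propagation DFS: starting from the all-free
pattern, a candidate literal is added and made *supported* by
branching over the prime implicants of the corresponding rule value
(computed recursively on the diagrams); each implicant's literals are
merged and the propagation repeats until the pattern is closed or
contradictory. Minimal trap spaces are exactly the closed patterns
admitting no further refinement; when no proper trap space exists the
single all-free pattern is returned. The 3^n pattern enumeration with
explicit state sweeps is the independent oracle. Admissibility was
examined rather than enforced: because the booleanization drains
non-admissible states, minimal trap spaces of booleanized models are
admissibility-consistent in all tested cases, so no extra intersection
step is applied.

**Ordering.** Stable states and trap-space rows are emitted in
lexicographic order, with free entries sorting after 1.

## Model modifications

* *Fix* replaces a rule by a constant; *range* clamps every target
  into `[lo, hi]` (adding a row that lifts the implicit default 0 to
  `lo` when `lo ≥ 1`). Range restriction clamps the target function,
  not the state space, and the declared maximum level is retained —
  levels above the range simply become unreachable targets.
* *Interaction removal* substitutes the regulator's **inactive level
  0** into the target's rule (`reg:t` ↦ false). Substituting the
  maximal level instead would destroy the oscillatory trap space of
  the p53 case study's repair-impaired mutant; level 0 reproduces its
  behaviour and matches the biological reading (the regulator no
  longer acts on this target). Removing a non-regulator warns and is a
  no-op.
* *Booleanization* uses the stepwise rule
  `v_bi ← ([target(v) ≥ i] & v_b(i−1)) | (v_bi & v_b(i+1))` with
  `v_b0 = 1`, `v_b(m+1) = 0`, where `target(v)` is evaluated on
  count-decoded levels (a non-admissible state decodes to the number
  of active sub-components; any decoding agreeing on admissible states
  would do, and this one lets non-admissible states drain). The
  construction is validated by the tested properties — state
  bijection, transition correspondence, drainage of non-admissible
  states, admissibility of all attractors — rather than assumed
  identical to any particular published implementation.
* *Reduction* eliminates components one at a time, in the requested
  order; eliminating a self-regulated component is an error (detected
  semantically, at the time of its elimination). The substituted
  conditions are taken from the **canonical diagrams**, not the
  written rows: a rule may cite a component syntactically while being
  semantically independent of it, and raw textual substitution would
  re-introduce the eliminated component. Removed components keep a
  derived rule over the kept components (their expected level) but
  take no part in dynamics or state strings. Output reduction
  iterates over components regulating no other component, skipping
  self-regulated ones (an oscillating output has no well-defined
  elimination); fixed-value propagation substitutes semantically
  constant components to a fixpoint. Reduction preserves stable states
  (projections onto the kept components), which the tests verify on
  every legal single elimination of the fixture models.

## Formats

`mnet` infers each component's maximum from its assigned target levels
and the thresholds citing it; a writer emits one line per row plus, if
needed, a `name:m <- 0` witness line so the inferred maximum survives
round trips. Components that are referenced but never assigned are
errors (inputs must be written `x <- x`); `#` comments and blank lines
are accepted; duplicate rows with the same target merge by OR. The
`tt` dialect is: a header of component names, then one
`input target` digit-string pair per state, complete and in
lexicographic order; parsing validates completeness and functional
consistency and reconstructs compact rule rows from the table's
diagrams. The `bnet` header `targets, factors` is optional on input
and always emitted. All writers end with a trailing LF newline.

## Fixture generator

`generate.random_model` draws, per component, a maximum level and one
random guard expression per level; row conditions are made mutually
exclusive by construction with a priority encoding (the row for level
k is guarded by the negation of all higher-level guards), and the row
at the maximum level is always present syntactically so serialisation
round trips preserve ranges. Default fixture sizes (2–6 components,
maxima ≤ 3) keep exhaustive state sweeps and 3^n pattern enumerations
fast; the property suites use 200 models for the fixed-point oracle,
100 Boolean models (≤ 8 components) for the trap-space oracle, and
full STG comparisons for booleanization. The generator emulates the
*structure* of curated models (sparse rules, small ranges, mixed
signs) but not their biological organisation — no scale-free
topology, no biased truth densities, no curated mutual-exclusivity
idioms — so passing tests certify the algorithms' correctness on the
formalism, not calibration to any particular biological corpus.

## Known limitations

* Cyclical and complex attractors are only approximated by minimal
  trap spaces; no completeness claim is made (attractors that do not
  correspond to a stable pattern are missed by design).
* The trap-space DFS memoises visited patterns and can, on
  pathological models whose every pattern is a trap space (e.g. pure
  identity rules), visit up to 3^n patterns; it is intended for
  desk-scale models.
* Logical rules are deterministic: one target value per state.
  Transitions updating several components as a single named event are
  out of scope.
* Weighted stochastic updating covers the asynchronous base only.
* The explicit STG builder is capped (2^16 states) and meant as an
  oracle, not as an analysis engine for large models.
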