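# mvlogic

A Python toolkit for **multi-valued logical models** of biological
regulatory networks: loading and saving models in several text
formats, transforming them (perturbations, reduction, booleanization),
simulating them under a comprehensive choice of updating modes, and
statically identifying their attractors.

It is aimed at systems biologists and methodologists who work with
logical (qualitative) models — Boolean networks and their multi-valued
generalisation — and need a scriptable library plus a small
command-line tool for everyday model manipulation and analysis.

## The formalism

A model is an ordered list of components `x_1 … x_n`, each with a
finite activity range `x_i ∈ {0, …, m_i}` (`m_i = 1` for Boolean
components) and a logical rule `f_i` giving the **target value** of
`x_i` as a function of the current state `x = (x_1, …, x_n)`. Rules
are written as rows `target_level ← condition` over threshold literals
(`c:t` is true iff `x_c ≥ t`; a bare `c` means `c:1`) combined with
`!`, `&`, `|`; the target is 0 when no row condition holds, and row
conditions must be mutually exclusive.

* A component is **called to update** in state `x` when
  `f_i(x) ≠ x_i`; dynamics use **unit steps** — a called component
  moves one level toward its target per transition.
* **Updating modes** decide which calls fire together: deterministic
  (synchronous, sequential, block-sequential, synchronous priority),
  non-deterministic (asynchronous, complete, priority classes), and
  stochastic (uniform or rate-weighted random choice).
* **Stable states** (`f(x) = x`) are identical under every updating
  mode. They are computed symbolically by conjoining the per-component
  stability conditions `f_i(x) = x_i` as decision diagrams — no state
  enumeration.
* **Minimal trap spaces** approximate complex attractors: a pattern
  (partial assignment over the booleanized components) is a trap space
  when the synchronous image of every covered state stays inside it.
  They are computed by a prime-implicant constraint-propagation
  search, and independently by brute force on small models.
* **Booleanization** maps a multi-valued component of maximum `m` to
  `m` ordered Boolean sub-components `v_b1 … v_bm`; admissible Boolean
  states (`v_b1 ≥ … ≥ v_bm`) correspond one-to-one to multi-valued
  states, transitions correspond under the bijection, and no attractor
  contains a non-admissible state.
* **Regulatory interactions** are recovered from the rules:
  `r` regulates `i` (sign `+`, `−` or `±`) according to the monotone
  dependence of `f_i` on `x_r`.

Supported formats: `mnet` (multi-valued rules), `bnet` (BoolNet
dialect), `boolfunction` (Boolean rule lines), and `tt` (explicit
truth table), dispatched by file extension; saving a multi-valued
model to a Boolean-only format booleanizes it automatically.

## Worked example: the p53-Mdm2 DNA-damage network

The bundled four-component model couples DNA damage, the transcription
factor p53 (ternary), cytoplasmic Mdm2 (ternary) and nuclear Mdm2:

```
DNAdam <- DNAdam & !p53:2
p53:2 <- !Mdm2nuc
Mdm2cyt:1 <- !p53:2
Mdm2cyt:2 <- p53:2
Mdm2nuc <- Mdm2cyt:2 | (Mdm2cyt & !p53 & !DNAdam)
```

Write it to `p53.mnet` (or use `mvlogic.P53_MDM2_MNET`) and ask for
the stable states:

```
$ mvlogic p53.mnet -r fixpoints
DNAdam p53 Mdm2cyt Mdm2nuc
0011
```

The single stable state `0011` is the resting state: no damage, p53
off, basal cytoplasmic Mdm2, nuclear Mdm2 present. The `trapspace`
tool confirms it is the only attractor (one fully fixed minimal trap
space over the six booleanized components):

```
$ mvlogic p53.mnet -r trapspace
DNAdam p53_b1 p53_b2 Mdm2cyt_b1 Mdm2cyt_b2 Mdm2nuc
0 0 0 1 0 1
```

Adding DNA damage to the resting state (`1011`) and simulating
synchronously shows the repair excursion — p53 rises to full activity,
damage is repaired, Mdm2 re-accumulates, and the system returns to
rest:

```
$ mvlogic p53.mnet -r trace -i 1011
1011
1010
1110
1210
0220
0221
0121
0011
```

Perturbations are compact tokens after `-m perturbation`. A full p53
knockout leaves the damage unrepairable, creating a second stable
state `1010`:

```
$ mvlogic p53.mnet -m perturbation p53%0 -r fixpoints
DNAdam p53 Mdm2cyt Mdm2nuc
0011
1010
```

Removing only the p53→DNAdam repair interaction instead keeps the
resting state as the unique fixed point but creates an oscillating
complex attractor, visible as a second, partially free trap space:

```
$ mvlogic p53.mnet -m perturbation p53:DNAdam%0 -r trapspace
DNAdam p53_b1 p53_b2 Mdm2cyt_b1 Mdm2cyt_b2 Mdm2nuc
0 0 0 1 0 1
1 - - 1 - -
```

The same operations are available as library functions
(`fixpoints(model)`, `trapspaces(model)`, `trace(...)`,
`apply_fix(...)`, `reduce(...)`, `booleanize(...)`, …), which is the
recommended interface for scripted analyses.

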