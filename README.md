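# crnregions

Partition the rate-constant space of a mass-action chemical reaction
network into regions of **monostationarity** (every stoichiometric
compatibility class contains exactly one positive equilibrium) and
**multistationarity** (some class contains at least two), using exact
symbolic computation throughout.

## The idea

A reaction network with stoichiometric matrix `N` (rank `s`) and
mass-action rates `v(x; κ)` evolves by `x' = f(x) = N v(x)`.  Linear
combinations `W x` with `W N = 0` are conserved, so trajectories live in
*stoichiometric compatibility classes* `P_c = {x ≥ 0 : W x = c}`.
Replacing the redundant components of `f` by the conservation equations
gives a square system `φ_c(x)` whose positive zeros are the equilibria
in `P_c`, with Jacobian `M(x)`.

For **dissipative** networks without **boundary equilibria**, a
Brouwer-degree argument pins down the equilibrium count from one sign:

- if `sign det M(x) = (−1)^s` at every positive `x` (or every positive
  equilibrium), each class has exactly one positive, non-degenerate
  equilibrium;
- if a positive equilibrium has `sign det M = (−1)^{s+1}`, its class
  contains at least two positive equilibria.

The tool runs a seven-step procedure:

1. **Structure** — `N`, rank `s`, row-reduced conservation basis `W`.
2. **Dissipativity** — an exact LP searches for a strictly positive
   conservation relation (conservativity); otherwise a user-supplied
   certificate vector `ω` is validated syntactically on `ω·f`.
3. **Boundary equilibria** — all minimal siphons are enumerated and
   each must support a non-negative conservation relation.
4. **Determinant** — `det M(x)` is expanded exactly over `ℚ[κ, x]`.
5. **Determinant signs** — if every coefficient has sign `(−1)^s`, done:
   unique equilibrium per class for all rate constants.
6. **Parameterization** — a *non-interacting* (or reactant-non-
   interacting) set of `s` species is solved from the equilibrium
   equations, giving a positive rational map `Φ(x̂)` onto the positive
   equilibrium variety.
7. **Region certificate** — the coefficients of
   `a(x̂) = det M(Φ(x̂))` are classified against `(−1)^s`.  Non-strict
   inequalities on the sign kernels give the uniqueness region; strict
   opposite-sign inequalities at **Newton-polytope vertices** (decided
   by exact rational LP) give multistationarity regions, each with an
   explicit verified witness `(κ, x̂, c = WΦ(x̂))`.

Everything feeding a certificate is exact: rational linear programming
(a built-in fraction simplex), fraction-free determinants, and rational
evaluation of witnesses.  A seeded multi-start numeric solver is
included only as an independent cross-check oracle.

## Worked example

The hybrid histidine kinase network, via the CLI:

```
crn-regions analyze HYBRID
```

```
# Parameter-region analysis

## Network

X1 -> X2 [k1]
X2 -> X3 [k2]
X3 -> X4 [k3]
X3 + X5 -> X1 + X6 [k4]
X4 + X5 -> X2 + X6 [k5]
X6 -> X5 [k6]

## Procedure

1. **structure** — ok: rank s = 4, conservation relations d = 2
2. **dissipativity** — ok: conservative, omega = (1, 1, 1, 1, 1, 1)
3. **boundary equilibria** — ok: minimal siphons {X1, X2, X3, X4}, {X5, X6} all support conservation relations
4. **determinant** — ok: det M expanded: 7 x-monomials
5. **determinant signs** — ok: coefficients of both signs possible; continuing with a positive parameterization
6. **parameterization** — ok: solved {X1, X2, X3, X6} (reactant_non_interacting) in terms of the rest
7. **region certificate** — conclusive: unique positive equilibrium per class iff k1 - k3 >= 0; multistationary if k1 - k3 < 0

## Outcome

unique positive equilibrium per class iff k1 - k3 >= 0; multistationary if k1 - k3 < 0

### Multistationarity witnesses

- under `k1 - k3 < 0`: kappa = (k1=1, k2=1, k3=2, k4=1, k5=1, k6=1), x̂ = (16, 16), class c = (4496, 2320)
```

The rate-constant space is *completely* partitioned by the single
inequality `k3 > k1` (phosphorylation of the first site is faster when
the second site is occupied).  The same analysis is available as a
library:

```python
from crnregions import run_procedure

trace = run_procedure("""
    X1 -> X2
    X2 -> X3
    X3 -> X4
    X3 + X5 -> X1 + X6
    X4 + X5 -> X2 + X6
    X6 -> X5
""")
print(trace.certificate.summary())
# unique positive equilibrium per class iff k1 - k3 >= 0; multistationary if k1 - k3 < 0
```

Manual inputs for the steps the automatic checks cannot decide (a
dissipativity vector when the network is not conservative, or an
explicit species set to solve for) are passed as `omega=` / `split=` to
`run_procedure`, or `--omega` / `--split` on the CLI.

## Input format

Reaction lists, one reaction per line (or `;`-separated):

```
A + K <-> AK   [kon1, koff1]   # reversible, named rate constants
AK -> Ap + K   [kc1]
2 X2 -> 2 X1                   # integer coefficients: "2 X", "2*X" or "2X"
X1 -> 0                        # empty complex
```

Unnamed rate constants are auto-named `k1..kℓ` in reaction order; a
reversible arrow expands into two irreversible reactions.

## Built-in networks

`crnregions.fixtures()` returns six benchmark networks — `RUNNING`
(two-species toy), `TWOCOMP` (two-component system), `HYBRID` (hybrid
histidine kinase), `GENE` (gene transcription with dimerization),
`MOTIF1`/`MOTIF2` (one-site two-substrate and two-site phosphorylation
cycles) — usable by name on the CLI.  For the motifs, conditions are
also reported in catalytic/Michaelis–Menten constants
(`kc = kcat`, `kM = (koff + kcat)/kon`); e.g. the two-site motif yields
unique equilibria when `b1 ≥ 0 ∧ b2 ≥ 0` and multiple when `b1 < 0`,
with `b1 = kc1·kc4 − kc2·kc3` and
`b2 = kc1·kc4(kM2 + kM3) − kc2·kc3(kM1 + kM4)`, while
`b1 ≥ 0 ∧ b2 < 0` remains undecided.

## Limitations

- Mass-action kinetics (plus rational-function kinetics for the
  determinant sign analysis); no stability or bifurcation analysis.
- The procedure is sufficient, not complete: it may end *indecisive*
  (e.g. no structural variable split exists, or a sign kernel is only
  opposite-capable at non-vertex exponents), never wrong.
- Symbolic determinants limit practical network size to a few tens of
  species.
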