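# Methods

This document records the mathematics implemented by `crnregions` and
the precise decision rules used where theory leaves freedom.

## Networks and classes

A reaction network on species `X1..Xn` is a list of reactions
`R_j: Σ_i α_ij X_i → Σ_i β_ij X_i` with non-negative integer
coefficients.  Its stoichiometric matrix is `N = β − α` (species ×
reactions), with rank `s` and corank `d = n − s`.  Mass-action kinetics
assigns `v_j(x) = κ_j Π_i x_i^{α_ij}` and the dynamics
`x' = f(x) = N v(x)`.

Rows of any `W` with `W N = 0` are conservation relations; the tool
canonicalizes `W` to reduced row-echelon form of a left-kernel basis,
making the pivot indices `i_1 < … < i_d` deterministic.  The
stoichiometric compatibility classes are `P_c = {x ≥ 0 : W x = c}`;
networks with `d = 0` are rejected (the procedure has nothing to
partition over).

## The sign criterion

Since `W f(x) ≡ 0`, replacing components `i_1..i_d` of `f` by
`(W x − c)` yields the square system

```
φ_c(x)_i = (W x − c)_r   if i = i_r (pivot row),
φ_c(x)_i = f_i(x)        otherwise,
```

whose positive zeros are exactly the equilibria in `P_c`.  Its Jacobian
`M(x)` does not depend on `c`.  For a **dissipative** network with no
**boundary equilibria** in any class with non-empty interior, the
Brouwer degree of `φ_c` on the interior of `P_c` equals `(−1)^s`, and
therefore:

- **(A)** if `sign det M(x) = (−1)^s` for all positive `x`, each class
  with non-empty interior contains exactly one positive equilibrium,
  and it is non-degenerate;
- **(B)** if some positive equilibrium `x*` has
  `sign det M(x*) = (−1)^{s+1}`, the class of `x*` contains at least
  two positive equilibria (at least three if all are non-degenerate).

`det M(x)` is computed exactly over `ℚ[κ, x]` with sympy's
`DomainMatrix` fraction-free elimination.  For rational-function
kinetics `v_j = p_j/q_j` with certified-positive `q_j`, the determinant
is `p(x)/q(x)` with `q = Π q_j² > 0`, and the analysis proceeds on the
numerator.

## Preconditions (steps 2–3)

**Dissipativity.**  The network is *conservative* iff a strictly
positive left-null vector of `N` exists; this is decided by an exact
rational LP (maximize the minimum entry of `yᵀW` under an L1
normalization, two-phase simplex over `fractions.Fraction` with Bland's
rule).  Conservative networks are dissipative (classes are compact).
Otherwise, a user-supplied strictly positive `ω` is validated as a
dissipativity certificate: the residual `ω·f(x)` must (i) be non-zero,
(ii) contain unbounded species only in negatively-signed monomials,
and (iii) contain at least one such negative monomial — so the residual
is eventually negative far from the region bounded by the non-negative
conservation relations.  "Bounded" species are those in the support of
some non-negative vector of the row space of `W` (per-species exact
LP).  This validates hand-picked certificates; it is not a proof
search.

**Boundary equilibria.**  A *siphon* is a species set `Z` such that
every reaction producing a member also consumes a member.  Minimal
siphons are enumerated by closure-repair search (branching over the
consumers of each violated reaction), then reduced to the
inclusion-minimal ones; the test suite cross-checks against brute-force
subset enumeration.  If each minimal siphon contains the support of a
non-negative, non-zero conservation relation (per-siphon exact-LP
feasibility), no class with non-empty interior contains a boundary
equilibrium.  When either precondition fails without a manual input,
the run ends *indecisive* — never with a claim of boundary equilibria
or multistationarity.

## Determinant sign analysis (step 5)

`det M(x)` is collected as a polynomial in `x` with coefficients in
`ℚ[κ]`.  A coefficient is classified by the signs of its `κ`-monomial
coefficients: all equal to `(−1)^s` → always target; all equal to
`(−1)^{s+1}` → always opposite; mixed → conditional.  This is a
sufficient criterion (a mixed-sign polynomial that never changes sign
on the positive orthant is conservatively kept conditional).  If all
coefficients are always-target, the run concludes: uniqueness for all
rate constants, steps 6–7 skipped.

## Positive parameterization (step 6)

A species set is *non-interacting* if no two members appear on the same
side of any reaction and all their coefficients are at most one;
*reactant-non-interacting* relaxes this to reactant sides.  Candidate
sets of size exactly `s` are enumerated deterministically (maximal
independent sets of the conflict graph via networkx clique enumeration
on the complement, large cliques broken into subsets), discarding sets
whose interior supports a non-negative conservation relation (the
linear system would be singular; exact-LP filter).

For each candidate split, subsets of `s` of the independent equations
(the `f_i` with `i` outside the pivot rows) are tried in lexicographic
order.  Linear systems are solved exactly; each solution is certified
componentwise (numerator and denominator with all-positive
coefficients, up to a global sign flip) and verified against the
*entire* system `f(Φ) ≡ 0`.  The first success defines
`Φ : ℝ^m_{>0} → V ∩ ℝ^n_{>0}`, `m = n − s`.  This rule reproduces the
conventional parameterizations for the benchmark networks.  A
user-supplied split bypasses the structural search but not the
verification.

## Region certificates (step 7)

`a(x̂) = det M(Φ(x̂))` is reduced to `p(x̂)/q(x̂)` with `q` certified
positive; the monomial content of `p` (a positive factor) is stripped
and the sign analysis of step 5 is repeated on the core polynomial.
For a conditional coefficient, the sign-determining *kernel* is
obtained by exact factorization, dropping positive factors (numeric
constants, even powers, all-positive-coefficient polynomials) with sign
tracking.

**Uniqueness region.**  The conjunction of non-strict inequalities
`(−1)^s · kernel ≥ 0` over all (deduplicated) conditional kernels.  If
some coefficient is always-opposite, the uniqueness region is empty.
Non-strict inequalities are sound because at the boundary the offending
terms vanish and the remaining coefficients keep the target sign, so
`det M` never attains `(−1)^{s+1}` on the equilibrium set.

**Multistationarity regions.**  An exponent vector `α` of the core of
`p` is a *vertex of the Newton polytope* iff an integer separating
vector `w` with `w·α > w·α′` for all other exponents exists — decided
by exact rational LP and independently re-checked in the tests by
brute-force convex-combination feasibility.  For a vertex-backed
coefficient that attains `(−1)^{s+1}` (always, or under the strict
inequality on its kernel), the curve `x̂(t) = (t^{w_1}, …, t^{w_m})`
makes the `α` term dominate, so `p` itself attains `(−1)^{s+1}`; `t`
is doubled from 2 until the exactly-evaluated sign flips.  Each emitted
condition carries a verified witness: deterministic rate constants with
the kernel strictly opposite (all-ones, else a vertex-scaling of the
kernel's own Newton polytope), the exact point `x̂`, and the class
`c = W Φ(x̂)` (checked positive).  Opposite-capable kernels with no
vertex-backed monomial fall into the *undecided* region, and a full
truth table over the distinct kernel sign patterns is reported with
per-cell verdicts (mono / multi / undecided).

Mono and multi regions are disjoint by construction (non-strict versus
strict inequalities on the same kernels).

**Presentation.**  When the network contains enzyme-mechanism triples
`E + S ⇌ ES → E + P`, conditions are additionally reported in
catalytic and Michaelis–Menten constants via the (sign-preserving)
substitution `kon = (koff + kcat)/kM`.

## Numeric oracle

`count_equilibria` solves `φ_c = 0` from 200 seeded log-uniform starts
(scipy `hybr` with exact-Jacobian lambdification), accepting roots with
relative residual below 1e−9 and all coordinates above 1e−8, and
deduplicating at relative radius 1e−6.  It is a lower-bound counter
used only to corroborate certificates in the test suite: uniqueness
regions must never reveal a second equilibrium, and every
multistationarity witness class must reveal at least two.

## Determinism

All symbolic outputs are canonical (RREF bases, lexicographic
enumeration orders, seedless witness construction); identical inputs
and overrides produce byte-identical reports.  The random elements
(oracle starts, random network generator) are explicitly seeded.
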