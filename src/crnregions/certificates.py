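"""Newton-polytope vertex certificates and parameter-region verdicts.

The last stage of the procedure turns the coefficient-sign analysis of
the parameterized determinant numerator ``p(x̂)`` into explicit
parameter regions:

* **Uniqueness** (one positive equilibrium per class): holds whenever
  every coefficient of ``p`` has the reference sign ``(-1)^s`` — i.e.
  under the conjunction of non-strict inequalities on the conditional
  coefficients' sign kernels.
* **Multistationarity** (some class with >= 2 positive equilibria):
  guaranteed when a coefficient attains the opposite sign *and* its
  exponent vector is a vertex of the Newton polytope of ``p`` — the
  monomial then dominates along a curve ``x̂(t) = (t^{w_1}, ...,
  t^{w_m})`` for the separating direction ``w``, so ``p`` itself attains
  the opposite sign at some positive point.

Vertex status is decided by an exact rational LP; every emitted
multistationarity condition is backed by an explicit numeric witness
``(kappa, x̂, c = W Phi(x̂))`` at which the sign is verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re
from fractions import Fraction
from typing import Optional, Sequence

import sympy as sp

from ._exactlp import solve_lp
from .equilibrium import (
    DeterminantPolynomial,
    SignAnalysis,
    SignCategory,
    classify_signs,
)
from .network import ConservationBasis
from .parameterization import ARational, PositiveParameterization

__all__ = [
    "NewtonPolytope",
    "RegionCertificate",
    "Witness",
    "newton_polytope",
    "sign_witness",
    "assemble_certificate",
    "kappa_with_kernel_sign",
    "enzyme_triples",
    "michaelis_menten_form",
]


@dataclass(frozen=True)
class NewtonPolytope:
    """Exponent vectors of a polynomial with exact vertex flags.

    ``separating_vectors[i]`` (for vertices) is an integer vector ``w``
    with ``w . alpha_i > w . alpha_j`` for every other exponent.
    """

    exponents: tuple
    vertex_flags: tuple
    separating_vectors: tuple

    def is_vertex(self, alpha) -> bool:
        alpha = tuple(alpha)
        return self.vertex_flags[self.exponents.index(alpha)]

    def separating_vector(self, alpha) -> Optional[tuple]:
        alpha = tuple(alpha)
        return self.separating_vectors[self.exponents.index(alpha)]

    @property
    def vertices(self) -> tuple:
        return tuple(
            a for a, flag in zip(self.exponents, self.vertex_flags) if flag
        )


def _vertex_lp(alpha, others):
    """Exact LP: find integer w with w.alpha >= w.alpha' + 1 for all others."""
    m = len(alpha)
    if not others:
        return [0] * m
    # vars: u (m), v (m), t ; maximize t ;  (a'-a).(u-v) + t <= 0 ; sum(u+v) <= 1
    c = [0] * (2 * m) + [1]
    A_ub, b_ub = [], []
    for ap in others:
        diff = [Fraction(ap[i] - alpha[i]) for i in range(m)]
        A_ub.append(diff + [-v for v in diff] + [Fraction(1)])
        b_ub.append(Fraction(0))
    A_ub.append([Fraction(1)] * (2 * m) + [Fraction(0)])
    b_ub.append(Fraction(1))
    res = solve_lp(c, A_ub=A_ub, b_ub=b_ub)
    if res.status != "optimal" or res.objective <= 0:
        return None
    w = [res.x[i] - res.x[m + i] for i in range(m)]
    lcm = 1
    for v in w:
        lcm = lcm * v.denominator // sp.igcd(lcm, v.denominator)
    w = [int(v * lcm) for v in w]
    assert all(
        sum(w[i] * (alpha[i] - ap[i]) for i in range(m)) > 0 for ap in others
    )
    return w


def newton_polytope(p: sp.Poly) -> NewtonPolytope:
    """Vertex classification of the exponent set of ``p``.

    Monomials whose coefficient is identically zero are dropped by the
    ``Poly`` representation already.  An exponent is a vertex iff a
    rational separating vector exists (decided exactly).
    """
    exponents = tuple(mono for mono, _ in p.terms())
    flags, seps = [], []
    for alpha in exponents:
        others = [a for a in exponents if a != alpha]
        w = _vertex_lp(alpha, others)
        flags.append(w is not None)
        seps.append(tuple(w) if w is not None else None)
    return NewtonPolytope(exponents, tuple(flags), tuple(seps))


def sign_witness(
    p: sp.Poly,
    alpha: Sequence[int],
    w: Sequence[int],
    kappa_values: dict,
    max_doublings: int = 60,
) -> tuple:
    """Find ``x̂`` with ``sign p(x̂) = sign`` of the ``alpha`` coefficient.

    Walks ``x̂(t) = (t^{w_1}, ..., t^{w_m})`` with ``t`` doubling from 2;
    the ``alpha`` term dominates as ``t`` grows because ``w`` separates
    ``alpha``, so termination is guaranteed.  Evaluation is exact
    (rational ``t`` and kappa), so the returned sign is certified.
    """
    alpha = tuple(alpha)
    coef = dict(p.terms())[alpha]
    target = sp.sign(coef.subs(kappa_values) if coef.free_symbols else coef)
    if target == 0:
        raise ValueError("coefficient vanishes at the supplied kappa")
    gens = p.gens
    t = sp.Integer(2)
    for _ in range(max_doublings):
        point = {g: t ** wi for g, wi in zip(gens, w)}
        val = p.as_expr().subs(kappa_values).subs(point)
        val = sp.Rational(sp.nsimplify(val))
        if sp.sign(val) == target:
            return tuple(point[g] for g in gens)
        t *= 2
    raise RuntimeError("witness search did not terminate")  # pragma: no cover


def kappa_with_kernel_sign(
    kernel: sp.Expr, kappa: Sequence[sp.Symbol], desired: int,
    max_doublings: int = 60,
) -> Optional[dict]:
    """Deterministically pick positive kappa with ``sign(kernel) = desired``.

    Starts from all rate constants equal to one; if the sign is wrong,
    scales kappa along the separating direction of a ``desired``-signed
    vertex monomial of the kernel's own Newton polytope (``kappa_j =
    t^{w_j}``, t doubling).  Seedless and exact.
    """
    kappa = tuple(kappa)
    ones = {k: sp.Integer(1) for k in kappa}
    if sp.sign(kernel.subs(ones)) == desired:
        return ones
    kpoly = sp.Poly(kernel, *kappa)
    terms = [(mono, coef) for mono, coef in kpoly.terms() if sp.sign(coef) == desired]
    exponents = [mono for mono, _ in kpoly.terms()]
    for mono, _ in terms:
        w = _vertex_lp(mono, [a for a in exponents if a != mono])
        if w is None:
            continue
        t = sp.Integer(2)
        for _ in range(max_doublings):
            point = {k: t ** wi for k, wi in zip(kappa, w)}
            if sp.sign(kernel.subs(point)) == desired:
                return point
            t *= 2
    # fall back: plain doubling along each desired-signed monomial support
    for mono, _ in terms:
        t = sp.Integer(2)
        for _ in range(20):
            point = {k: (t ** e if e else sp.Integer(1)) for k, e in zip(kappa, mono)}
            if sp.sign(kernel.subs(point)) == desired:
                return point
            t *= 2
    return None


@dataclass(frozen=True)
class Witness:
    """A verified multistationarity witness: ``sign p(x̂; kappa) = (-1)^{s+1}``
    with ``c = W Phi(x̂) > 0`` componentwise (all checked exactly)."""

    kappa: dict
    xhat: tuple
    c: tuple


@dataclass(frozen=True)
class Condition:
    """One parameter inequality: ``kernel`` compared against zero.

    ``relation`` is ``">="`` / ``"<"`` etc.; ``always`` marks conditions
    that hold for every positive kappa (empty inequality).
    """

    kernel: Optional[sp.Expr]
    relation: str
    always: bool = False

    def holds_at(self, kappa_values: dict) -> bool:
        if self.always:
            return True
        val = self.kernel.subs(kappa_values)
        return {
            ">=": val >= 0, ">": val > 0, "<=": val <= 0, "<": val < 0
        }[self.relation]

    def __str__(self) -> str:
        if self.always:
            return "all kappa > 0"
        return f"{self.kernel} {self.relation} 0"


@dataclass(frozen=True)
class RegionCertificate:
    """Final verdict on the parameter-space partition.

    ``mono_conditions`` — conjunction under which every compatibility
    class has exactly one positive (non-degenerate) equilibrium; ``None``
    when uniqueness is impossible (an always-opposite coefficient
    exists), ``()`` when it holds for all kappa.

    ``multi_conditions`` — list of ``(condition, witness)`` pairs, each
    sufficient for some class to contain at least two positive
    equilibria.

    ``undecided`` — human-readable description of the parameter region
    (possibly empty) not covered by either side.

    ``assumptions`` — the structural certificates the verdict relies on.
    """

    s: int
    mono_conditions: Optional[tuple]
    multi_conditions: tuple
    undecided: tuple
    truth_table: tuple = ()
    assumptions: tuple = ()
    stage: str = "parameterized"  # or "determinant" (concluded at step 5)

    @property
    def mono_for_all_kappa(self) -> bool:
        return self.mono_conditions == ()

    @property
    def multi_for_all_kappa(self) -> bool:
        return any(cond.always for cond, _ in self.multi_conditions)

    def summary(self) -> str:
        lines = []
        if self.mono_for_all_kappa:
            lines.append(
                "exactly one positive non-degenerate equilibrium in every "
                "stoichiometric compatibility class with non-empty positive "
                "part, for all rate constants"
            )
        elif self.mono_conditions is None:
            lines.append("uniqueness region: empty")
        else:
            conj = " and ".join(str(c) for c in self.mono_conditions)
            lines.append(f"unique positive equilibrium per class iff {conj}")
        for cond, _ in self.multi_conditions:
            if cond.always:
                lines.append("multistationary for all rate constants")
            else:
                lines.append(f"multistationary if {cond}")
        for u in self.undecided:
            lines.append(f"undecided: {u}")
        return "; ".join(lines)


def _positive_class_vector(W: ConservationBasis, Phi, xhat_point, kappa_values):
    subs = dict(zip(Phi.free_symbols, xhat_point))
    subs.update(kappa_values)
    comps = [sp.nsimplify(c.subs(subs)) for c in Phi.components]
    cvec = [
        sum(W.W[r, i] * comps[i] for i in range(len(comps)))
        for r in range(W.d)
    ]
    return tuple(sp.Rational(v) for v in cvec)


def assemble_certificate(
    a: ARational,
    analysis: SignAnalysis,
    polytope: NewtonPolytope,
    W: ConservationBasis,
    Phi: PositiveParameterization,
    assumptions: Sequence = (),
) -> RegionCertificate:
    """Assemble the region verdict from the sign classes of ``p`` core.

    Implements the vertex-per-coefficient rule: an always-opposite
    coefficient at a vertex yields unconditional multistationarity; a
    conditional coefficient at a vertex yields the strict opposite-sign
    inequality on its kernel; opposite-capable coefficients at non-vertex
    exponents fall into the undecided region.  The uniqueness side is the
    conjunction of non-strict target-sign inequalities over *all*
    conditional kernels.
    """
    s = a.s
    target = (-1) ** s
    mono_rel = ">=" if target > 0 else "<="
    multi_rel = "<" if target > 0 else ">"

    opp = [e for e in analysis.entries if e.category is SignCategory.ALWAYS_OPPOSITE]
    cond = [e for e in analysis.entries if e.category is SignCategory.CONDITIONAL]

    # uniqueness side
    if opp:
        mono_conditions: Optional[tuple] = None
    else:
        seen, mono_list = set(), []
        for e in cond:
            key = sp.srepr(e.kernel)
            if key not in seen:
                seen.add(key)
                mono_list.append(Condition(e.kernel, mono_rel))
        mono_conditions = tuple(mono_list)

    # multistationarity side
    multi = []
    undecided = []
    emitted = set()
    for e in opp:
        if polytope.is_vertex(e.monomial):
            if "always" in emitted:
                continue
            emitted.add("always")
            kappa_values = {k: sp.Integer(1) for k in a.kappa}
            wvec = polytope.separating_vector(e.monomial)
            xhat = sign_witness(a.core, e.monomial, wvec, kappa_values)
            cvec = _positive_class_vector(W, Phi, xhat, kappa_values)
            assert all(v > 0 for v in cvec)
            multi.append(
                (Condition(None, "", always=True), Witness(kappa_values, xhat, cvec))
            )
        else:
            undecided.append(
                f"coefficient of {sp.Mul(*[g**m for g, m in zip(a.core.gens, e.monomial)])} "
                "always has the opposite sign but is not a polytope vertex"
            )
    vertex_backed_keys = {
        sp.srepr(e.kernel) for e in cond if polytope.is_vertex(e.monomial)
    }
    for e in cond:
        key = sp.srepr(e.kernel)
        if polytope.is_vertex(e.monomial):
            if ("cond", key) in emitted:
                continue
            emitted.add(("cond", key))
            condition = Condition(e.kernel, multi_rel)
            desired = -target
            kappa_values = kappa_with_kernel_sign(e.kernel, a.kappa, desired)
            witness = None
            if kappa_values is not None:
                wvec = polytope.separating_vector(e.monomial)
                xhat = sign_witness(a.core, e.monomial, wvec, kappa_values)
                cvec = _positive_class_vector(W, Phi, xhat, kappa_values)
                assert all(v > 0 for v in cvec)
                witness = Witness(kappa_values, xhat, cvec)
            multi.append((condition, witness))
        else:
            # a kernel already backed by a vertex elsewhere is decided
            if key in vertex_backed_keys or ("undec", key) in emitted:
                continue
            emitted.add(("undec", key))
            undecided.append(
                f"{e.kernel} {multi_rel} 0 with all vertex-backed conditions "
                "in their uniqueness range"
            )

    truth_table = _truth_table(analysis, polytope, target)
    return RegionCertificate(
        s,
        mono_conditions,
        tuple(multi),
        tuple(undecided),
        truth_table=truth_table,
        assumptions=tuple(assumptions),
    )


def _truth_table(analysis: SignAnalysis, polytope: NewtonPolytope, target: int):
    """Per-cell verdicts over the sign patterns of the distinct kernels.

    Cells assign each kernel either its target-sign range (non-strict)
    or the strict opposite; a cell is 'multi' when some strictly-opposite
    kernel is vertex-backed, 'mono' when all kernels are in the target
    range and no always-opposite coefficient exists, else 'undecided'.
    """
    import itertools as it

    kernels = analysis.kernels
    if not kernels:
        return ()
    vertex_backed = set()
    for e in analysis.entries:
        if e.category is SignCategory.CONDITIONAL and polytope.is_vertex(e.monomial):
            vertex_backed.add(sp.srepr(e.kernel))
    has_opp = any(
        e.category is SignCategory.ALWAYS_OPPOSITE for e in analysis.entries
    )
    rows = []
    for pattern in it.product(("target", "opposite"), repeat=len(kernels)):
        if has_opp:
            verdict = "multi_or_undecided"
        elif any(
            p == "opposite" and sp.srepr(kern) in vertex_backed
            for p, kern in zip(pattern, kernels)
        ):
            verdict = "multi"
        elif all(p == "target" for p in pattern):
            verdict = "mono"
        else:
            verdict = "undecided"
        rows.append((pattern, verdict))
    return tuple(rows)


# --------------------------------------------------------------------------
# Presentation-only translation to catalytic / Michaelis-Menten constants


def enzyme_triples(net) -> tuple:
    """Detect enzyme-mechanism reaction triples ``E + S <-> ES -> E + P``.

    Returns tuples ``(on, off, cat)`` of reaction indices: ``on`` binds
    enzyme and substrate into a complex, ``off`` is its exact reverse,
    and ``cat`` converts the complex back into the enzyme plus a product
    distinct from the substrate.
    """
    triples = []
    for on in range(net.ell):
        a_on = tuple(net.alpha[i][on] for i in range(net.n))
        b_on = tuple(net.beta[i][on] for i in range(net.n))
        if sum(a_on) != 2 or sum(b_on) != 1 or max(a_on) != 1:
            continue
        complex_i = b_on.index(1)
        reactants = {i for i, v in enumerate(a_on) if v}
        for off in range(net.ell):
            if off == on:
                continue
            a_off = tuple(net.alpha[i][off] for i in range(net.n))
            b_off = tuple(net.beta[i][off] for i in range(net.n))
            if a_off != b_on or b_off != a_on:
                continue
            for cat in range(net.ell):
                if cat in (on, off):
                    continue
                a_cat = tuple(net.alpha[i][cat] for i in range(net.n))
                b_cat = tuple(net.beta[i][cat] for i in range(net.n))
                if a_cat != b_on or sum(b_cat) != 2 or max(b_cat) > 1:
                    continue
                products = {i for i, v in enumerate(b_cat) if v}
                # exactly one reactant (the enzyme) is released unchanged
                if len(products & reactants) == 1 and products != reactants:
                    triples.append((on, off, cat))
    return tuple(sorted(triples))


def michaelis_menten_form(kernel: sp.Expr, net, kappa: Sequence[sp.Symbol]):
    """Rewrite a sign kernel in catalytic/Michaelis-Menten constants.

    For every detected enzyme triple with rate symbols ``(kon, koff,
    kcat)`` the binding constant is eliminated via ``kon = (koff + kcat)
    / kM`` where ``kM`` is a fresh positive symbol (named after the
    catalytic constant, e.g. ``kc1 -> kM1``).  The result is the
    positive-factor-stripped numerator of the substituted kernel — the
    same sign as ``kernel`` on the positive orthant.  Returns ``(expr,
    kM_symbols)``; when no triple is detected the kernel is returned
    unchanged.
    """
    from .equilibrium import strip_positive_factors

    kappa = tuple(kappa)
    subs = {}
    kms = []
    for idx, (on, off, cat) in enumerate(enzyme_triples(net), start=1):
        kon, koff, kcat = kappa[on], kappa[off], kappa[cat]
        m = re.fullmatch(r"[A-Za-z_]*?(\d+)", kcat.name)
        kM = sp.Symbol(f"kM{m.group(1) if m else idx}", positive=True)
        subs[kon] = (koff + kcat) / kM
        kms.append(kM)
    if not subs:
        return kernel, ()
    num, _ = sp.fraction(sp.cancel(sp.together(kernel.subs(subs))))
    remaining = [k for k in kappa if k not in subs] + kms
    return strip_positive_factors(sp.expand(num), remaining), tuple(kms)
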