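"""Positive algebraic parameterizations of the positive equilibrium set.

The multistationarity side of the analysis needs the determinant
``det M`` evaluated *on* the equilibrium set.  For many signalling
networks the equilibrium equations can be solved for a subset of the
species in terms of the remaining ("free") ones, giving a rational map

    Phi : R^m_{>0} -> V ∩ R^n_{>0},   x = Phi(x̂),

whose components have numerators and denominators with all-positive
coefficients — manifestly positive on the positive orthant.

Two structural sufficient conditions are used to pick the solved set:

* **non-interacting** sets — no two members on the same side of any
  reaction, all their coefficients at most one; the chosen equilibrium
  equations are then linear in the members;
* **reactant-non-interacting** sets — the relaxation that only
  constrains reactant sides.

Conservation relations are never used as equations here: the map must
parameterize the full positive equilibrium variety, not one class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import sympy as sp

from .equilibrium import DeterminantPolynomial, PhiSystem, positive_coefficients
from .network import ConservationBasis, MassActionSystem, ReactionNetwork

__all__ = [
    "VariableSplit",
    "PositiveParameterization",
    "ARational",
    "find_splits",
    "solve_split",
    "compute_a",
]


@dataclass(frozen=True)
class VariableSplit:
    """A candidate partition into solved and free species.

    ``mode`` records which structural condition justified the set
    (``"non_interacting"``, ``"reactant_non_interacting"`` or
    ``"user_supplied"``).
    """

    solved: tuple  # species indices, sorted
    free: tuple
    mode: str

    def __post_init__(self):
        if set(self.solved) & set(self.free):
            raise ValueError("solved and free sets overlap")


@dataclass(frozen=True)
class PositiveParameterization:
    """A rational map from free variables onto the positive equilibria.

    ``components[i]`` is the expression for ``x_i`` (the identity for
    free variables).  Construction guarantees ``f(Phi(x̂)) == 0``
    symbolically and that each component's numerator and denominator
    have all-positive coefficients.
    """

    split: VariableSplit
    components: tuple
    x: tuple
    kappa: tuple

    @property
    def m(self) -> int:
        return len(self.split.free)

    @property
    def free_symbols(self) -> tuple:
        return tuple(self.x[i] for i in self.split.free)

    def substitution(self) -> dict:
        return dict(zip(self.x, self.components))


def _interaction_conflicts(net: ReactionNetwork, reactant_only: bool):
    """(eligible species, set of conflicting pairs) for a structural mode."""
    n = net.n
    eligible = set(range(n))
    for i in range(n):
        for j in range(net.ell):
            if net.alpha[i][j] > 1 or (not reactant_only and net.beta[i][j] > 1):
                eligible.discard(i)
                break
    conflicts = set()
    for j in range(net.ell):
        sides = [net.reactant_support(j)]
        if not reactant_only:
            sides.append(net.product_support(j))
        for side in sides:
            members = sorted(side & eligible)
            for a, b in itertools.combinations(members, 2):
                conflicts.add((a, b))
    return eligible, conflicts


def _independent_sets(eligible, conflicts, max_size):
    """Deterministic enumeration of candidate sets of size <= max_size.

    Maximal independent sets of the conflict graph are found first
    (networkx clique enumeration on the complement); larger ones are
    broken into all subsets of ``max_size``.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(sorted(eligible))
    for a, b in sorted(conflicts):
        g.add_edge(a, b)
    comp = nx.complement(g)
    out = set()
    for clique in nx.find_cliques(comp):
        clique = tuple(sorted(clique))
        if len(clique) <= max_size:
            out.add(clique)
        else:
            for sub in itertools.combinations(clique, max_size):
                out.add(sub)
    return sorted(out, key=lambda t: (-len(t), t))


def _has_internal_unit_relation(W: ConservationBasis, members) -> bool:
    """Necessary-condition filter: a non-negative conservation relation
    supported inside the solved set makes the linear system singular."""
    from fractions import Fraction

    from ._exactlp import solve_lp

    Wm = W.W
    d, n = Wm.rows, Wm.cols
    inside = set(members)
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    norm = [Fraction(0)] * (2 * d)

    def frac(q):
        q = sp.Rational(q)
        return Fraction(int(q.p), int(q.q))

    for j in range(n):
        col = [frac(Wm[r, j]) for r in range(d)]
        row = [v for v in col] + [-v for v in col]
        if j in inside:
            A_ub.append([-v for v in row])
            b_ub.append(Fraction(0))
            norm = [a + b for a, b in zip(norm, row)]
        else:
            A_eq.append(row)
            b_eq.append(Fraction(0))
    A_eq.append(norm)
    b_eq.append(Fraction(1))
    res = solve_lp([0] * (2 * d), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq)
    return res.status == "optimal"


def find_splits(net: ReactionNetwork, W: ConservationBasis) -> list:
    """Enumerate structural variable splits, best first.

    Non-interacting sets come before reactant-non-interacting ones; within
    a mode, larger sets first, ties broken lexicographically.  Sets whose
    interior supports a non-negative conservation relation are dropped
    (their linear systems are singular).  Only sets of size at most
    ``s = n - d`` are returned, since only ``s`` equilibrium equations
    are independent.
    """
    s = net.n - W.d
    out = []
    seen = set()
    for mode, reactant_only in (
        ("non_interacting", False),
        ("reactant_non_interacting", True),
    ):
        eligible, conflicts = _interaction_conflicts(net, reactant_only)
        for cand in _independent_sets(eligible, conflicts, s):
            # only sets with exactly s members can parameterize the full
            # (n - s)-dimensional positive equilibrium variety
            if len(cand) != s or cand in seen:
                continue
            if _has_internal_unit_relation(W, cand):
                continue
            seen.add(cand)
            free = tuple(i for i in range(net.n) if i not in cand)
            out.append(VariableSplit(cand, free, mode))
    order = {"non_interacting": 0, "reactant_non_interacting": 1}
    out.sort(key=lambda sp_: (order[sp_.mode], -len(sp_.solved), sp_.solved))
    return out


def _certify_component(expr, syms):
    """Return the canceled expression if numerator and denominator pass
    the all-positive-coefficients test (after a possible global sign
    flip), else None."""
    try:
        expr = sp.cancel(sp.together(expr))
        num, den = sp.fraction(expr)
        if positive_coefficients(num, syms) and positive_coefficients(den, syms):
            return expr
        if positive_coefficients(-num, syms) and positive_coefficients(-den, syms):
            return sp.cancel((-num) / (-den))
    except sp.PolynomialError:
        pass
    return None


def solve_split(
    sys: MassActionSystem,
    split: VariableSplit,
    W: ConservationBasis,
    max_equation_subsets: int = 20,
) -> Optional[PositiveParameterization]:
    """Solve equilibrium equations for the split's solved variables.

    Candidate equation subsets are drawn from the independent equations
    (the ``f_i`` with ``i`` outside the pivot rows), in lexicographic
    order.  Each solution is verified against the *full* system
    ``f(Phi) == 0`` and positivity-certified componentwise; the first
    success is returned, ``None`` if all candidates fail.
    """
    solved_syms = [sys.x[i] for i in split.solved]
    free_syms = [sys.x[i] for i in split.free]
    syms = list(free_syms) + list(sys.kappa)
    nonpivot = [i for i in range(sys.network.n) if i not in W.pivots]
    k = len(split.solved)
    if k > len(nonpivot):
        return None
    tried = 0
    for subset in itertools.combinations(nonpivot, k):
        if tried >= max_equation_subsets:
            break
        tried += 1
        eqs = [sys.f[i] for i in subset]
        solutions = _solve_equations(eqs, solved_syms)
        for sol in solutions:
            comp_full = list(sys.x)
            ok = True
            for i, sym in zip(split.solved, solved_syms):
                cert = _certify_component(sol[sym], syms)
                if cert is None:
                    ok = False
                    break
                comp_full[i] = cert
            if not ok:
                continue
            subs = dict(zip(sys.x, comp_full))
            residuals = (
                sp.expand(sp.fraction(sp.cancel(sp.together(fi.subs(subs))))[0])
                for fi in sys.f
            )
            if all(r == 0 for r in residuals):
                return PositiveParameterization(
                    split, tuple(comp_full), sys.x, sys.kappa
                )
    return None


def _solve_equations(eqs, unknowns):
    """Solve for ``unknowns`` over the rational-function field.

    Uses an exact linear solve when the system is linear in the
    unknowns (the structural cases), falling back to sympy's general
    solver otherwise.  Returns a list of solution dicts.
    """
    linear = all(sp.Poly(eq, *unknowns).total_degree() <= 1 for eq in eqs)
    if linear:
        A, b = sp.linear_eq_to_matrix(eqs, unknowns)
        if A.rows != A.cols:
            return []
        det = sp.cancel(DomainDet(A))
        if det == 0:
            return []
        sol_vec = A.LUsolve(b)
        return [
            {u: sp.cancel(sp.together(v)) for u, v in zip(unknowns, sol_vec)}
        ]
    try:
        sols = sp.solve(eqs, unknowns, dict=True)
    except Exception:
        return []
    return [s for s in sols if set(unknowns) <= set(s)]


def DomainDet(A: sp.Matrix):
    from sympy.polys.matrices import DomainMatrix

    try:
        d = DomainMatrix.from_Matrix(A).det()
        return d.as_expr() if hasattr(d, "as_expr") else sp.sympify(d)
    except Exception:
        return A.det(method="berkowitz")


@dataclass(frozen=True)
class ARational:
    """``a(x̂) = det M(Phi(x̂))`` in lowest terms.

    ``numerator`` is the full numerator polynomial in the free
    variables; ``core`` is the numerator with its monomial content
    (a positive monomial factor) stripped — the polytope and sign
    analyses run on ``core``.  ``denominator`` passes the all-positive
    coefficient test.
    """

    numerator: sp.Poly = field(repr=False)
    denominator: sp.Expr
    core: sp.Poly = field(repr=False)
    content_monomial: sp.Expr
    free: tuple
    kappa: tuple
    s: int

    @property
    def expr(self) -> sp.Expr:
        return self.numerator.as_expr() / self.denominator

    def as_determinant_polynomial(self) -> DeterminantPolynomial:
        """View of the core numerator for the coefficient-sign machinery."""
        return DeterminantPolynomial(
            self.core.as_expr(), self.core, self.free, self.kappa, self.s,
            denominator=self.denominator * (1 / self.content_monomial),
        )


def compute_a(detp: DeterminantPolynomial, Phi: PositiveParameterization) -> ARational:
    """Substitute the parameterization into ``det M`` and reduce.

    Raises ``ValueError`` when the reduced denominator cannot be
    certified positive (the sign analysis would then be unsound).
    """
    free_syms = Phi.free_symbols
    syms = list(free_syms) + list(Phi.kappa)
    a = sp.cancel(sp.together(detp.expr.subs(Phi.substitution())))
    p, q = sp.fraction(a)
    p, q = sp.expand(p), sp.expand(q)
    if not positive_coefficients(q, syms):
        if positive_coefficients(-q, syms):
            p, q = sp.expand(-p), sp.expand(-q)
        else:
            raise ValueError("denominator of a(x̂) not certified positive")
    poly = sp.Poly(p, *free_syms)
    # strip the monomial content in the free variables (positive on the
    # positive orthant, so irrelevant for signs and the polytope)
    min_exp = [min(mono[i] for mono, _ in poly.terms()) for i in range(len(free_syms))]
    content = sp.Mul(*[sym ** e for sym, e in zip(free_syms, min_exp)])
    core = sp.Poly(sp.expand(sp.cancel(p / content)), *free_syms)
    return ARational(
        poly, q, core, content, tuple(free_syms), tuple(Phi.kappa), detp.s
    )
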