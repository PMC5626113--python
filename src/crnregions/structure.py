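"""Structural preconditions: dissipativity and absence of boundary equilibria.

The sign-based counting results only apply to dissipative networks whose
stoichiometric compatibility classes (with non-empty interior) contain
no boundary equilibria.  Two sufficient criteria are implemented:

* **Conservativity** — a strictly positive left null vector of ``N``
  exists; the classes are then compact and the network is dissipative.
  Decided by an exact rational LP.
* **A dissipativity certificate check** — given a user-supplied strictly
  positive vector ``omega``, the residual ``omega . f(x)`` is examined
  syntactically: the check succeeds when every monomial with a positive
  rate coefficient involves only species bounded by non-negative
  conservation relations and at least one unbounded species occurs in a
  negative term.  This validates the kind of hand-picked certificate
  used in practice; it is sufficient evidence, not a proof search.

Boundary equilibria are excluded via minimal siphons: if every minimal
siphon contains the support of a non-negative, non-zero conservation
relation, no class with non-empty interior has a boundary equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import sympy as sp

from ._exactlp import solve_lp
from .network import ConservationBasis, MassActionSystem, ReactionNetwork, StoichiometricMatrix

__all__ = [
    "SiphonSet",
    "DissipativityCertificate",
    "is_conservative",
    "check_proposition1",
    "minimal_siphons",
    "siphon_criterion",
    "bounded_species",
]


@dataclass(frozen=True)
class SiphonSet:
    """A siphon: a species set closed under 'production requires consumption'.

    If a member is produced by a reaction then some member (possibly the
    same) is consumed by that reaction.  If all members start at zero
    concentration they remain at zero, which is why siphons locate
    candidate boundary equilibria.
    """

    members: frozenset
    minimal: bool = True

    def sorted(self) -> tuple:
        return tuple(sorted(self.members))


@dataclass(frozen=True)
class DissipativityCertificate:
    """Evidence that a network is dissipative (or that the check failed).

    ``kind`` is ``"conservative"`` (``omega`` is a strictly positive left
    null vector of ``N``), ``"certificate"`` (user-supplied ``omega``
    passed the syntactic residual check; ``residual`` stores
    ``omega . f``), or ``"failed"``.
    """

    kind: str
    omega: Optional[tuple] = None
    residual: Optional[sp.Expr] = None
    bounded_vars: tuple = ()

    @property
    def ok(self) -> bool:
        return self.kind != "failed"


def _frac(q) -> Fraction:
    q = sp.Rational(q)
    return Fraction(int(q.p), int(q.q))


def is_conservative(nmat: StoichiometricMatrix, W: Optional[ConservationBasis] = None
                    ) -> DissipativityCertificate:
    """Search for a strictly positive rational vector with ``omega^t N = 0``.

    The vector is sought in the row space of ``W`` by maximizing the
    minimum entry of ``y^t W`` under a normalization bound; the LP is
    exact, so a returned certificate satisfies ``omega^t N = 0`` and
    ``min(omega) > 0`` identically.
    """
    if W is None:
        kernel = nmat.N.T.nullspace()
        if not kernel:
            return DissipativityCertificate("failed")
        Wm = sp.Matrix([v.T for v in kernel]).rref()[0]
    else:
        Wm = W.W
    d, n = Wm.rows, Wm.cols
    # Variables: y+ (d), y- (d), t.  Maximize t subject to
    #   (y^t W)_i >= t  for all i,   sum(y+ + y-) <= 1.
    c = [0] * (2 * d) + [1]
    A_ub, b_ub = [], []
    for i in range(n):
        col = [_frac(Wm[r, i]) for r in range(d)]
        A_ub.append([-v for v in col] + [v for v in col] + [Fraction(1)])
        b_ub.append(Fraction(0))
    A_ub.append([Fraction(1)] * (2 * d) + [Fraction(0)])
    b_ub.append(Fraction(1))
    res = solve_lp(c, A_ub=A_ub, b_ub=b_ub)
    if res.status != "optimal" or res.objective <= 0:
        return DissipativityCertificate("failed")
    y = [res.x[r] - res.x[d + r] for r in range(d)]
    omega = [sum(sp.Rational(y[r].numerator, y[r].denominator) * Wm[r, i] for r in range(d))
             for i in range(n)]
    # normalize to small integers for readability
    denoms = [sp.Rational(w).q for w in omega]
    scale = sp.ilcm(*denoms) if len(denoms) > 1 else denoms[0]
    omega = [sp.nsimplify(w * scale) for w in omega]
    g = sp.igcd(*[int(w) for w in omega]) if all(w.is_integer for w in omega) else 1
    if g > 1:
        omega = [w / g for w in omega]
    assert all(w > 0 for w in omega)
    assert (sp.Matrix([omega]) * nmat.N).is_zero_matrix
    return DissipativityCertificate("conservative", omega=tuple(omega))


def bounded_species(W: ConservationBasis) -> tuple:
    """Species provably bounded on every compatibility class.

    A species is bounded if it lies in the support of some non-negative,
    non-zero vector in the row space of ``W`` (then its concentration is
    at most the corresponding conserved total).  Decided per species by
    exact LP feasibility.  Sufficient, not necessary.
    """
    Wm = W.W
    d, n = Wm.rows, Wm.cols
    out = []
    for i in range(n):
        # find y with  y^t W >= 0  and  (y^t W)_i = 1
        A_ub, b_ub, A_eq, b_eq = [], [], [], []
        for j in range(n):
            col = [_frac(Wm[r, j]) for r in range(d)]
            row = [-v for v in col] + [v for v in col]
            if j == i:
                A_eq.append([-v for v in row])
                b_eq.append(Fraction(1))
            else:
                A_ub.append(row)
                b_ub.append(Fraction(0))
        res = solve_lp([0] * (2 * d), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq)
        if res.status == "optimal":
            out.append(i)
    return tuple(out)


def check_proposition1(
    sys: MassActionSystem, W: ConservationBasis, omega: Sequence
) -> DissipativityCertificate:
    """Validate a user-supplied dissipativity vector ``omega > 0``.

    Computes ``residual = omega . f(x)`` symbolically and accepts when
    (i) the residual is not identically zero, (ii) every monomial with a
    positive coefficient involves only bounded species, and (iii) some
    unbounded species appears in a negatively-signed monomial, so the
    residual is eventually negative far from the bounded region.
    """
    omega = [sp.Rational(w) for w in omega]
    if len(omega) != sys.network.n:
        raise ValueError("omega has wrong length")
    if any(w <= 0 for w in omega):
        raise ValueError("omega must be strictly positive")
    residual = sp.expand(sum(w * fi for w, fi in zip(omega, sys.f)))
    if residual == 0:
        return DissipativityCertificate("failed", omega=tuple(omega), residual=residual)
    bounded = set(bounded_species(W))
    xset_bounded = {sys.x[i] for i in bounded}
    xall = set(sys.x)
    poly = sp.Poly(residual, *sys.x)
    neg_has_unbounded = False
    for mono, coef in poly.terms():
        coeffs = sp.Poly(coef, *sys.kappa).coeffs()
        support = {sys.x[i] for i, e in enumerate(mono) if e > 0}
        if all(sp.sign(cc) > 0 for cc in coeffs):
            if not support <= xset_bounded:
                return DissipativityCertificate(
                    "failed", omega=tuple(omega), residual=residual,
                    bounded_vars=tuple(sorted(bounded)),
                )
        elif all(sp.sign(cc) < 0 for cc in coeffs):
            if support & (xall - xset_bounded):
                neg_has_unbounded = True
        else:  # mixed-sign coefficient: treat conservatively as positive
            if not support <= xset_bounded:
                return DissipativityCertificate(
                    "failed", omega=tuple(omega), residual=residual,
                    bounded_vars=tuple(sorted(bounded)),
                )
    kind = "certificate" if neg_has_unbounded else "failed"
    return DissipativityCertificate(
        kind, omega=tuple(omega), residual=residual, bounded_vars=tuple(sorted(bounded))
    )


def _is_siphon(net: ReactionNetwork, Z: frozenset) -> bool:
    for j in range(net.ell):
        produced = Z & net.product_support(j)
        if produced and not (Z & net.reactant_support(j)):
            return False
    return True


def minimal_siphons(net: ReactionNetwork) -> list:
    """Enumerate all minimal siphons (as sorted index sets).

    Guided search: starting from each seed species, unsatisfied closure
    constraints are repaired by branching over the consumers of the
    offending reaction; the candidates are then reduced to the minimal
    ones.  Complete for the network sizes this tool targets (the test
    suite cross-checks against brute-force subset enumeration).
    """
    n = net.n
    consumers = [net.reactant_support(j) for j in range(net.ell)]
    producers = [net.product_support(j) for j in range(net.ell)]

    candidates: set = set()

    def close(Z: frozenset, ceiling: frozenset):
        # find first violated constraint
        for j in range(net.ell):
            if Z & producers[j] and not (Z & consumers[j]):
                for k in sorted(consumers[j] & ceiling):
                    close(Z | {k}, ceiling)
                return
        candidates.add(Z)

    full = frozenset(range(n))
    for seed in range(n):
        close(frozenset([seed]), full)

    minimal = []
    for Z in sorted(candidates, key=lambda z: (len(z), sorted(z))):
        if not any(m <= Z for m in minimal):
            minimal.append(Z)
    return [SiphonSet(Z) for Z in sorted(minimal, key=lambda z: sorted(z))]


def siphon_criterion(siphons: Sequence[SiphonSet], W: ConservationBasis) -> bool:
    """True iff every minimal siphon supports a positive conservation relation.

    For each siphon ``Z`` an exact LP decides whether a non-negative,
    non-zero vector in the row space of ``W`` has support contained in
    ``Z`` (normalized so the entries on ``Z`` sum to one).  When true,
    no compatibility class with non-empty interior contains a boundary
    equilibrium.
    """
    Wm = W.W
    d, n = Wm.rows, Wm.cols
    for siphon in siphons:
        Z = siphon.members
        A_ub, b_ub, A_eq, b_eq = [], [], [], []
        norm = [Fraction(0)] * (2 * d)
        for j in range(n):
            col = [_frac(Wm[r, j]) for r in range(d)]
            pos = [v for v in col] + [-v for v in col]  # (y+ - y-)^t W_col
            if j in Z:
                A_ub.append([-v for v in pos])  # omega_j >= 0
                b_ub.append(Fraction(0))
                norm = [a + b for a, b in zip(norm, pos)]
            else:
                A_eq.append(pos)  # omega_j = 0
                b_eq.append(Fraction(0))
        A_eq.append(norm)
        b_eq.append(Fraction(1))
        res = solve_lp([0] * (2 * d), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq)
        if res.status != "optimal":
            return False
    return True
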