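"""Exact rational linear programming (dense two-phase simplex).

Several structural decisions of the analysis must not depend on
floating-point tolerances: the existence of a strictly positive
conservation vector, whether a siphon contains the support of a
non-negative conservation relation, and whether an exponent vector is a
vertex of a Newton polytope.  All of these reduce to tiny linear
programs over the rationals.  This module provides a dense tableau
simplex over :class:`fractions.Fraction` with Bland's anti-cycling rule;
problems have at most a few dozen variables, so performance is a
non-issue and exactness is guaranteed.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence

__all__ = ["LPResult", "solve_lp"]

_ZERO = Fraction(0)
_ONE = Fraction(1)


class LPResult:
    """Outcome of an exact LP solve.

    Attributes
    ----------
    status : str
        One of ``"optimal"``, ``"infeasible"``, ``"unbounded"``.
    x : list[Fraction] | None
        Optimal point (for ``"optimal"``).
    objective : Fraction | None
        Optimal objective value (for ``"optimal"``).
    """

    def __init__(self, status: str, x: Optional[list] = None, objective=None):
        self.status = status
        self.x = x
        self.objective = objective

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LPResult({self.status}, obj={self.objective})"


def _to_frac_matrix(rows):
    return [[Fraction(v) for v in row] for row in rows]


def solve_lp(
    c: Sequence,
    A_ub: Optional[Sequence[Sequence]] = None,
    b_ub: Optional[Sequence] = None,
    A_eq: Optional[Sequence[Sequence]] = None,
    b_eq: Optional[Sequence] = None,
) -> LPResult:
    """Maximize ``c . z`` subject to ``A_ub z <= b_ub``, ``A_eq z = b_eq``, ``z >= 0``.

    All data is converted to :class:`~fractions.Fraction`; the solve is
    exact.  Free variables must be split into positive and negative
    parts by the caller.
    """
    c = [Fraction(v) for v in c]
    n = len(c)
    A_ub = _to_frac_matrix(A_ub or [])
    b_ub = [Fraction(v) for v in (b_ub or [])]
    A_eq = _to_frac_matrix(A_eq or [])
    b_eq = [Fraction(v) for v in (b_eq or [])]

    m_ub, m_eq = len(A_ub), len(A_eq)
    m = m_ub + m_eq
    # Columns: n structural, m_ub slacks, m artificials.
    n_slack = m_ub
    n_art = m
    width = n + n_slack + n_art

    T = []  # constraint rows
    rhs = []
    basis = []
    for i in range(m_ub):
        row = list(A_ub[i]) + [_ZERO] * n_slack + [_ZERO] * n_art
        row[n + i] = _ONE
        b = b_ub[i]
        if b < 0:
            row = [-v for v in row]
            b = -b
        row[n + n_slack + i] = _ONE
        T.append(row)
        rhs.append(b)
        basis.append(n + n_slack + i)
    for j in range(m_eq):
        row = list(A_eq[j]) + [_ZERO] * n_slack + [_ZERO] * n_art
        b = b_eq[j]
        if b < 0:
            row = [-v for v in row]
            b = -b
        row[n + n_slack + m_ub + j] = _ONE
        T.append(row)
        rhs.append(b)
        basis.append(n + n_slack + m_ub + j)

    def pivot(r, col):
        piv = T[r][col]
        T[r] = [v / piv for v in T[r]]
        rhs[r] = rhs[r] / piv
        for i in range(m):
            if i != r and T[i][col] != 0:
                factor = T[i][col]
                T[i] = [a - factor * b for a, b in zip(T[i], T[r])]
                rhs[i] -= factor * rhs[r]
        basis[r] = col

    def reduced_costs(obj):
        # obj: full-width objective (maximize). Returns reduced cost row.
        z = list(obj)
        for r, bcol in enumerate(basis):
            coef = obj[bcol]
            if coef != 0:
                for jj in range(width):
                    z[jj] -= coef * T[r][jj]
        return z

    def simplex(obj, allowed):
        """Run simplex maximizing obj over columns in `allowed` (Bland)."""
        while True:
            red = reduced_costs(obj)
            enter = None
            for jcol in range(width):
                if allowed[jcol] and red[jcol] > 0:
                    enter = jcol
                    break
            if enter is None:
                value = sum(obj[bcol] * rhs[r] for r, bcol in enumerate(basis))
                return "optimal", value
            # ratio test, Bland: smallest index leaving variable
            leave, best = None, None
            for r in range(m):
                if T[r][enter] > 0:
                    ratio = rhs[r] / T[r][enter]
                    if best is None or ratio < best or (
                        ratio == best and basis[r] < basis[leave]
                    ):
                        best, leave = ratio, r
            if leave is None:
                return "unbounded", None
            pivot(leave, enter)

    allowed = [True] * width
    # Phase 1: maximize -(sum of artificials)
    obj1 = [_ZERO] * (n + n_slack) + [Fraction(-1)] * n_art
    status, value = simplex(obj1, allowed)
    if status != "optimal" or value < 0:
        return LPResult("infeasible")
    # Drive remaining artificials out of the basis where possible.
    for r in range(m):
        if basis[r] >= n + n_slack:
            for jcol in range(n + n_slack):
                if T[r][jcol] != 0:
                    pivot(r, jcol)
                    break
    for jcol in range(n + n_slack, width):
        allowed[jcol] = False

    # Phase 2
    obj2 = list(c) + [_ZERO] * (n_slack + n_art)
    status, value = simplex(obj2, allowed)
    if status == "unbounded":
        return LPResult("unbounded")
    x = [_ZERO] * n
    for r, bcol in enumerate(basis):
        if bcol < n:
            x[bcol] = rhs[r]
    return LPResult("optimal", x, value)
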