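"""The equilibrium system phi_c, its Jacobian determinant and sign analysis.

Because ``W f(x) = 0`` identically, ``d`` of the equilibrium equations
``f(x) = 0`` are redundant.  Replacing the components of ``f`` at the
pivot indices of the row-reduced ``W`` by the conservation equations
``(W x - c)`` yields the square system

    phi_c(x)_i = f_i(x)            for non-pivot rows,
    phi_c(x)_i = (W x - c)_i       for pivot rows,

whose positive zeros are exactly the positive equilibria in the class
``P_c``.  Let ``M(x)`` be its Jacobian (independent of ``c``).  The sign
of ``det M(x)`` against the reference sign ``(-1)^s`` (``s = rank N``)
drives the whole analysis:

* if every coefficient of ``det M`` (a polynomial in ``x`` whose
  coefficients are polynomials in the rate constants) has sign
  ``(-1)^s``, each compatibility class contains exactly one positive,
  non-degenerate equilibrium — for all rate constants satisfying the
  derived conditions;
* coefficients that can attain the opposite sign are the raw material
  for the multistationarity analysis carried out on the parameterized
  determinant ``a(x̂)`` downstream.

Determinants are computed exactly over the polynomial ring
``QQ[kappa, x]`` (fraction-free elimination via sympy's DomainMatrix),
which is orders of magnitude faster than generic symbolic expansion on
the sparse Jacobians that arise here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import sympy as sp
from sympy.polys.matrices import DomainMatrix

from .network import ConservationBasis, MassActionSystem

__all__ = [
    "PhiSystem",
    "DeterminantPolynomial",
    "SignCategory",
    "CoefficientSign",
    "SignAnalysis",
    "DegenerateSystem",
    "build_phi",
    "jacobian_determinant",
    "classify_signs",
    "rational_kinetics_determinant",
    "positive_coefficients",
    "strip_positive_factors",
]


class DegenerateSystem(ValueError):
    """``det M(x)`` vanishes identically: every equilibrium is degenerate."""


@dataclass(frozen=True)
class PhiSystem:
    """The square system ``phi_c`` and its Jacobian ``M(x)``."""

    phi: sp.Matrix
    M: sp.Matrix = field(repr=False)
    x: tuple
    kappa: tuple
    c: tuple
    replaced_rows: tuple  # pivot indices of W (0-based)
    s: int


def build_phi(sys: MassActionSystem, W: ConservationBasis) -> PhiSystem:
    """Replace the pivot rows of ``f`` by the conservation equations."""
    d = W.d
    n = sys.network.n
    c = sp.symbols(f"c1:{d + 1}", positive=True)
    phi = sp.Matrix(sys.f)
    xvec = sp.Matrix(sys.x)
    for r, i in enumerate(W.pivots):
        phi[i] = (W.W[r, :] * xvec)[0, 0] - c[r]
    M = phi.jacobian(sys.x)
    return PhiSystem(phi, M, sys.x, sys.kappa, tuple(c), tuple(W.pivots), n - d)


@dataclass(frozen=True)
class DeterminantPolynomial:
    """``det M(x)`` collected as a polynomial in ``x`` with kappa coefficients.

    ``coefficient_table`` maps exponent tuples (in the order of ``x``)
    to the corresponding rate-constant polynomial.  For rational
    kinetics, ``denominator`` stores the certified-positive denominator
    (``1`` for mass action).
    """

    expr: sp.Expr
    poly: sp.Poly = field(repr=False)
    x: tuple
    kappa: tuple
    s: int
    denominator: sp.Expr = sp.Integer(1)

    @property
    def coefficient_table(self) -> dict:
        return {mono: coef for mono, coef in self.poly.terms()}


def jacobian_determinant(phi: PhiSystem) -> DeterminantPolynomial:
    """Exact expanded determinant of ``M(x)``; verified independent of ``c``."""
    det = DomainMatrix.from_Matrix(phi.M).det()
    det = sp.expand(det.as_expr() if hasattr(det, "as_expr") else det)
    if det == 0:
        raise DegenerateSystem("det M(x) is identically zero")
    assert not (det.free_symbols & set(phi.c)), "det M must not depend on c"
    poly = sp.Poly(det, *phi.x)
    return DeterminantPolynomial(det, poly, phi.x, phi.kappa, phi.s)


class SignCategory(Enum):
    ALWAYS_TARGET = "always_target"
    ALWAYS_OPPOSITE = "always_opposite"
    CONDITIONAL = "conditional"
    ZERO = "zero"


@dataclass(frozen=True)
class CoefficientSign:
    """Sign classification of one x-monomial coefficient.

    ``kernel`` (for CONDITIONAL coefficients) is the sign-determining
    factor left after stripping a positive prefactor: the coefficient
    has the target sign ``(-1)^s`` iff ``(-1)^s * kernel >= 0``.
    """

    monomial: tuple
    coefficient: sp.Expr
    category: SignCategory
    kernel: Optional[sp.Expr] = None


def positive_coefficients(expr: sp.Expr, syms: Sequence[sp.Symbol]) -> bool:
    """Sufficient positivity test: all monomial coefficients positive.

    ``expr`` is treated as a polynomial in ``syms``; returns True when
    the expansion is non-zero and every coefficient is a positive
    rational.  Polynomials positive for subtler reasons are *not*
    certified.
    """
    expr = sp.expand(expr)
    if expr == 0:
        return False
    syms = [s for s in syms if s in expr.free_symbols]
    if not syms:
        return bool(sp.Rational(expr) > 0)
    return all(sp.sign(c) > 0 for c in sp.Poly(expr, *syms).coeffs())


def strip_positive_factors(expr: sp.Expr, syms: Sequence[sp.Symbol]) -> sp.Expr:
    """Remove factors that are positive on the positive orthant.

    Factors the expression over the rationals and drops numeric positive
    constants, monomials in ``syms``, even powers, and polynomial factors
    with all-positive coefficients.  What remains carries the sign.
    """
    const, factors = sp.factor_list(sp.expand(expr))
    kernel = sp.sign(const) if const != 0 else sp.Integer(0)
    for base, exp in factors:
        if exp % 2 == 0:
            continue
        if positive_coefficients(base, syms):
            continue
        neg = sp.expand(-base)
        if positive_coefficients(neg, syms):
            kernel = -kernel
            continue
        kernel = kernel * base ** 1  # odd power contributes one sign factor
    return sp.expand(kernel) if kernel.free_symbols else sp.Integer(int(kernel))


@dataclass(frozen=True)
class SignAnalysis:
    """Per-monomial sign classes of a determinant-type polynomial.

    ``target`` is ``(-1)^s``.  ``kernels`` lists the distinct
    sign-determining condition polynomials of the CONDITIONAL
    coefficients (deduplicated, in first-appearance order).
    """

    target: int
    entries: tuple

    @property
    def categories(self) -> set:
        return {e.category for e in self.entries}

    @property
    def kernels(self) -> tuple:
        seen, out = set(), []
        for e in self.entries:
            if e.category is SignCategory.CONDITIONAL:
                key = sp.srepr(e.kernel)
                if key not in seen:
                    seen.add(key)
                    out.append(e.kernel)
        return tuple(out)

    @property
    def verdict(self) -> str:
        cats = self.categories - {SignCategory.ZERO}
        if cats <= {SignCategory.ALWAYS_TARGET}:
            return "target_for_all_kappa"
        if SignCategory.ALWAYS_OPPOSITE in cats:
            return "opposite_for_some_monomial"
        return "conditional"


def classify_signs(detp: DeterminantPolynomial) -> SignAnalysis:
    """Classify each x-monomial coefficient against the sign ``(-1)^s``.

    A rate-constant polynomial is declared of fixed sign iff all its
    monomial coefficients share that sign (sufficient, not necessary;
    mixed-sign polynomials that never change sign are conservatively
    classified CONDITIONAL).
    """
    target = (-1) ** detp.s
    entries = []
    for mono, coef in detp.poly.terms():
        cpoly = sp.Poly(coef, *detp.kappa) if coef.free_symbols else None
        if cpoly is None:
            signs = {int(sp.sign(coef))}
        else:
            signs = {int(sp.sign(cc)) for cc in cpoly.coeffs()}
        if signs == {0} or not signs:
            cat, kernel = SignCategory.ZERO, None
        elif signs == {target}:
            cat, kernel = SignCategory.ALWAYS_TARGET, None
        elif signs == {-target}:
            cat, kernel = SignCategory.ALWAYS_OPPOSITE, None
        else:
            cat = SignCategory.CONDITIONAL
            kernel = strip_positive_factors(coef, detp.kappa)
        entries.append(CoefficientSign(mono, coef, cat, kernel))
    return SignAnalysis(target, tuple(entries))


def rational_kinetics_determinant(
    rates: Sequence[sp.Expr],
    N: sp.Matrix,
    W: ConservationBasis,
    x: Sequence[sp.Symbol],
    kappa: Sequence[sp.Symbol],
) -> DeterminantPolynomial:
    """Determinant for rational-function kinetics ``v_j = p_j / q_j``.

    Each denominator must be certified positive on the positive orthant
    (all-positive-coefficients test after expansion), in which case
    ``det M = p(x) / q(x)`` with ``q = prod q_j^2 > 0`` and only the
    numerator matters for the sign analysis.  Mass-action input (all
    ``q_j = 1``) reproduces :func:`jacobian_determinant` exactly.
    """
    x = tuple(x)
    kappa = tuple(kappa)
    syms = list(x) + list(kappa)
    for vj in rates:
        _, qj = sp.fraction(sp.cancel(sp.together(vj)))
        if not positive_coefficients(qj, syms):
            raise ValueError(
                f"denominator {qj} not certified positive on the positive orthant"
            )
    f = N * sp.Matrix(list(rates))
    n = len(x)
    d = W.d
    c = sp.symbols(f"c1:{d + 1}", positive=True)
    xvec = sp.Matrix(x)
    phi = sp.Matrix(f)
    for r, i in enumerate(W.pivots):
        phi[i] = (W.W[r, :] * xvec)[0, 0] - c[r]
    M = phi.jacobian(x)
    det = sp.cancel(sp.together(M.det(method="berkowitz")))
    p, q = sp.fraction(det)
    p, q = sp.expand(p), sp.expand(q)
    if not positive_coefficients(q, syms):
        if positive_coefficients(-q, syms):
            p, q = -p, -q
        else:
            raise ValueError("combined denominator not certified positive")
    if p == 0:
        raise DegenerateSystem("det M(x) is identically zero")
    assert not (p.free_symbols & set(c))
    poly = sp.Poly(p, *x)
    return DeterminantPolynomial(p / q, poly, x, kappa, n - d, denominator=q)
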