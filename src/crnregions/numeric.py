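"""Numeric cross-check: count positive equilibria in one compatibility class.

This module is an *oracle*, not part of the certified pipeline: it
solves ``phi_c(x) = 0`` numerically from many deterministic starting
points and reports the distinct positive roots found.  The symbolic
certificates never depend on it; the test suite uses it to corroborate
them (a class certified multistationary must reveal >= 2 equilibria, a
uniqueness region must never reveal more than one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import sympy as sp
from scipy.optimize import root

from .equilibrium import build_phi
from .network import ConservationBasis, MassActionSystem

__all__ = ["EquilibriumCount", "count_equilibria"]

_RESIDUAL_TOL = 1e-9
_POSITIVITY_TOL = 1e-8
_DEDUP_RTOL = 1e-6


@dataclass(frozen=True)
class EquilibriumCount:
    """Distinct positive roots of ``phi_c`` found by multi-start solving.

    ``count`` is a lower bound on the true number of equilibria (roots
    can be missed), never an overcount beyond the dedup tolerance.
    """

    count: int
    points: tuple
    attempts: int

    def __int__(self) -> int:
        return self.count


def count_equilibria(
    sys: MassActionSystem,
    W: ConservationBasis,
    kappa_values: dict,
    c_values: Sequence,
    seed: int = 0,
    n_starts: int = 200,
    extra_starts: Sequence = (),
) -> EquilibriumCount:
    """Count distinct positive roots of ``phi_c`` for fixed kappa and c.

    Starting points are drawn log-uniformly around the scale of the
    class (set by ``c``) from a seeded generator, plus any user-supplied
    ``extra_starts`` (e.g. known approximate equilibria).  Roots are
    accepted when the residual is below ``1e-9`` relative to the
    equation scale and all coordinates exceed ``1e-8``; duplicates are
    merged at relative tolerance ``1e-6``.
    """
    phi = build_phi(sys, W)
    n = len(phi.x)
    subs = dict(kappa_values)
    subs.update(dict(zip(phi.c, [sp.Float(v) for v in c_values])))
    phi_num = phi.phi.subs(subs)
    jac_num = phi.M.subs(subs)
    fun = sp.lambdify([phi.x], list(phi_num), "numpy")
    jac = sp.lambdify([phi.x], jac_num.tolist(), "numpy")

    def F(z):
        return np.asarray(fun(z), dtype=float).ravel()

    def J(z):
        return np.asarray(jac(z), dtype=float)

    scale = max(float(max(abs(float(v)) for v in c_values)), 1.0)
    rng = np.random.default_rng(seed)
    starts = [np.asarray([float(v) for v in p]) for p in extra_starts]
    for _ in range(n_starts):
        starts.append(scale * 10.0 ** rng.uniform(-4, 1, size=n))

    found: list = []
    for x0 in starts:
        try:
            sol = root(F, x0, jac=J, method="hybr")
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        z = sol.x
        if not np.all(np.isfinite(z)):
            continue
        if np.any(z <= _POSITIVITY_TOL):
            continue
        res = np.max(np.abs(F(z)))
        if res > _RESIDUAL_TOL * max(scale, np.max(np.abs(z)), 1.0):
            continue
        if any(
            np.allclose(z, w, rtol=_DEDUP_RTOL, atol=_DEDUP_RTOL * scale)
            for w in found
        ):
            continue
        found.append(z)
    found.sort(key=lambda z: tuple(z))
    return EquilibriumCount(len(found), tuple(tuple(z) for z in found), len(starts))
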