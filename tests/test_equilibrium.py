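import numpy as np
import pytest
import sympy as sp

from crnregions import (
    DegenerateSystem,
    SignCategory,
    build_phi,
    classify_signs,
    conservation_basis,
    jacobian_determinant,
    mass_action_system,
    rational_kinetics_determinant,
    stoichiometric_matrix,
)
from crnregions.equilibrium import (
    PhiSystem,
    positive_coefficients,
    strip_positive_factors,
)


def system_and_basis(net):
    nmat = stoichiometric_matrix(net)
    return mass_action_system(net), conservation_basis(nmat)


class TestPhiConstruction:
    def test_twocomp_phi_matches_known_form(self, nets):
        sys, W = system_and_basis(nets["TWOCOMP"])
        phi = build_phi(sys, W)
        x1, x2, x3, x4 = sys.x
        k1, k2, k3 = sys.kappa
        c1, c2 = phi.c
        expected = [
            x1 + x2 - c1,
            k1 * x1 - k2 * x2 * x3,
            x3 + x4 - c2,
            k2 * x2 * x3 - k3 * x4,
        ]
        for got, want in zip(phi.phi, expected):
            assert sp.expand(got - want) == 0
        assert phi.replaced_rows == (0, 2)
        assert phi.s == 2

    def test_jacobian_is_c_independent(self, nets):
        sys, W = system_and_basis(nets["HYBRID"])
        phi = build_phi(sys, W)
        assert not (set(phi.c) & phi.M.free_symbols)


class TestDeterminants:
    def test_twocomp_determinant(self, nets):
        sys, W = system_and_basis(nets["TWOCOMP"])
        detp = jacobian_determinant(build_phi(sys, W))
        x = sys.x
        k1, k2, k3 = sys.kappa
        expected = k1 * k2 * x[1] + k2 * k3 * x[2] + k1 * k3
        assert sp.expand(detp.expr - expected) == 0

    def test_hybrid_determinant(self, nets):
        sys, W = system_and_basis(nets["HYBRID"])
        detp = jacobian_determinant(build_phi(sys, W))
        x = sys.x
        k1, k2, k3, k4, k5, k6 = sys.kappa
        expected = (
            k2 * k4 * k5 * (k1 - k3) * x[2] * x[4]
            + k1 * k2 * k4 * k5 * x[3] * x[4]
            + k4 * k5 * k6 * (k1 + k2) * x[4] ** 2
            + k1 * k2 * k3 * k4 * x[2]
            + k1 * k2 * k3 * k5 * x[3]
            + k1 * k5 * k6 * (k3 + k2) * x[4]
            + k1 * k2 * k3 * k6
        )
        assert sp.expand(detp.expr - expected) == 0

    def test_gene_determinant(self, nets):
        sys, W = system_and_basis(nets["GENE"])
        detp = jacobian_determinant(build_phi(sys, W))
        x = sys.x
        k = sys.kappa
        expected = (
            2 * k[0] * k[1] * k[4] * k[6] * k[8] * x[0] * x[1] * x[3]
            - k[2] * k[3] * k[4] * k[7] * k[8] * x[2] * x[5]
            - k[2] * k[3] * k[4] * k[7] * k[9] * x[2]
            - k[2] * k[3] * k[5] * k[7] * k[8] * x[5]
            - k[2] * k[3] * k[5] * k[7] * k[9]
        )
        assert sp.expand(detp.expr - expected) == 0

    def test_numeric_jacobian_oracle(self, nets):
        # the symbolic determinant must agree with numpy's determinant of
        # the numerically evaluated Jacobian at random positive points
        sys, W = system_and_basis(nets["HYBRID"])
        phi = build_phi(sys, W)
        detp = jacobian_determinant(phi)
        rng = np.random.default_rng(11)
        for _ in range(5):
            xv = rng.uniform(0.2, 3.0, size=len(sys.x))
            kv = rng.uniform(0.2, 3.0, size=len(sys.kappa))
            subs = dict(zip(sys.x, xv)) | dict(zip(sys.kappa, kv))
            numeric = np.linalg.det(
                np.array(phi.M.subs(subs), dtype=float)
            )
            symbolic = float(detp.expr.subs(subs))
            assert numeric == pytest.approx(symbolic, rel=1e-9)

    def test_degenerate_system_detected(self):
        x1, x2 = sp.symbols("x1 x2", positive=True)
        k1 = sp.Symbol("k1", positive=True)
        c1 = sp.Symbol("c1", positive=True)
        phi = PhiSystem(
            phi=sp.Matrix([x1 + x2 - c1, k1 * (x1 + x2) - k1 * x1 - k1 * x2]),
            M=sp.Matrix([[1, 1], [0, 0]]),
            x=(x1, x2),
            kappa=(k1,),
            c=(c1,),
            replaced_rows=(0,),
            s=1,
        )
        with pytest.raises(DegenerateSystem):
            jacobian_determinant(phi)


class TestSignClassification:
    def test_twocomp_all_target(self, nets):
        sys, W = system_and_basis(nets["TWOCOMP"])
        analysis = classify_signs(jacobian_determinant(build_phi(sys, W)))
        assert analysis.target == 1
        assert analysis.verdict == "target_for_all_kappa"

    def test_hybrid_conditional_kernel(self, nets):
        sys, W = system_and_basis(nets["HYBRID"])
        analysis = classify_signs(jacobian_determinant(build_phi(sys, W)))
        assert analysis.verdict == "conditional"
        (kernel,) = analysis.kernels
        k1, k3 = sys.kappa[0], sys.kappa[2]
        assert sp.expand(kernel - (k1 - k3)) == 0 or sp.expand(
            kernel + (k1 - k3)
        ) == 0

    def test_gene_opposite_coefficient(self, nets):
        sys, W = system_and_basis(nets["GENE"])
        analysis = classify_signs(jacobian_determinant(build_phi(sys, W)))
        assert analysis.target == -1
        assert analysis.verdict == "opposite_for_some_monomial"
        opp = [
            e for e in analysis.entries
            if e.category is SignCategory.ALWAYS_OPPOSITE
        ]
        assert [e.monomial for e in opp] == [(1, 1, 0, 1, 0, 0, 0)]

    def test_positive_coefficients_helper(self):
        a, b = sp.symbols("a b", positive=True)
        assert positive_coefficients(a + 2 * b, (a, b))
        assert not positive_coefficients(a - b, (a, b))
        assert not positive_coefficients(sp.Integer(0), (a, b))
        assert positive_coefficients(sp.Integer(3), (a, b))

    def test_strip_positive_factors(self):
        a, b, c = sp.symbols("a b c", positive=True)
        expr = 6 * c ** 2 * (a + b) * (a - b) ** 3
        kernel = strip_positive_factors(expr, (a, b, c))
        assert sp.expand(kernel - (a - b)) == 0


class TestRationalKinetics:
    def test_mass_action_reduces_to_polynomial_path(self, nets):
        sys, W = system_and_basis(nets["TWOCOMP"])
        ref = jacobian_determinant(build_phi(sys, W))
        nmat = stoichiometric_matrix(nets["TWOCOMP"])
        detp = rational_kinetics_determinant(
            list(sys.v), nmat.N, W, sys.x, sys.kappa
        )
        assert sp.expand(detp.expr - ref.expr) == 0

    def test_michaelis_menten_conversion_always_target(self):
        # S <-> P with a saturating forward rate and linear reverse rate:
        # the determinant numerator is negative for all concentrations
        x1, x2 = sp.symbols("x1 x2", positive=True)
        k1, k2, kM = sp.symbols("k1 k2 kM", positive=True)
        N = sp.Matrix([[-1, 1], [1, -1]])
        from crnregions.network import ConservationBasis

        W = ConservationBasis(sp.Matrix([[1, 1]]), (0,))
        rates = [k1 * x1 / (kM + x1), k2 * x2]
        detp = rational_kinetics_determinant(
            rates, N, W, (x1, x2), (k1, k2, kM)
        )
        assert detp.s == 1
        assert positive_coefficients(detp.denominator, (x1, x2, k1, k2, kM))
        analysis = classify_signs(detp)
        assert analysis.verdict == "target_for_all_kappa"

    def test_sign_uncertifiable_denominator_rejected(self):
        x1, x2 = sp.symbols("x1 x2", positive=True)
        k1, k2, kM = sp.symbols("k1 k2 kM", positive=True)
        N = sp.Matrix([[-1, 1], [1, -1]])
        from crnregions.network import ConservationBasis

        W = ConservationBasis(sp.Matrix([[1, 1]]), (0,))
        rates = [k1 * x1 / (kM - x1), k2 * x2]
        with pytest.raises(ValueError, match="not certified positive"):
            rational_kinetics_determinant(rates, N, W, (x1, x2), (k1, k2, kM))
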