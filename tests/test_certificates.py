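import itertools
from fractions import Fraction

import sympy as sp

from crnregions import (
    enzyme_triples,
    michaelis_menten_form,
    newton_polytope,
    sign_witness,
)
from crnregions._exactlp import solve_lp
from crnregions.certificates import kappa_with_kernel_sign


def brute_force_vertices(exponents):
    """Oracle: alpha is a vertex iff it is not a convex combination of
    the other exponents (exact rational feasibility problem)."""
    out = []
    for alpha in exponents:
        others = [a for a in exponents if a != alpha]
        if not others:
            out.append(True)
            continue
        # lambdas >= 0, sum lambda = 1, sum lambda * a' = alpha
        m = len(alpha)
        A_eq = [[Fraction(1)] * len(others)] + [
            [Fraction(a[i]) for a in others] for i in range(m)
        ]
        b_eq = [Fraction(1)] + [Fraction(alpha[i]) for i in range(m)]
        res = solve_lp([0] * len(others), A_eq=A_eq, b_eq=b_eq)
        out.append(res.status != "optimal")
    return out


class TestNewtonPolytope:
    def test_simple_triangle(self):
        x, y = sp.symbols("x y", positive=True)
        p = sp.Poly(1 + x ** 2 + y ** 2 + x * y, x, y)
        np_ = newton_polytope(p)
        assert np_.is_vertex((0, 0))
        assert np_.is_vertex((2, 0))
        assert np_.is_vertex((0, 2))
        assert not np_.is_vertex((1, 1))

    def test_separating_vectors_separate(self):
        x, y = sp.symbols("x y", positive=True)
        p = sp.Poly(1 + x ** 3 + y + x * y ** 2 + x * y, x, y)
        np_ = newton_polytope(p)
        for alpha, flag, w in zip(
            np_.exponents, np_.vertex_flags, np_.separating_vectors
        ):
            if not flag:
                assert w is None
                continue
            for other in np_.exponents:
                if other != alpha:
                    assert sum(
                        wi * (ai - oi) for wi, ai, oi in zip(w, alpha, other)
                    ) > 0

    def test_agrees_with_brute_force_on_fixture_polynomials(self, traces):
        for name in ("RUNNING", "HYBRID", "GENE", "MOTIF1", "MOTIF2"):
            trace = traces[name]
            assert trace.polytope is not None, name
            expected = brute_force_vertices(trace.polytope.exponents)
            assert list(trace.polytope.vertex_flags) == expected, name

    def test_hybrid_vertex_pattern(self, traces):
        poly = traces["HYBRID"].polytope
        assert poly.is_vertex((1, 2))
        assert not poly.is_vertex((1, 1))

    def test_gene_vertex_pattern(self, traces):
        poly = traces["GENE"].polytope
        assert poly.is_vertex((2, 1))


class TestWitnesses:
    def test_sign_witness_is_exact(self):
        x, y = sp.symbols("x y", positive=True)
        k = sp.Symbol("k", positive=True)
        p = sp.Poly(-k * x ** 2 * y + x + y + 1, x, y)
        np_ = newton_polytope(p)
        w = np_.separating_vector((2, 1))
        point = sign_witness(p, (2, 1), w, {k: sp.Integer(1)})
        val = p.as_expr().subs({k: 1, x: point[0], y: point[1]})
        assert sp.Rational(val) < 0

    def test_hybrid_witness_verifies(self, traces):
        trace = traces["HYBRID"]
        cert = trace.certificate
        [(cond, wit)] = cert.multi_conditions
        assert cond.holds_at(wit.kappa)
        # the parameterized determinant numerator attains sign (-1)^(s+1)
        subs = dict(zip(trace.a.free, wit.xhat))
        subs.update(wit.kappa)
        val = sp.Rational(trace.a.core.as_expr().subs(subs))
        assert sp.sign(val) == (-1) ** (cert.s + 1)
        assert all(v > 0 for v in wit.c)

    def test_gene_witness_verifies(self, traces):
        trace = traces["GENE"]
        cert = trace.certificate
        assert cert.multi_for_all_kappa
        [(cond, wit)] = cert.multi_conditions
        subs = dict(zip(trace.a.free, wit.xhat))
        subs.update(wit.kappa)
        val = sp.Rational(trace.a.core.as_expr().subs(subs))
        assert sp.sign(val) == (-1) ** (cert.s + 1)
        assert all(v > 0 for v in wit.c)

    def test_kappa_search_reaches_desired_sign(self):
        k1, k3 = sp.symbols("k1 k3", positive=True)
        point = kappa_with_kernel_sign(k1 - k3, (k1, k3), -1)
        assert point is not None
        assert sp.Rational((k1 - k3).subs(point)) < 0
        # already satisfied at kappa = 1
        point = kappa_with_kernel_sign(k1 + k3, (k1, k3), 1)
        assert point == {k1: 1, k3: 1}


class TestRegionAssembly:
    def test_hybrid_regions_cover_parameter_space(self, traces):
        cert = traces["HYBRID"].certificate
        assert cert.undecided == ()
        (mono_cond,) = cert.mono_conditions
        [(multi_cond, _)] = cert.multi_conditions
        # complementary inequalities on the same kernel
        assert sp.expand(mono_cond.kernel - multi_cond.kernel) == 0
        assert {mono_cond.relation, multi_cond.relation} == {">=", "<"} or {
            mono_cond.relation,
            multi_cond.relation,
        } == {"<=", ">"}

    def test_motif2_truth_table_has_undecided_cell(self, traces):
        cert = traces["MOTIF2"].certificate
        table = dict(cert.truth_table)
        assert table[("target", "target")] == "mono"
        assert table[("opposite", "target")] == "multi"
        assert table[("opposite", "opposite")] == "multi"
        assert table[("target", "opposite")] == "undecided"
        assert len(cert.undecided) == 1

    def test_motif1_single_condition(self, traces):
        cert = traces["MOTIF1"].certificate
        assert len(cert.mono_conditions) == 1
        assert len(cert.multi_conditions) == 1
        assert cert.undecided == ()


class TestMichaelisMenten:
    def test_triples_detected(self, nets):
        for name in ("MOTIF1", "MOTIF2"):
            assert len(enzyme_triples(nets[name])) == 4
        assert enzyme_triples(nets["RUNNING"]) == ()

    def test_motif1_condition_translates_to_catalytic_form(self, nets, traces):
        cert = traces["MOTIF1"].certificate
        trace = traces["MOTIF1"]
        (cond,) = cert.mono_conditions
        mm, kms = michaelis_menten_form(
            cond.kernel, nets["MOTIF1"], trace.system.kappa
        )
        kc1, kc2, kc3, kc4 = sp.symbols("kc1 kc2 kc3 kc4", positive=True)
        kM1, kM2, kM3, kM4 = sp.symbols("kM1 kM2 kM3 kM4", positive=True)
        b = (kc1 * kc4 - kc2 * kc3) * (
            kc1 * kc4 * kM2 * kM3 - kc2 * kc3 * kM1 * kM4
        )
        assert sp.expand(mm - b) == 0 or sp.expand(mm + b) == 0

    def test_motif2_conditions_translate_to_catalytic_form(self, nets, traces):
        cert = traces["MOTIF2"].certificate
        trace = traces["MOTIF2"]
        kernels = [c.kernel for c in cert.mono_conditions]
        kc1, kc2, kc3, kc4 = sp.symbols("kc1 kc2 kc3 kc4", positive=True)
        kM1, kM2, kM3, kM4 = sp.symbols("kM1 kM2 kM3 kM4", positive=True)
        b1 = kc1 * kc4 - kc2 * kc3
        b2 = kc1 * kc4 * (kM2 + kM3) - kc2 * kc3 * (kM1 + kM4)
        translated = [
            michaelis_menten_form(kern, nets["MOTIF2"], trace.system.kappa)[0]
            for kern in kernels
        ]
        for b in (b1, b2):
            assert any(
                sp.expand(t - b) == 0 or sp.expand(t + b) == 0
                for t in translated
            ), b
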