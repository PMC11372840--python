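import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdscreen.activity_model import (
    Component,
    ConvergenceError,
    ModelConfig,
    dispersion_constant,
    hardcore_volume,
    lngamma_dsp,
    lngamma_fv,
    lngamma_fv_minus_fh,
    lngamma_residual,
    lngamma_sg,
    lngamma_total,
)
from asdscreen.constants import CLASSES, N_BINS, PARAMS_2010, SIGMA_GRID
from asdscreen.fixtures import gen_analytic_system, gen_gaussian_profile
from asdscreen.sigma_io import SigmaProfile

from .oracles import residual_lngamma_oracle


def _bin_of(sigma):
    return int(round((sigma + 0.025) / 0.001))


def profile_from_segments(name, segments, volume=100.0):
    """Exact on-grid profile from (sigma, class, area) triples."""
    areas = np.zeros((3, N_BINS))
    for sigma, cls, area in segments:
        areas[CLASSES.index(cls), _bin_of(sigma)] += area
    return SigmaProfile(name, areas, volume)


SEGS_1 = [(-0.008, "nhb", 30.0), (0.0, "nhb", 50.0), (0.012, "oh", 20.0)]
SEGS_2 = [(-0.01, "ot", 40.0), (0.002, "nhb", 60.0), (0.015, "ot", 25.0)]


def _component(name, segments, volume=100.0, **kwargs):
    return Component(name, profile_from_segments(name, segments, volume), **kwargs)


class TestResidual:
    def test_pure_component_is_zero(self, tight_config):
        c1 = _component("a", SEGS_1)
        c2 = _component("b", SEGS_2)
        out = lngamma_residual([c1, c2], [1.0, 0.0], 300.0, tight_config)
        assert out[0] == pytest.approx(0.0, abs=1e-10)

    def test_identical_profiles_zero_at_any_x(self, tight_config):
        c1 = _component("a", SEGS_1)
        c2 = _component("b", SEGS_1)
        for x in (0.2, 0.5, 0.9):
            out = lngamma_residual([c1, c2], [x, 1 - x], 330.0, tight_config)
            np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_three_bin_profiles_match_independent_oracle(self, tight_config):
        c1 = _component("a", SEGS_1)
        c2 = _component("b", SEGS_2)
        ours = lngamma_residual([c1, c2], [0.5, 0.5], 310.0, tight_config)
        oracle = residual_lngamma_oracle(SEGS_1, SEGS_2, 0.5, 310.0)
        assert ours[0] == pytest.approx(oracle[0], abs=1e-8)
        assert ours[1] == pytest.approx(oracle[1], abs=1e-8)

    def test_single_class_reduction(self, tight_config):
        """Three-class machinery reduces to single-class when OH/OT empty."""
        segs_a = [(-0.006, "nhb", 35.0), (0.004, "nhb", 45.0)]
        segs_b = [(-0.002, "nhb", 55.0), (0.009, "nhb", 25.0)]
        c1 = _component("a", segs_a)
        c2 = _component("b", segs_b)
        ours = lngamma_residual([c1, c2], [0.3, 0.7], 298.15, tight_config)
        oracle = residual_lngamma_oracle(segs_a, segs_b, 0.3, 298.15)
        np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_nonconvergence_reports_residual(self):
        c1 = _component("a", SEGS_1)
        c2 = _component("b", SEGS_2)
        cfg = ModelConfig(gamma_tol=1e-14, gamma_maxiter=2)
        with pytest.raises(ConvergenceError) as err:
            lngamma_residual([c1, c2], [0.5, 0.5], 300.0, cfg)
        assert err.value.residual > 0


class TestStavermanGuggenheim:
    def test_pure_limit(self):
        c1 = _component("a", SEGS_1, volume=90.0)
        c2 = _component("b", SEGS_2, volume=400.0)
        out = lngamma_sg([c1, c2], [1.0, 0.0])
        assert out[0] == pytest.approx(0.0, abs=1e-14)

    def test_equal_parameters_zero(self):
        c1 = _component("a", SEGS_1, volume=100.0)
        c2 = _component("b", SEGS_1, volume=100.0)
        np.testing.assert_allclose(lngamma_sg([c1, c2], [0.37, 0.63]), 0.0, atol=1e-14)

    def test_hand_evaluated_formula(self):
        # r = V/r0, q = A/q0 computed by hand for A1=100, V1=100, A2=125, V2=250
        c1 = _component("a", SEGS_1, volume=100.0)
        c2 = _component("b", SEGS_2, volume=250.0)
        x = np.array([0.3, 0.7])
        r = np.array([100.0 / 66.69, 250.0 / 66.69])
        q = np.array([100.0 / 79.53, 125.0 / 79.53])
        phi_x = r / (x @ r)
        theta_phi = (q / r) * (x @ r) / (x @ q)
        ell = 5.0 * (r - q) - (r - 1.0)
        expected = (
            np.log(phi_x) + 5.0 * q * np.log(theta_phi) + ell - phi_x * (x @ ell)
        )
        out = lngamma_sg([c1, c2], x)
        np.testing.assert_allclose(out, expected, rtol=1e-12)


class TestFreeVolume:
    def test_pure_limit(self):
        c1 = Component("a", m=1, v=100.0, v_hc=50.0)
        c2 = Component("b", m=1, v=5500.0, v_hc=500.0)
        out = lngamma_fv([c1, c2], [1.0, 0.0])
        assert out[0] == pytest.approx(0.0, abs=1e-14)

    def test_equal_free_volumes_zero(self):
        c1 = Component("a", m=1, v=100.0, v_hc=40.0)
        c2 = Component("b", m=1, v=160.0, v_hc=100.0)
        for x in (0.1, 0.5, 0.8):
            np.testing.assert_allclose(lngamma_fv([c1, c2], [x, 1 - x]), 0.0, atol=1e-14)

    def test_hand_evaluated_formula(self):
        # v^F = 50 and 5000 cm3/mol at x = 0.5
        c1 = Component("a", m=1, v=100.0, v_hc=50.0)
        c2 = Component("b", m=1, v=5500.0, v_hc=500.0)
        phi1 = 0.5 * 50.0 / (0.5 * 50.0 + 0.5 * 5000.0)
        expected1 = math.log(phi1 / 0.5) + 1.0 - phi1 / 0.5
        out = lngamma_fv([c1, c2], [0.5, 0.5])
        assert out[0] == pytest.approx(expected1, rel=1e-12)

    def test_v_below_hard_core_rejected(self):
        with pytest.raises(ValueError):
            Component("bad", m=1, v=50.0, v_hc=60.0)

    @settings(max_examples=50, deadline=None)
    @given(
        v1=st.floats(60, 400), f1=st.floats(0.1, 0.9),
        v2=st.floats(500, 40000), f2=st.floats(0.1, 0.9),
        x=st.floats(1e-3, 1 - 1e-3),
    )
    def test_fv_minus_fh_identity(self, v1, f1, v2, f2, x):
        """Term-by-term FV − FH equals the closed-form difference to 1e-10."""
        c1 = Component("a", m=1, v=v1, v_hc=v1 * (1 - f1))
        c2 = Component("b", m=1, v=v2, v_hc=v2 * (1 - f2))
        xs = np.array([x, 1 - x])
        fv = lngamma_fv([c1, c2], xs)
        v = np.array([v1, v2])
        phi_x = v / (xs @ v)
        fh = np.log(phi_x) + 1.0 - phi_x
        closed = lngamma_fv_minus_fh([c1, c2], xs)
        np.testing.assert_allclose(fv - fh, closed, atol=1e-10)


class TestDispersion:
    def _pair(self, eps1, eps2, cls1="nhb", cls2="nhb"):
        c1 = Component("a", m=1, eps=eps1, dispersion_class=cls1)
        c2 = Component("b", m=1, eps=eps2, dispersion_class=cls2)
        return c1, c2

    def test_infinite_dilution_of_other_component(self):
        c1, c2 = self._pair(100.0, 50.0)
        out = lngamma_dsp([c1, c2], [1.0, 0.0])
        assert out[0] == 0.0

    def test_equal_eps_gives_zero(self):
        c1, c2 = self._pair(80.0, 80.0)
        np.testing.assert_array_equal(lngamma_dsp([c1, c2], [0.3, 0.7]), 0.0)

    def test_margules_arithmetic(self):
        c1, c2 = self._pair(0.0, 0.0)
        out = lngamma_dsp([c1, c2], [0.25, 0.75], a_override=0.8)
        assert out[0] == pytest.approx(0.45)
        assert out[1] == pytest.approx(0.05)

    def test_sign_rule_exceptions(self):
        w = PARAMS_2010.w_dsp
        c1, c2 = self._pair(100.0, 64.0, "water", "hb-acceptor")
        expected = -w * (0.5 * 164.0 - math.sqrt(6400.0))
        assert dispersion_constant(c1, c2, w) == pytest.approx(expected)
        c3, c4 = self._pair(100.0, 64.0, "cooh", "nhb")
        assert dispersion_constant(c3, c4, w) == pytest.approx(expected)
        c5, c6 = self._pair(100.0, 64.0, "nhb", "nhb")
        assert dispersion_constant(c5, c6, w) == pytest.approx(-expected)

    def test_missing_eps_raises(self):
        c1 = Component("a", m=1)
        c2 = Component("b", m=1, eps=10.0)
        with pytest.raises(ValueError, match="missing"):
            lngamma_dsp([c1, c2], [0.5, 0.5])


class TestTotal:
    def test_cs_is_residual_only(self, tight_config):
        c1 = _component("a", SEGS_1, eps=100.0)
        c2 = _component("b", SEGS_2, eps=60.0)
        cfg = ModelConfig.from_label("CS", gamma_tol=1e-12, gamma_maxiter=10000)
        out = lngamma_total([c1, c2], [0.4, 0.6], 320.0, cfg)
        np.testing.assert_array_equal(out.lngamma_comb, 0.0)
        np.testing.assert_array_equal(out.lngamma_dsp, 0.0)
        np.testing.assert_array_equal(out.total, out.lngamma_res)

    def test_identical_components_all_zero(self):
        c1, c2 = gen_analytic_system(0.0)
        out = lngamma_total([c1, c2], [0.3, 0.7], 300.0, ModelConfig.from_label("CS_dsp^FV"))
        np.testing.assert_allclose(out.total, 0.0, atol=1e-12)

    def test_recomposition(self, tight_config):
        c1 = _component("a", SEGS_1, volume=90.0, m=1, v=120.0, v_hc=70.0, eps=100.0)
        c2 = _component("b", SEGS_2, volume=300.0, m=1, v=900.0, v_hc=500.0, eps=80.0)
        cfg = ModelConfig.from_label("CS_dsp^SG", gamma_tol=1e-12, gamma_maxiter=10000)
        x = [0.35, 0.65]
        out = lngamma_total([c1, c2], x, 305.0, cfg)
        res = lngamma_residual([c1, c2], x, 305.0, cfg)
        sg = lngamma_sg([c1, c2], x, cfg)
        dsp = lngamma_dsp([c1, c2], x, cfg)
        np.testing.assert_allclose(out.total, res + sg + dsp, atol=1e-14)

    def test_all_six_labels(self):
        for label, (comb, dsp) in {
            "CS": ("none", False), "CS^SG": ("sg", False), "CS^FV": ("fv", False),
            "CS_dsp": ("none", True), "CS_dsp^SG": ("sg", True), "CS_dsp^FV": ("fv", True),
        }.items():
            cfg = ModelConfig.from_label(label)
            assert (cfg.combinatorial, cfg.dispersion) == (comb, dsp)
            assert cfg.label == label

    @settings(max_examples=8, deadline=None)
    @given(seed=st.integers(0, 1000), x=st.floats(0.05, 0.95))
    def test_gibbs_duhem(self, seed, x):
        rng = np.random.default_rng(seed)
        p1 = gen_gaussian_profile(
            "a", float(rng.uniform(80, 300)), 150.0,
            [("nhb", float(rng.uniform(-0.005, 0.005)), 0.004, 0.7),
             ("oh", float(rng.uniform(0.008, 0.014)), 0.003, 0.3)],
        )
        p2 = gen_gaussian_profile(
            "b", float(rng.uniform(300, 2000)), 900.0,
            [("nhb", float(rng.uniform(-0.005, 0.005)), 0.005, 0.8),
             ("ot", float(rng.uniform(-0.014, -0.008)), 0.003, 0.2)],
        )
        c1 = Component("a", p1, m=100.0, v=150.0, v_hc=90.0, eps=110.0)
        c2 = Component("b", p2, m=5000.0, v=4000.0, v_hc=2500.0, eps=95.0)
        cfg = ModelConfig(gamma_tol=1e-12, gamma_maxiter=20000)
        t, h = 330.0, 1e-5

        def total(xx):
            return lngamma_total([c1, c2], [xx, 1 - xx], t, cfg).total

        d = (total(x + h) - total(x - h)) / (2 * h)
        assert abs(x * d[0] + (1 - x) * d[1]) < 1e-5

    @settings(max_examples=10, deadline=None)
    @given(x=st.floats(0.02, 0.98), label=st.sampled_from(
        ["CS", "CS^SG", "CS^FV", "CS_dsp", "CS_dsp^SG", "CS_dsp^FV"]))
    def test_pure_component_limit_all_configs(self, x, label):
        c1 = _component("a", SEGS_1, volume=90.0, m=1, v=120.0, v_hc=70.0, eps=100.0)
        c2 = _component("b", SEGS_2, volume=300.0, m=1, v=900.0, v_hc=500.0, eps=80.0)
        cfg = ModelConfig.from_label(label, gamma_tol=1e-12, gamma_maxiter=10000)
        out = lngamma_total([c1, c2], [1.0, 0.0], 310.0, cfg)
        assert out.total[0] == pytest.approx(0.0, abs=1e-10)


class TestHardcoreVolume:
    def test_zero_atoms(self):
        assert hardcore_volume({}, 0, 0, 0) == 0.0

    def test_linearity(self):
        counts = {"C": 6, "H": 6}
        v1 = hardcore_volume(counts, 12, 1, 0)
        v2 = hardcore_volume({k: 2 * n for k, n in counts.items()}, 24, 2, 0)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_benzene_hand_evaluation(self):
        expected_a3 = 6 * 20.58 + 6 * 7.24 - 12 * 5.92 - 14.7
        expected = expected_a3 * 6.02214076e23 / 1e24
        assert hardcore_volume({"C": 6, "H": 6}, 12, 1, 0) == pytest.approx(expected)

    def test_unknown_element_lists_supported(self):
        with pytest.raises(ValueError, match="supported"):
            hardcore_volume({"Xx": 1}, 0)

    def test_rdkit_route_matches_manual_counts(self):
        rdkit = pytest.importorskip("rdkit")
        from asdscreen.activity_model import hardcore_volume_from_smiles

        manual = hardcore_volume({"C": 6, "H": 6}, 12, 1, 0)
        assert hardcore_volume_from_smiles("c1ccccc1") == pytest.approx(manual)
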