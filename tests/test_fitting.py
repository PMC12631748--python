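"""Estimation stage: lineshape fits, thickness and swelling regressions,
peak detection and the Porod representation."""

import numpy as np
import pytest
from sklearn.base import clone

import lamsans as ls
from lamsans import (
    KratkyPorodThickness,
    NalletFitter,
    NalletParameters,
    ScatteringCurve,
    SlabModel,
    SwellingLawFit,
    ThicknessNotDeterminableError,
    detect_bragg_peak,
    estimate_thickness_kratky,
    fit_swelling,
    highq_overlap_metric,
    porod_representation,
    slab_intensity,
)
from lamsans.reference import CHARGED_SERIES, NEUTRAL_SERIES, POLYMER_SERIES

from conftest import make_curve


# ---------------------------------------------------------------------------
# Nallet fitter
# ---------------------------------------------------------------------------

class TestNalletFitter:
    @pytest.mark.parametrize("params", [
        NEUTRAL_SERIES[0.30], CHARGED_SERIES[0.05], POLYMER_SERIES[0.20],
    ], ids=["neutral-30", "charged-05", "polymer-20"])
    def test_noise_free_roundtrip_from_jittered_start(self, q200, params):
        curve = make_curve(params, q200)
        f = NalletFitter(initial=params, jitter_initial=True, n_restarts=3,
                         random_state=42).fit(curve)
        rel = np.abs(f.parameters_.as_array() / params.as_array() - 1.0)
        assert rel.max() < 1e-3
        assert f.converged_

    def test_heuristic_initialisation_recovers_charged_row(self, q200):
        curve = make_curve(CHARGED_SERIES[0.05], q200)
        f = NalletFitter(random_state=0).fit(curve)
        rel = np.abs(f.parameters_.as_array() / CHARGED_SERIES[0.05].as_array() - 1.0)
        assert rel.max() < 1e-3

    def test_flat_curve_collapses_to_background(self, q200):
        curve = ScatteringCurve(q200, np.full(q200.size, 5.0))
        f = NalletFitter(fit_background=True).fit(curve)
        assert f.parameters_.background == pytest.approx(5.0, abs=1e-6)
        assert f.parameters_.A_z == pytest.approx(0.0, abs=1e-6)
        assert f.parameters_.A_B == 0.0

    def test_intensity_rescaling_scales_amplitudes_only(self, q200):
        params = CHARGED_SERIES[0.10]
        curve = make_curve(params, q200, sigma_rel=0.05, seed=3)
        scaled = ScatteringCurve(q200, 7.3 * curve.intensity, 7.3 * curve.sigma)
        f1 = NalletFitter(initial=params, random_state=1).fit(curve)
        big = NalletParameters(7.3 * params.A_z, params.xi_p, 7.3 * params.A_B,
                               params.xi_l, params.q0)
        f2 = NalletFitter(initial=big, random_state=1).fit(scaled)
        assert f2.parameters_.A_z == pytest.approx(7.3 * f1.parameters_.A_z, rel=1e-6)
        assert f2.parameters_.A_B == pytest.approx(7.3 * f1.parameters_.A_B, rel=1e-6)
        assert f2.parameters_.xi_p == pytest.approx(f1.parameters_.xi_p, rel=1e-6)
        assert f2.parameters_.xi_l == pytest.approx(f1.parameters_.xi_l, rel=1e-6)
        assert f2.parameters_.q0 == pytest.approx(f1.parameters_.q0, rel=1e-8)

    def test_returned_point_is_a_local_minimum(self, q200):
        params = CHARGED_SERIES[0.30]
        curve = make_curve(params, q200, sigma_rel=0.05, seed=7)
        f = NalletFitter(initial=params, random_state=7).fit(curve)
        theta = f.parameters_.as_array()
        w = 1.0 / curve.sigma

        def rss(t):
            model = ls.nallet_intensity(q200, NalletParameters.from_array(t))
            return float(np.sum(((model - curve.intensity) * w) ** 2))

        best = rss(theta)
        for i in range(5):
            for sign in (+1, -1):
                t = theta.copy()
                t[i] *= 1.0 + sign * 0.01
                assert rss(t) >= best * (1.0 - 1e-9)

    def test_unresolvable_bragg_term_reported_not_determined(self, q200):
        """A ξ_l of ~1e-7 Å makes the Bragg term constant over any finite
        q range: the fitted curve matches but the Bragg-direction
        parameters carry no information."""
        params = NEUTRAL_SERIES[0.05]
        curve = make_curve(params, q200)
        f = NalletFitter(initial=params, jitter_initial=True, random_state=3).fit(curve)
        assert np.max(np.abs(f.predict(q200) / curve.intensity - 1.0)) < 1e-6
        xi_l_err, q0_err = f.uncertainties_[3], f.uncertainties_[4]
        assert np.isnan(xi_l_err) or np.isnan(q0_err)

    def test_window_and_size_validation(self, q200):
        curve = make_curve(CHARGED_SERIES[0.05], q200)
        with pytest.raises(ValueError, match="10 points"):
            NalletFitter(q_window=(0.01, 0.011)).fit(curve)

    def test_sklearn_protocol(self, q200):
        f = NalletFitter(n_restarts=2, random_state=5)
        params = f.get_params()
        assert params["n_restarts"] == 2
        g = clone(f)
        assert g.get_params() == params
        curve = make_curve(CHARGED_SERIES[0.05], q200)
        g.fit(curve.q, curve.intensity)
        assert g.predict(q200).shape == q200.shape


# ---------------------------------------------------------------------------
# Kratky-Porod thickness
# ---------------------------------------------------------------------------

class TestKratkyPorodThickness:
    def test_noise_free_consistency(self, q200):
        curve = ScatteringCurve(q200, slab_intensity(q200, SlabModel(0.05, 32.0)))
        est = estimate_thickness_kratky(curve, 0.05, (0.063, 0.138))
        assert est.delta == pytest.approx(32.0, rel=1e-2)
        assert est.r_squared > 0.9999

    def test_scale_invariance(self, q200):
        intensity = slab_intensity(q200, SlabModel(0.10, 32.0))
        a = estimate_thickness_kratky(ScatteringCurve(q200, intensity), 0.10,
                                      (0.055, 0.141))
        b = estimate_thickness_kratky(ScatteringCurve(q200, 13.7 * intensity), 0.10,
                                      (0.055, 0.141))
        assert a.delta == pytest.approx(b.delta, rel=1e-12)

    def test_two_percent_noise_unbiased_over_seeds(self, q200):
        clean = slab_intensity(q200, SlabModel(0.05, 32.0))
        deltas = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noisy = np.maximum(clean * (1.0 + 0.02 * rng.normal(size=q200.size)), 1e-12)
            est = estimate_thickness_kratky(ScatteringCurve(q200, noisy), 0.05,
                                            (0.063, 0.138))
            deltas.append(est.delta)
        assert np.mean(deltas) == pytest.approx(32.0, rel=0.02)

    def test_rising_signal_has_no_thickness(self, q200):
        curve = ScatteringCurve(q200, q200**2)  # q² I rises: positive slope
        with pytest.raises(ThicknessNotDeterminableError):
            estimate_thickness_kratky(curve, 1.0, (0.063, 0.138))

    def test_window_outside_span_rejected(self, q200):
        curve = ScatteringCurve(q200, slab_intensity(q200, SlabModel(0.05, 32.0)))
        with pytest.raises(ValueError, match="q_window"):
            KratkyPorodThickness(phi=0.05, q_window=(0.3, 0.9)).fit(curve)


# ---------------------------------------------------------------------------
# swelling law
# ---------------------------------------------------------------------------

class TestSwellingLaw:
    def test_exact_law_recovered_exactly(self):
        phis = np.array([0.05, 0.1, 0.2, 0.3])
        fit = fit_swelling(list(zip(phis, 30.0 / phis)))
        assert fit.delta == pytest.approx(30.0, rel=1e-14)
        assert fit.delta_err == pytest.approx(0.0, abs=1e-12)

    def test_single_point_slope(self):
        fit = fit_swelling([(0.1, 350.0)])
        assert fit.delta == pytest.approx(35.0, rel=1e-14)

    def test_charged_series_bragg_spacings(self):
        pts = [(phi, ls.bragg_spacing(p.q0)) for phi, p in CHARGED_SERIES.items()]
        fit = fit_swelling(pts)
        assert abs(fit.delta - 30.0) <= 1.0

    def test_free_intercept_variant(self):
        phis = np.array([0.05, 0.1, 0.2, 0.3])
        d = 30.0 / phis + 5.0
        sw = SwellingLawFit(through_origin=False).fit(phis, d)
        assert sw.delta_ == pytest.approx(30.0, rel=1e-10)
        assert sw.intercept_ == pytest.approx(5.0, rel=1e-8)

    def test_validation(self):
        with pytest.raises(ValueError):
            fit_swelling([])
        with pytest.raises(ValueError, match="distinct"):
            fit_swelling([(0.1, 300.0), (0.1, 310.0)])


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

class TestDetectBraggPeak:
    def test_monotone_family_has_no_peak(self, q200):
        for xi_p in (20.0, 100.0, 500.0):
            p = NalletParameters(A_z=100.0, xi_p=xi_p, A_B=0.0, xi_l=0.0, q0=0.0)
            curve = make_curve(p, q200)
            assert detect_bragg_peak(curve) is None

    @pytest.mark.parametrize("params,q0", [
        (CHARGED_SERIES[0.05], 0.0105),
        (NEUTRAL_SERIES[0.30], 0.06207),
    ], ids=["charged-05", "neutral-30"])
    def test_peak_found_within_one_grid_step(self, params, q0):
        curve = ls.generate_nallet_curve(params)
        found = detect_bragg_peak(curve)
        assert found is not None
        step = q0 * (np.log(0.4 / 0.002) / 199)  # local log-grid spacing
        assert abs(found - q0) <= step

    def test_too_few_points_rejected(self):
        q = np.linspace(0.01, 0.1, 10)
        with pytest.raises(ValueError, match="20 points"):
            detect_bragg_peak(ScatteringCurve(q, np.ones(10)))


# ---------------------------------------------------------------------------
# Porod representation and overlap
# ---------------------------------------------------------------------------

class TestPorodRepresentation:
    def test_inverse_square_becomes_constant(self, q200):
        curve = ScatteringCurve(q200, 1.0 / q200**2)
        t = porod_representation(curve, 1.0)
        assert np.allclose(t.intensity, 1.0, rtol=1e-12)
        assert np.array_equal(t.q, q200)

    def test_equal_thickness_curves_collapse_at_high_q(self, q200):
        a = porod_representation(
            ScatteringCurve(q200, slab_intensity(q200, SlabModel(0.05, 32.0))), 0.05)
        b = porod_representation(
            ScatteringCurve(q200, slab_intensity(q200, SlabModel(0.10, 32.0))), 0.10)
        assert highq_overlap_metric(a, b, 0.05) < 0.01

    def test_amplifies_second_order_reflection(self, q200):
        """Multiplying by q² raises the weight of the reflection at 2q0
        relative to the first-order peak by a factor of four."""
        p = CHARGED_SERIES[0.20]
        curve = ls.generate_nallet_curve(
            p, ls.InstrumentConfig(resolution_sigmas=(0.0,)),
            second_order=(30.0, 150.0))
        t = porod_representation(curve, 0.20)
        i1 = np.argmin(np.abs(q200 - p.q0))
        i2 = np.argmin(np.abs(q200 - 2 * p.q0))
        raw_ratio = curve.intensity[i2] / curve.intensity[i1]
        porod_ratio = t.intensity[i2] / t.intensity[i1]
        assert porod_ratio == pytest.approx(4.0 * raw_ratio, rel=0.05)

    def test_zero_phi_rejected(self, q200):
        with pytest.raises(ValueError, match="phi"):
            porod_representation(ScatteringCurve(q200, np.ones(q200.size)), 0.0)


class TestHighQOverlapMetric:
    def test_identical_curves_give_zero(self, q200):
        c = ScatteringCurve(q200, 1.0 + q200)
        assert highq_overlap_metric(c, c, 0.05) == 0.0

    def test_constant_ratio_and_symmetry(self, q200):
        a = ScatteringCurve(q200, 1.0 + q200)
        b = ScatteringCurve(q200, 1.10 * (1.0 + q200))
        m_ab = highq_overlap_metric(a, b, 0.05)
        assert m_ab == pytest.approx(0.10, abs=1e-6)
        assert m_ab == highq_overlap_metric(b, a, 0.05)

    def test_empty_overlap_rejected(self, q200):
        a = ScatteringCurve(q200, np.ones(q200.size))
        with pytest.raises(ValueError, match="common q support"):
            highq_overlap_metric(a, a, 1.0)
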