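"""Coincidence-model predictions: sensitivity index, log-normal moments,
model variants M1-M3, and the parameter exploration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import lognorm

import distcapture as dc
from distcapture.models import DegenerateModelError


def matched_spec(variant, **kw):
    """Spec with identical (k=1, a=1) power laws in both modalities."""
    unit = dc.PowerFit(k=1.0, a=1.0, r_squared=1.0)
    return dc.ModelSpec(variant=variant, aud_fit=unit, vis_fit=unit, **kw)


class TestSensitivityDprime:
    def test_equal_means_give_zero(self):
        assert dc.sensitivity_dprime(2.0, 2.0, 1.0, 0.5, 0.3) == 0.0

    def test_hand_evaluated_closed_form(self):
        assert dc.sensitivity_dprime(2.0, 1.0, 1.0, 0.5, 0.0) == pytest.approx(
            1.0 / np.sqrt(1.25), rel=1e-9
        )

    def test_degenerate_difference_variance(self):
        with pytest.raises(DegenerateModelError):
            dc.sensitivity_dprime(2.0, 1.0, 1.0, 1.0, 1.0)

    def test_symmetry_under_modality_swap(self):
        a = dc.sensitivity_dprime(2.0, 1.2, 0.8, 0.3, 0.4)
        b = dc.sensitivity_dprime(1.2, 2.0, 0.3, 0.8, 0.4)
        assert a == pytest.approx(b)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        gap=st.floats(min_value=0.01, max_value=5.0),
        extra=st.floats(min_value=0.01, max_value=5.0),
        r1=st.floats(min_value=0.0, max_value=0.5),
        r2=st.floats(min_value=0.5, max_value=0.99),
    )
    def test_monotone_in_separation_and_correlation(self, gap, extra, r1, r2):
        assert dc.sensitivity_dprime(1.0 + gap + extra, 1.0, 1.0, 0.5, r1) > (
            dc.sensitivity_dprime(1.0 + gap, 1.0, 1.0, 0.5, r1)
        )
        assert dc.sensitivity_dprime(1.0 + gap, 1.0, 1.0, 0.5, r2) >= (
            dc.sensitivity_dprime(1.0 + gap, 1.0, 1.0, 0.5, r1)
        )


class TestLognormalMoments:
    def test_point_masses(self):
        assert dc.lognormal_moments(0.0, 0.0) == (1.0, 0.0)
        mu, sigma = dc.lognormal_moments(np.log(3.0), 0.0)
        assert mu == pytest.approx(3.0)
        assert sigma == 0.0

    def test_against_scipy_distribution(self):
        # independent oracle: scipy's log-normal mean/std
        s = float(np.log(10 ** 0.23))
        mu, sigma = dc.lognormal_moments(0.0, s)
        ref = lognorm(s=s, scale=np.exp(0.0))
        assert mu == pytest.approx(ref.mean(), rel=1e-9)
        assert sigma == pytest.approx(ref.std(), rel=1e-9)
        assert mu == pytest.approx(1.150544, rel=1e-6)
        assert sigma == pytest.approx(0.654651, rel=1e-6)

    def test_against_simulation(self):
        rng = np.random.default_rng(1)
        m, s = 0.4, 0.5
        draws = np.exp(rng.normal(m, s, size=1_000_000))
        mu, sigma = dc.lognormal_moments(m, s)
        assert mu == pytest.approx(draws.mean(), rel=0.005)
        assert sigma == pytest.approx(draws.std(), rel=0.005)

    def test_printed_mode_differs_only_in_mean(self):
        m, s = 0.2, 0.4
        mu_std, sig_std = dc.lognormal_moments(m, s)
        mu_prt, sig_prt = dc.lognormal_moments(m, s, printed=True)
        assert mu_prt == pytest.approx(np.exp(m + s ** 2))
        assert mu_prt > mu_std
        assert sig_prt == pytest.approx(sig_std)


class TestPredictDprime:
    def test_matched_targets_give_zero_for_all_variants(self):
        for variant in ("M1", "M2", "M3"):
            spec = matched_spec(variant)
            assert dc.predict_dprime(spec, 3.0, 3.0) == pytest.approx(0.0)

    def test_m1_symmetric_in_linear_offset(self):
        spec = matched_spec("M1")
        assert dc.predict_dprime(spec, 3.0, 2.0) == pytest.approx(
            dc.predict_dprime(spec, 3.0, 4.0), rel=1e-12
        )

    def test_m3_symmetric_in_log_ratio(self):
        # equal log ratios (x2 closer vs x2 farther) -> equal d'
        spec = matched_spec("M3")
        assert dc.predict_dprime(spec, 3.0, 1.5) == pytest.approx(
            dc.predict_dprime(spec, 3.0, 6.0), rel=1e-12
        )

    @pytest.mark.parametrize("v", [1.5, 3.0])
    def test_m3_asymmetric_on_linear_axis(self, v):
        # nearer sources are easier to reject than farther ones at equal
        # linear offset — the proximity-image asymmetry
        spec = matched_spec("M3")
        for delta in np.arange(0.25, min(1.26, v), 0.25):
            near = dc.predict_dprime(spec, v, v - delta)
            far = dc.predict_dprime(spec, v, v + delta)
            assert near > far

    def test_m3_linear_moment_mode_shifts_minimum(self):
        # re-expressing M3 through linear log-normal moments moves the curve
        # minimum below the visual distance and breaks log-ratio symmetry
        spec = matched_spec("M3", m3_space="linear")
        grid = np.linspace(1.0, 5.0, 401)
        curve = dc.predict_dprime(spec, 3.0, grid)
        argmin = grid[np.argmin(curve)]
        assert argmin < 3.0
        assert not np.isclose(
            dc.predict_dprime(spec, 3.0, 1.5), dc.predict_dprime(spec, 3.0, 6.0)
        )

    def test_m2_sigma_scales_with_distance(self):
        # at equal |mu difference|, larger sigma at far distances lowers d'
        spec = matched_spec("M2")
        assert dc.predict_dprime(spec, 3.0, 2.0) > dc.predict_dprime(spec, 3.0, 4.0)

    def test_k_aud_override_moves_the_minimum(self):
        spec = matched_spec("M3", k_aud_override=2.0)
        grid = np.linspace(0.5, 5.0, 901)
        curve = dc.predict_dprime(spec, 3.0, grid)
        assert grid[np.argmin(curve)] == pytest.approx(1.5, abs=0.01)

    def test_zero_variability_degenerates_consistently(self):
        # M3 with unit factors has zero log-SDs -> degenerate d'; the same
        # degeneracy surfaces for zero linear SDs in the index itself
        spec = matched_spec("M3", aud_factor=1.0, vis_factor=1.0)
        with pytest.raises(DegenerateModelError):
            dc.predict_dprime(spec, 3.0, 2.0)
        with pytest.raises(DegenerateModelError):
            dc.sensitivity_dprime(2.0, 1.0, 0.0, 0.0, 0.0)


class TestParameterSweep:
    def test_k_aud_positions_the_minimum_monotonically(self):
        spec = matched_spec("M3")
        grid = np.linspace(0.5, 8.0, 751)
        curves = dc.parameter_sweep(spec, 3.0, grid, "k_aud", [0.5, 1.0, 2.0])
        argmins = [grid[np.argmin(c)] for c in curves.values()]
        assert argmins == sorted(argmins, reverse=True)
        # minimum solves k * x = visual mean -> x = 3 / k
        for k, am in zip([0.5, 1.0, 2.0], argmins):
            assert am == pytest.approx(3.0 / k, abs=0.02)

    def test_r_sharpens_the_function(self):
        spec = matched_spec("M3")
        grid = np.array([1.5, 2.0, 2.5, 3.5, 4.0, 5.0])
        curves = dc.parameter_sweep(spec, 3.0, grid, "r", [0.0, 0.9])
        assert (curves[0.9] > curves[0.0]).all()

    def test_single_value_matches_predict_dprime(self):
        spec = matched_spec("M1")
        grid = np.array([2.0, 3.0, 4.0])
        (curve,) = dc.parameter_sweep(spec, 3.0, grid, "r", [0.4]).values()
        direct = dc.predict_dprime(spec.with_params(r=0.4, k_aud_override=1.0), 3.0, grid)
        assert np.allclose(curve, direct)

    def test_out_of_bound_values_rejected(self):
        spec = matched_spec("M3")
        with pytest.raises(dc.ParameterError):
            dc.parameter_sweep(spec, 3.0, [2.0, 3.0], "r", [1.5])
        with pytest.raises(dc.ParameterError):
            dc.parameter_sweep(spec, 3.0, [2.0, 3.0], "k_aud", [-1.0])
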