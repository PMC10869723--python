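"""Sine/linear spatial-gain fits, AIC/adjusted-r2 bookkeeping, physics."""

import math
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spatialgain as sg
from spatialgain.fitting import FitError, gaussian_aic


def _obs(x, y):
    return sg.observations_from_arrays(x, y)


GRID = [-24.0, -12.0, 0.0, 12.0, 24.0]


class TestSineFit:
    def test_exact_recovery_on_noiseless_data(self):
        y = sg.sine_model(GRID, 90.0, 20.0)
        fit = sg.fit_sine(_obs(GRID, y))
        assert fit.beta0 == pytest.approx(90.0, abs=1e-10)
        assert fit.beta1 == pytest.approx(20.0, abs=1e-10)
        assert fit.teg is None

    def test_constant_data(self):
        fit = sg.fit_sine(_obs(GRID, [100.0] * 5))
        assert fit.beta0 == pytest.approx(100.0)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert math.isnan(fit.adjusted_r2)  # zero total sum of squares

    def test_unbiased_under_noise(self):
        rng = np.random.default_rng(11)
        b0 = [
            sg.fit_sine(_obs(*sg.simulate_mgv_observations(rng))).beta0
            for _ in range(500)
        ]
        assert np.mean(b0) == pytest.approx(80.0, abs=0.5)

    def test_degenerate_designs_raise(self):
        with pytest.raises(FitError, match="at least 3"):
            sg.fit_sine(_obs([0.0, 12.0], [80.0, 75.0]))
        with pytest.raises(FitError, match="rank-deficient"):
            sg.fit_sine(_obs([12.0, -12.0, 12.0], [75.0, 74.0, 76.0]))


class TestLinearFit:
    def test_exact_recovery_and_teg(self):
        x = [0.0, 5.0, 10.0, 15.0, -5.0]
        y = [80.0 - 1.6 * abs(v) for v in x]
        fit = sg.fit_linear(_obs(x, y))
        assert fit.beta0 == pytest.approx(80.0, abs=1e-10)
        assert fit.beta1 == pytest.approx(1.6, abs=1e-10)
        assert fit.teg == pytest.approx(2.0, abs=1e-10)

    def test_constant_data_gives_zero_teg(self):
        fit = sg.fit_linear(_obs(GRID, [90.0] * 5))
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.teg == pytest.approx(0.0, abs=1e-10)

    def test_small_angle_link_between_families(self):
        """On sine data the linear slope approximates b1_sine * pi/180."""
        b1_sine = 2.0 * 180.0 / math.pi  # i.e. 2 gray values per radian
        y = sg.sine_model(GRID, 80.0, b1_sine)
        fit = sg.fit_linear(_obs(GRID, y))
        assert fit.beta1 == pytest.approx(b1_sine * math.pi / 180.0, rel=0.15)

    def test_beta0_equivalence_at_small_angles(self):
        """Within +-6 degrees the two families agree on MGV_00 to < 0.1."""
        grid = [-6.0, -3.0, 0.0, 3.0, 6.0]
        y = sg.sine_model(grid, 80.0, 33.5)
        s = sg.fit_sine(_obs(grid, y))
        l = sg.fit_linear(_obs(grid, y))
        assert abs(s.beta0 - l.beta0) < 0.1


class TestGoodnessOfFit:
    def test_adjusted_r2_hand_case(self):
        """y = {0,1,1} on x = {0,1,2}: r2 = 0.75, adjusted = 0.5."""
        fit = sg.fit_linear(_obs([0.0, 1.0, 2.0], [100.0, 99.0, 99.0]))
        # sign-flipped copy of the classic hand case; r2 is unaffected
        assert 1.0 - fit.rss / fit.tss == pytest.approx(0.75)
        assert sg.adjusted_r2(fit) == pytest.approx(0.5)

    def test_perfect_fit(self):
        fit = sg.fit_linear(_obs([0.0, 1.0, 2.0], [3.0, 2.0, 1.0]))
        assert sg.adjusted_r2(fit) == pytest.approx(1.0)
        assert math.isnan(sg.aic(fit))  # rss = 0: AIC undefined

    def test_aic_formula_hand_case(self):
        n, rss = 3, 0.5
        expected = n * math.log(2.0 * math.pi * rss / n) + n + 2 * 3
        assert gaussian_aic(rss, n) == pytest.approx(expected, abs=1e-12)

    def test_aic_monotone_in_rss_and_log_identity(self):
        assert gaussian_aic(1.0, 10) < gaussian_aic(2.0, 10)
        assert gaussian_aic(2.0, 10) - gaussian_aic(1.0, 10) == pytest.approx(
            10 * math.log(2.0)
        )

    def test_matches_r_lm_oracle(self, tmp_path):
        """Coefficients and AIC agree with R's lm()/AIC() on the same data."""
        rng = np.random.default_rng(3)
        x, y = sg.simulate_mgv_observations(rng)
        fit = sg.fit_sine(_obs(x, y))
        data = tmp_path / "d.csv"
        np.savetxt(
            data,
            np.column_stack([np.sin(2 * np.deg2rad(np.abs(x))) / 2, y]),
            delimiter=",",
            header="s,y",
            comments="",
        )
        script = textwrap.dedent(
            f"""
            d <- read.csv("{data}")
            m <- lm(y ~ s, data = d)
            cat(sprintf("%.12f", c(coef(m)[1], -coef(m)[2], AIC(m))), sep = "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        b0, b1, aic_r = (float(v) for v in out.stdout.split())
        assert fit.beta0 == pytest.approx(b0, abs=1e-6)
        assert fit.beta1 == pytest.approx(b1, abs=1e-6)
        assert fit.aic == pytest.approx(aic_r, abs=1e-6)


class TestModelComparison:
    def test_identical_fits_tie(self):
        # residuals orthogonal to both regressors: the two families yield
        # identical fitted values (zero slopes), hence identical AICs
        x = np.asarray(GRID)
        rng = np.random.default_rng(0)
        X = np.column_stack(
            [np.ones(5), np.sin(2 * np.deg2rad(np.abs(x))) / 2.0, np.abs(x)]
        )
        raw = rng.normal(0, 2.0, 5)
        resid = raw - X @ np.linalg.lstsq(X, raw, rcond=None)[0]
        y = 80.0 + resid
        comp = sg.compare_models(sg.fit_sine(_obs(x, y)), sg.fit_linear(_obs(x, y)))
        assert comp.delta_aic == pytest.approx(0.0, abs=1e-9)
        assert comp.preferred == "linear"  # parsimony tie-break

    def test_mismatched_n_rejected(self):
        s = sg.fit_sine(_obs(GRID, sg.sine_model(GRID, 80, 20) + 0.1))
        l = sg.fit_linear(_obs(GRID[:4], [80.0, 75.0, 71.0, 74.9]))
        with pytest.raises(ValueError, match="different n"):
            sg.compare_models(s, l)

    def test_ensemble_selection_direction(self):
        """Study-scale replicates prefer the generating family."""
        sine_wins = lin_wins = 0
        for i in range(40):
            rng = np.random.default_rng(500 + i)
            for family, counter in (("sine", "s"), ("linear", "l")):
                df = sg.simulate_study_observations(rng, family=family)
                obs = _obs(df.fpa_deg, df.mgv)
                comp = sg.compare_models(sg.fit_sine(obs), sg.fit_linear(obs))
                if family == "sine":
                    sine_wins += comp.preferred == "sine"
                else:
                    lin_wins += comp.preferred == "linear"
        assert sine_wins >= 32  # >= 80%
        assert lin_wins > 20  # majority


class TestPredict:
    def test_beta0_at_zero_for_both_families(self):
        y = sg.sine_model(GRID, 85.0, 30.0)
        for fit in (sg.fit_sine(_obs(GRID, y)), sg.fit_linear(_obs(GRID, y))):
            assert sg.predict_mgv(fit, 0.0) == pytest.approx(fit.beta0)

    def test_sine_prediction_symmetric_and_45deg_value(self):
        y = sg.sine_model(GRID, 90.0, 20.0)
        fit = sg.fit_sine(_obs(GRID, y))
        assert sg.predict_mgv(fit, 17.0) == pytest.approx(sg.predict_mgv(fit, -17.0))
        assert sg.predict_mgv(fit, 45.0) == pytest.approx(80.0)  # sin 90 = 1


class TestProperties:
    @settings(derandomize=True, max_examples=30)
    @given(k=st.floats(0.2, 2.5))
    def test_teg_scale_invariance(self, k):
        rng = np.random.default_rng(4)
        x, y = sg.simulate_mgv_observations(rng)
        t1 = sg.fit_linear(_obs(x, y)).teg
        t2 = sg.fit_linear(_obs(x, np.clip(k * y, 0, 255))).teg
        assert t2 == pytest.approx(t1, abs=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_order_and_sign_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = sg.simulate_mgv_observations(rng)
        perm = rng.permutation(x.size)
        signs = rng.choice([-1.0, 1.0], size=x.size)
        for fitter in (sg.fit_sine, sg.fit_linear):
            a = fitter(_obs(x, y))
            b = fitter(_obs((x * signs)[perm], y[perm]))
            assert b.beta0 == pytest.approx(a.beta0, abs=1e-9)
            assert b.beta1 == pytest.approx(a.beta1, abs=1e-9)

    def test_bias_vanishes_with_noise(self):
        rng = np.random.default_rng(6)
        for sd, tol in ((1.0, 0.2), (0.01, 0.01)):
            b0 = [
                sg.fit_sine(
                    _obs(*sg.simulate_mgv_observations(rng, noise_sd=sd))
                ).beta0
                for _ in range(200)
            ]
            assert np.mean(b0) == pytest.approx(80.0, abs=tol)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(3, 11))
            x = rng.uniform(-30, 30, n)
            if np.ptp(np.abs(x)) < 1.0:
                continue
            y = rng.uniform(40, 120, n)
            for fitter, reg in (
                (sg.fit_sine, np.sin(2 * np.deg2rad(np.abs(x))) / 2),
                (sg.fit_linear, np.abs(x)),
            ):
                fit = fitter(_obs(x, np.clip(y, 0, 255)))
                X = np.column_stack([np.ones(n), reg])
                beta = np.linalg.solve(X.T @ X, X.T @ np.clip(y, 0, 255))
                assert fit.beta0 == pytest.approx(beta[0], abs=1e-9)
                assert fit.beta1 == pytest.approx(-beta[1], abs=1e-9)


class TestPhysics:
    def test_wavelength_in_muscle_and_gel(self):
        assert round(sg.acoustic_wavelength(1580.0, 15e6)) == 105
        assert sg.acoustic_wavelength(1460.0, 15e6) == pytest.approx(97.3, abs=0.05)

    def test_axial_resolution_is_half_pulse_length(self):
        assert sg.axial_resolution(105.0) == pytest.approx(52.5)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sg.acoustic_wavelength(0.0, 15e6)
        with pytest.raises(ValueError):
            sg.axial_resolution(-1.0)

    def test_linearization_error_values(self):
        x = math.radians(20.0)
        expected = 100.0 * (2 * x - math.sin(2 * x)) / math.sin(2 * x)
        assert sg.linearization_error(20.0) == pytest.approx(expected)
        assert 8.0 < sg.linearization_error(20.0) < 9.0
        assert sg.linearization_error(45.0) == pytest.approx(
            100.0 * (math.pi / 2 - 1.0), abs=1e-9
        )
        assert sg.linearization_error(0.5) < 0.01  # -> 0 as angle -> 0
        with pytest.raises(ValueError):
            sg.linearization_error(0.0)
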