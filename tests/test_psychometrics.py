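import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from avmotion.exceptions import UnidentifiableDataError, ValidationError
from avmotion.kinematics import VelocityDistribution
from avmotion.psychometrics import (
    AcrossTrialFit,
    BinnedData,
    PsychFit,
    bin_responses,
    binned_loglik,
    bootstrap_fit,
    fit_across_trial_model,
    fit_cumulative_gaussian,
    model_implied_curve,
    rmse,
)

GAINS = np.linspace(-0.5, 0.5, 13)


def simulate_binned(alpha, sigma, lapse, n_per, seed, gains=GAINS):
    rng = np.random.default_rng(seed)
    p = lapse + (1 - 2 * lapse) * ndtr((gains - alpha) / sigma)
    k = rng.binomial(n_per, p)
    return BinnedData(gains, k, np.full(gains.size, n_per))


def trial_frame(gains, responses, modality="audio", aj=False, vj=False):
    return pd.DataFrame({
        "participant_id": "p1",
        "modality": modality,
        "audio_jitter": aj,
        "visual_jitter": vj,
        "gain": gains,
        "response": responses,
        "head_velocity": 80.0,
        "sweep_index": 3,
    })


class TestBinResponses:
    def test_counting(self):
        df = trial_frame([0.1] * 30, ["with"] * 12 + ["against"] * 18)
        data = bin_responses(df)
        assert data.n_with.tolist() == [12]
        assert data.n_total.tolist() == [30]

    def test_canonical_slice(self):
        gains = np.repeat(GAINS, 30)
        rng = np.random.default_rng(0)
        resp = np.where(rng.random(gains.size) < 0.5, "with", "against")
        data = bin_responses(trial_frame(gains, resp))
        assert data.gain.size == 13
        assert (data.n_total == 30).all()

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            bin_responses(trial_frame([], []))

    def test_mixed_conditions_rejected(self):
        df = pd.concat([
            trial_frame([0.1], ["with"], modality="audio"),
            trial_frame([0.1], ["with"], modality="visual"),
        ])
        with pytest.raises(ValidationError):
            bin_responses(df)


class TestFitCumulativeGaussian:
    def test_parameter_recovery_large_n(self):
        data = simulate_binned(0.05, 0.15, 0.0, 10_000, seed=1)
        fit = fit_cumulative_gaussian(data)
        assert fit.converged
        assert abs(fit.alpha - 0.05) < 0.005
        assert abs(fit.sigma - 0.15) / 0.15 < 0.05

    def test_symmetric_data_zero_alpha(self):
        # k[i] + k[-1-i] = n makes the proportions symmetric about g = 0
        k = np.array([1, 2, 4, 8, 14, 18, 20, 22, 26, 32, 36, 38, 39])
        assert np.all(k + k[::-1] == 40)
        data = BinnedData(GAINS, k, np.full(13, 40))
        fit = fit_cumulative_gaussian(data)
        assert abs(fit.alpha) < 1e-3

    def test_matches_grid_oracle(self):
        data = simulate_binned(0.08, 0.2, 0.01, 30, seed=2)
        fit = fit_cumulative_gaussian(data)
        alphas = np.linspace(-0.2, 0.3, 81)
        sigmas = np.geomspace(0.05, 0.8, 81)
        lapses = np.linspace(0, 0.02, 5)
        best = (-np.inf, None)
        for lap in lapses:
            p = lap + (1 - 2 * lap) * ndtr(
                (GAINS[None, None, :] - alphas[:, None, None])
                / sigmas[None, :, None])
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll = (data.n_with * np.log(p)
                  + (data.n_total - data.n_with) * np.log1p(-p)).sum(axis=2)
            idx = np.unravel_index(np.argmax(ll), ll.shape)
            if ll[idx] > best[0]:
                best = (ll[idx], (alphas[idx[0]], sigmas[idx[1]], lap))
        assert fit.loglik >= best[0] - 1e-6
        da = alphas[1] - alphas[0]
        assert abs(fit.alpha - best[1][0]) <= da + 1e-9
        assert abs(math.log(fit.sigma / best[1][1])) <= math.log(
            sigmas[1] / sigmas[0]) + 1e-9

    def test_unidentifiable_data(self):
        data = BinnedData(GAINS, np.full(13, 30), np.full(13, 30))
        with pytest.raises(UnidentifiableDataError):
            fit_cumulative_gaussian(data)

    def test_too_few_levels(self):
        data = BinnedData(np.array([-0.1, 0.1]), [2, 28], [30, 30])
        with pytest.raises(ValidationError):
            fit_cumulative_gaussian(data)

    def test_shift_equivariance(self):
        data = simulate_binned(0.0, 0.18, 0.0, 500, seed=3)
        fit0 = fit_cumulative_gaussian(data)
        c = 0.13
        shifted = BinnedData(data.gain + c, data.n_with, data.n_total)
        fit1 = fit_cumulative_gaussian(shifted)
        assert fit1.alpha == pytest.approx(fit0.alpha + c, abs=2e-3)
        assert fit1.sigma == pytest.approx(fit0.sigma, rel=2e-2)

    @pytest.mark.parametrize("seed", range(5))
    def test_mle_dominance(self, seed):
        alpha, sigma, lapse = 0.05, 0.2, 0.01
        data = simulate_binned(alpha, sigma, lapse, 30, seed=seed)
        fit = fit_cumulative_gaussian(data)
        gen = PsychFit(alpha, sigma, lapse, 0.0, True)
        assert fit.loglik >= binned_loglik(gen, data) - 1e-9


class TestBootstrapFit:
    def test_determinism(self):
        data = simulate_binned(0.05, 0.2, 0.0, 30, seed=4)
        b1 = bootstrap_fit(data, n=50, seed=7)
        b2 = bootstrap_fit(data, n=50, seed=7)
        np.testing.assert_array_equal(b1.samples, b2.samples)

    def test_degenerate_step_function(self):
        # huge-n step data: essentially no resampling variance in alpha
        k = np.where(GAINS > 0, 4000, 0)
        k[GAINS == 0] = 2000
        data = BinnedData(GAINS, k, np.full(13, 4000))
        boot = bootstrap_fit(data, n=50, seed=0)
        se_alpha, _ = boot.se()
        assert se_alpha < 0.01

    def test_bootstrap_consistency(self):
        """Bootstrap SE of alpha tracks the SD across fresh simulations.

        Scaled down from the production default (2000 replicates) to keep
        the suite fast; the comparison is tolerance 25% as specified.
        """
        alpha, sigma = 0.05, 0.2
        data = simulate_binned(alpha, sigma, 0.0, 30, seed=5)
        boot = bootstrap_fit(data, n=400, seed=6)
        se_boot, _ = boot.se()
        fresh = [fit_cumulative_gaussian(
            simulate_binned(alpha, sigma, 0.0, 30, seed=100 + i),
            n_starts=1).alpha for i in range(200)]
        sd_fresh = np.std(fresh, ddof=1)
        assert abs(se_boot - sd_fresh) / sd_fresh < 0.25


class TestAcrossTrialModel:
    def test_zero_variance_matches_standard(self):
        data = simulate_binned(0.05, 0.15, 0.0, 200, seed=8)
        hd = VelocityDistribution(80.0, 0.0, 100)
        at = fit_across_trial_model(data, hd)
        st = fit_cumulative_gaussian(data)
        assert at.g0 == pytest.approx(st.alpha, abs=2e-3)
        assert at.sigma_amp / hd.mean == pytest.approx(st.sigma, rel=0.01)

    def test_high_head_variance_beats_standard(self):
        """Across-trial noise compresses the asymptotes of the standard fit
        and the marginalized model attains higher log-likelihood."""
        rng = np.random.default_rng(9)
        g0, sigma_amp = 0.0, 8.0
        hd_true = VelocityDistribution(60.0, 35.0**2, 500)
        n_per = 400
        k = []
        for g in GAINS:
            h = np.empty(n_per)
            filled = 0
            while filled < n_per:
                d = rng.normal(60.0, 35.0, 2 * n_per)
                d = d[d >= 15.0][: n_per - filled]
                h[filled:filled + d.size] = d
                filled += d.size
            amp = (g - g0) * h + rng.normal(0, sigma_amp, n_per)
            k.append(int((amp > 0).sum()))
        data = BinnedData(GAINS, k, np.full(13, n_per))
        st = fit_cumulative_gaussian(data)
        at = fit_across_trial_model(data, hd_true)
        assert at.loglik > st.loglik
        # standard fit pushes lapse to its bound to mimic compressed tails
        assert st.lapse == pytest.approx(0.02, abs=1e-6)

    def test_quadrature_matches_monte_carlo(self):
        hd = VelocityDistribution(80.0, 15.0**2, 500)
        fit = AcrossTrialFit(0.03, 10.0, 0.01, hd, 0.0, True)
        curve = model_implied_curve(fit, GAINS)
        rng = np.random.default_rng(10)
        h = rng.normal(80.0, 15.0, 2_000_000)
        h = h[h >= 15.0][:1_000_000]
        for g, p in zip(GAINS, curve):
            mc = 0.01 + 0.98 * ndtr((g - 0.03) * h / 10.0).mean()
            assert abs(p - mc) < 1e-4


class TestModelImpliedCurve:
    def test_pse_gives_half(self):
        fit = PsychFit(0.1, 0.2, 0.0, 0.0, True)
        assert model_implied_curve(fit, np.array([0.1]))[0] == pytest.approx(0.5)

    def test_monotone(self):
        fit = PsychFit(0.0, 0.2, 0.01, 0.0, True)
        curve = model_implied_curve(fit, GAINS)
        assert np.all(np.diff(curve) > 0)
        assert curve.min() >= 0.01 and curve.max() <= 0.99

    def test_matches_large_simulation(self):
        from avmotion.cue_models import Modality
        from avmotion.synthetic_data import (
            Condition, ObserverParams, analytic_psychometric, simulate_response)

        params = ObserverParams(8.0, 6.0, 8.0, 6.0, 4.0, head_mu=80.0)
        cond = Condition(Modality.AUDIO)
        pse, sigma = analytic_psychometric(params, cond)
        fit = PsychFit(pse, sigma, 0.0, 0.0, True)
        rng = np.random.default_rng(11)
        n = 1_000_000
        for g in (-0.25, 0.0, 0.25):
            r = simulate_response(g, cond, np.full(n, 80.0), params, rng)
            p = model_implied_curve(fit, np.array([g]))[0]
            assert abs(r.mean() - p) < 0.005


class TestRmse:
    def test_identical(self):
        assert rmse(np.ones(5), np.ones(5)) == 0.0

    def test_hand_arithmetic(self):
        assert rmse(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == 1.0

    def test_constant_offset(self):
        x = np.linspace(0, 1, 7)
        assert rmse(x + 0.2, x) == pytest.approx(0.2)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            rmse(np.ones(3), np.ones(4))


class TestBootstrapCoverage:
    def test_ci_coverage(self):
        """95% percentile CIs for alpha cover the truth at roughly nominal
        rate. Scaled down (120 replications, 200 bootstrap draws) from the
        specified 500x2000; the acceptance band is widened accordingly."""
        alpha, sigma = 0.05, 0.2
        hits = 0
        n_rep = 120
        for i in range(n_rep):
            data = simulate_binned(alpha, sigma, 0.0, 30, seed=2000 + i)
            boot = bootstrap_fit(data, n=200, seed=3000 + i)
            lo, hi = boot.percentile_ci(0)
            hits += lo <= alpha <= hi
        assert 0.86 <= hits / n_rep <= 0.995
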