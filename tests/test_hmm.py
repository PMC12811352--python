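"""Unit and property tests for the known-state movement HMM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from sealars import hmm
from sealars.hmm import (
    HMMParameters,
    _Parameterisation,
    angle_cdf,
    angle_density,
    forward_loglik,
    step_density,
    wrap_angle,
)

from conftest import random_toy_instance


# --------------------------------------------------------------------------
# densities
# --------------------------------------------------------------------------


class TestStepDensity:
    def test_exponential_special_case(self):
        # mu == sigma gives shape 1: density at 0+ is (1 - pi0) / mu
        mu = 2.5
        assert step_density(1e-12, mu, mu, 0.2) == pytest.approx(0.8 / mu, rel=1e-6)

    @pytest.mark.parametrize("mu,sigma,pi0", [(3.38, 1.76, 0.0), (0.09, 0.09, 0.3),
                                              (7.63, 2.18, 0.0)])
    def test_integrates_to_one(self, mu, sigma, pi0):
        val, _ = integrate.quad(lambda x: step_density(x, mu, sigma, pi0), 0, np.inf)
        assert val + pi0 == pytest.approx(1.0, abs=1e-6)

    def test_atom_at_zero(self):
        assert step_density(0.0, 1.0, 1.0, 0.25) == 0.25

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            step_density(-0.1, 1.0, 1.0)

    def test_sampler_mean_matches_parameter(self):
        rng = np.random.default_rng(7)
        mu, sigma = 3.38, 1.76
        x = rng.gamma(mu**2 / sigma**2, sigma**2 / mu, size=100_000)
        se = sigma / np.sqrt(len(x))
        assert abs(x.mean() - mu) < 3 * se


class TestAngleDensity:
    def test_uniform_limit(self):
        phi = np.linspace(-np.pi, np.pi, 7)
        assert angle_density(phi, 0.0) == pytest.approx(1 / (2 * np.pi))

    def test_mode_closed_form(self):
        g = 0.81
        expected = (1 + g) / (1 - g) / (2 * np.pi)
        assert angle_density(0.0, g) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("conc", [0.0, 0.07, 0.53, 0.81, 0.99])
    def test_integrates_to_one(self, conc):
        val, _ = integrate.quad(lambda p: angle_density(p, conc), -np.pi, np.pi,
                                limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_wrapping_and_symmetry(self):
        assert angle_density(3 * np.pi / 2, 0.5) == pytest.approx(
            angle_density(-np.pi / 2, 0.5))
        assert angle_density(1.2, 0.5) == pytest.approx(angle_density(-1.2, 0.5))

    def test_cdf_consistent_with_density(self):
        for conc in (0.0, 0.46, 0.81):
            num, _ = integrate.quad(lambda p: angle_density(p, conc), -np.pi, 1.1)
            assert angle_cdf(1.1, conc) == pytest.approx(num, abs=1e-8)

    @settings(derandomize=True, max_examples=50)
    @given(phi=st.floats(-50, 50), conc=st.floats(0, 0.999, exclude_max=True))
    def test_density_properties_hold_for_arbitrary_inputs(self, phi, conc):
        d = angle_density(phi, conc)
        assert d > 0
        assert d == pytest.approx(angle_density(phi + 2 * np.pi, conc), rel=1e-9)
        assert d == pytest.approx(angle_density(-phi, conc), rel=1e-9)
        # density is maximal at the mean direction
        assert d <= angle_density(0.0, conc) * (1 + 1e-12)

    def test_wrap_angle_range(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-20, 20, 500)
        w = wrap_angle(phi)
        assert np.all((w > -np.pi) & (w <= np.pi))
        np.testing.assert_allclose(np.cos(w), np.cos(phi), atol=1e-12)


# --------------------------------------------------------------------------
# enumeration oracles
# --------------------------------------------------------------------------


def _oracle_emissions(df, params):
    """Emission matrix computed directly from scipy distributions."""
    T, K = len(df), params.n_states
    b = np.ones((T, K))
    for t in range(T):
        step = df["step"].iloc[t]
        phi = df["angle"].iloc[t]
        for z in range(params.n_emitting):
            val = 1.0
            if not np.isnan(step):
                mu, sg = params.mu[z], params.sigma[z]
                if step == 0:
                    val *= params.zero_mass[z]
                else:
                    val *= (1 - params.zero_mass[z]) * stats.gamma.pdf(
                        step, a=mu**2 / sg**2, scale=sg**2 / mu)
            if not np.isnan(phi):
                g = params.angle_conc[z]
                val *= (1 - g**2) / (2 * np.pi * (1 + g**2 - 2 * g * np.cos(phi)))
            b[t, z] = val
    return b


def _oracle_allowed(df, params):
    allowed = []
    for c in df["known_state"]:
        if c == "free":
            allowed.append([i for i, s in enumerate(params.states)
                            if s not in ("N", "Unk")])
        else:
            allowed.append([params.states.index(c)])
    return allowed


def _enumerate_paths(df, params):
    """Brute-force likelihood, best path, and smoothed marginals."""
    b = _oracle_emissions(df, params)
    allowed = _oracle_allowed(df, params)
    T, K = b.shape
    total = 0.0
    best_p, best_path = -1.0, None
    marg = np.zeros((T, K))
    for path in itertools.product(*allowed):
        p = params.delta[path[0]] * b[0, path[0]]
        for t in range(1, T):
            p *= params.tpm[path[t - 1], path[t]] * b[t, path[t]]
        total += p
        for t in range(T):
            marg[t, path[t]] += p
        if p > best_p:
            best_p, best_path = p, path
    return np.log(total), best_path, marg / total


class TestForwardOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_forward_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        df, params = random_toy_instance(rng, T=6, K=3)
        ll_oracle, _, _ = _enumerate_paths(df, params)
        assert forward_loglik(df, params) == pytest.approx(ll_oracle, abs=1e-10)

    def test_single_interval_known_state(self):
        rng = np.random.default_rng(1)
        df, params = random_toy_instance(rng, T=1, K=3, with_missing=False)
        df["known_state"] = [params.states[0]]
        params = HMMParameters(params.states, params.mu, params.sigma,
                               params.angle_conc, params.tpm, [1.0, 0.0, 0.0])
        expected = np.log(_oracle_emissions(df, params)[0, 0])
        assert forward_loglik(df, params) == pytest.approx(expected, abs=1e-10)

    def test_viterbi_equals_enumeration(self):
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            df, params = random_toy_instance(rng, T=8, K=3)
            _, best_path, _ = _enumerate_paths(df, params)
            got = hmm.viterbi_decode(df, params)
            assert tuple(params.states.index(s) for s in got) == best_path

    def test_viterbi_fully_constrained(self):
        rng = np.random.default_rng(5)
        df, params = random_toy_instance(rng, T=10, K=3, with_mask=False)
        codes = [params.states[i] for i in rng.integers(0, 3, size=10)]
        df["known_state"] = codes
        assert hmm.viterbi_decode(df, params).tolist() == codes

    def test_local_probs_equal_enumeration_marginals(self):
        rng = np.random.default_rng(42)
        df, params = random_toy_instance(rng, T=6, K=3)
        _, _, marg = _enumerate_paths(df, params)
        got = hmm.local_state_probs(df, params)
        np.testing.assert_allclose(got.to_numpy(), marg, atol=1e-10)

    def test_local_probs_rows_sum_to_one_and_masks(self, five_state_intervals):
        params = __import__("sealars").simulate.GREY_PROFILE
        probs = hmm.local_state_probs(five_state_intervals, params)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)
        known_n = five_state_intervals["known_state"] == "N"
        assert np.allclose(probs.loc[known_n.to_numpy(), "N"], 1.0)


class TestLikelihoodProperties:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        df, params = random_toy_instance(rng, T=20, K=3, with_mask=False)
        ll = forward_loglik(df, params)
        perm = [2, 0, 1]
        permuted = HMMParameters(
            params.states,
            params.mu[perm], params.sigma[perm], params.angle_conc[perm],
            params.tpm[np.ix_(perm, perm)], params.delta[perm],
        )
        assert forward_loglik(df, permuted) == pytest.approx(ll, abs=1e-9)

    def test_masking_never_increases_likelihood(self):
        rng = np.random.default_rng(12)
        df, params = random_toy_instance(rng, T=15, K=3, with_mask=False)
        ll_free = forward_loglik(df, params)
        df2 = df.copy()
        df2.loc[df2.index[3], "known_state"] = params.states[1]
        assert forward_loglik(df2, params) <= ll_free + 1e-12

    def test_true_path_mask_dominates_any_single_path(self, grey_profile,
                                                      grey_movement_intervals):
        """Masking all intervals to the truth sums more probability than any
        single alternative path can carry."""
        df = grey_movement_intervals.groupby("individual").head(30)
        df = df[df["individual"] == "ind000"].copy()
        truth = df["state"].tolist()
        df["known_state"] = truth
        ll_masked = forward_loglik(df, grey_profile)
        rng = np.random.default_rng(0)
        b = _oracle_emissions(df, grey_profile)
        for _ in range(20):
            path = rng.integers(0, 3, size=len(df))
            lp = np.log(grey_profile.delta[path[0]]) + np.log(b[0, path[0]])
            for t in range(1, len(df)):
                lp += np.log(grey_profile.tpm[path[t - 1], path[t]] * b[t, path[t]])
            assert ll_masked >= lp - 1e-9


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


class TestFit:
    def test_single_state_fit_matches_iid_mle(self):
        """With one state the HMM likelihood factorises, so the fit must equal
        independent maximum-likelihood fits of the two distributions."""
        rng = np.random.default_rng(8)
        mu, sigma, conc = 6.5, 2.0, 0.6
        n = 4000
        steps = rng.gamma(mu**2 / sigma**2, sigma**2 / mu, size=n)
        angles = np.mod(rng.standard_cauchy(n) * (-np.log(conc)) + np.pi,
                        2 * np.pi) - np.pi
        df = pd.DataFrame({"individual": "a", "step": steps, "angle": angles})
        fit = hmm.fit_ml(df, n_states=1, n_restarts=3, seed=1)
        # independent oracle: iid MLEs via scipy
        a_hat, _, scale_hat = stats.gamma.fit(steps, floc=0)
        mu_iid = a_hat * scale_hat
        sigma_iid = np.sqrt(a_hat) * scale_hat
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(
            lambda g: -np.sum(np.log(hmm.angle_density(angles, g))),
            bounds=(1e-6, 1 - 1e-6), method="bounded")
        assert fit.params.mu[0] == pytest.approx(mu_iid, rel=1e-3)
        assert fit.params.sigma[0] == pytest.approx(sigma_iid, rel=1e-3)
        assert fit.params.angle_conc[0] == pytest.approx(res.x, abs=1e-3)

    def test_restart_stability_and_relabelling(self, grey_movement_intervals):
        fit = hmm.fit_ml(grey_movement_intervals, n_states=3, n_restarts=3, seed=2)
        # movement states relabelled by ascending mean step
        assert np.all(np.diff(fit.params.mu) > 0)
        top = np.sort(fit.restarts["loglik"].to_numpy())[-2:]
        assert top[1] - top[0] < 1.0  # replicated optimum
        # decoding accuracy on well-separated simulation
        truth = grey_movement_intervals["state"]
        acc = (fit.viterbi == truth).mean()
        assert acc >= 0.90

    def test_five_state_parameter_count(self):
        par = _Parameterisation(("fARS", "bARS", "Tr", "N", "Unk"),
                                np.zeros(4, dtype=bool), False)
        assert par.n_params == 36

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            HMMParameters(("a", "b"), [1.0, -1.0], [1, 1], [0.5, 0.5],
                          [[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5])
        with pytest.raises(ValueError):
            HMMParameters(("a", "b"), [1.0, 1.0], [1, 1], [0.5, 0.5],
                          [[0.9, 0.5], [0.5, 0.5]], [0.5, 0.5])


# --------------------------------------------------------------------------
# pseudo-residuals and resampling
# --------------------------------------------------------------------------


class TestPseudoResiduals:
    def test_zero_step_with_atom_is_finite(self):
        params = HMMParameters(("Tr",), [1.0], [1.0], [0.3], [[1.0]], [1.0],
                               zero_mass=[0.3])
        df = pd.DataFrame({"individual": "a", "step": [0.0, 1.0, 0.0],
                           "angle": [np.nan, 0.2, 0.1]})
        res = hmm.pseudo_residuals(df, params)
        assert np.isfinite(res["step_residual"]).all()
        # mid-point of the CDF jump at the atom
        expected = stats.norm.ppf(0.15)
        assert res["step_residual"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_missing_streams_give_missing_residuals(self, five_state_intervals):
        from sealars.simulate import GREY_PROFILE
        res = hmm.pseudo_residuals(five_state_intervals, GREY_PROFILE)
        gaps = five_state_intervals["step"].isna().to_numpy()
        assert res.loc[gaps, "step_residual"].isna().all()


class TestSampleStateSequences:
    def test_indicator_rows_reproduce_state(self):
        probs = pd.DataFrame(np.eye(3)[[0, 2, 1, 1]], columns=["a", "b", "c"])
        draws = hmm.sample_state_sequences(probs, n_draws=5, seed=0)
        for col in draws:
            assert draws[col].tolist() == ["a", "c", "b", "b"]

    def test_marginal_frequencies(self):
        probs = pd.DataFrame([[0.5, 0.5, 0.0]] * 1, columns=["a", "b", "c"])
        draws = hmm.sample_state_sequences(probs, n_draws=10_000, seed=1)
        freq = (draws.iloc[0] == "a").mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(freq - 0.5) < 3 * se
        assert not (draws.iloc[0] == "c").any()

    def test_seed_reproducibility(self):
        probs = pd.DataFrame(np.random.default_rng(3).dirichlet(np.ones(3), 50),
                             columns=["a", "b", "c"])
        d1 = hmm.sample_state_sequences(probs, n_draws=10, seed=7)
        d2 = hmm.sample_state_sequences(probs, n_draws=10, seed=7)
        pd.testing.assert_frame_equal(d1, d2)
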