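import itertools

import numpy as np
import pytest

from hsmmseg import (
    EMConfig,
    EmissionModel,
    HSMMSpec,
    PosteriorProfile,
    SojournModel,
    complete_likelihood,
    decode_smoothed,
    em_fit,
    flat_sojourn,
    forward_backward,
    init_emission_quantile,
    uniform_offdiag,
    viterbi,
)
from conftest import random_spec


def enumerate_loglik(obs, spec):
    """Exhaustive sum of complete likelihoods over all state sequences."""
    T = len(obs)
    lls = [
        complete_likelihood(np.array(seq), obs, spec)
        for seq in itertools.product(range(spec.J), repeat=T)
    ]
    return np.logaddexp.reduce(lls), max(lls)


class TestCompleteLikelihood:
    def test_single_state_no_transitions(self, rng):
        spec = random_spec(rng, J=1, M=10)
        obs = rng.normal(0, 1, 3)
        from hsmmseg import emission_logdensity, sojourn_survivor

        expected = (
            np.log(spec.pi[0])
            + np.log(sojourn_survivor(spec.sojourn, 0, 3))
            + emission_logdensity(spec.emission, obs)[:, 0].sum()
        )
        got = complete_likelihood(np.zeros(3, dtype=int), obs, spec)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_hand_expanded_single_transition(self, rng):
        from hsmmseg import emission_logdensity, sojourn_pmf, sojourn_survivor

        spec = random_spec(rng, J=2, M=10)
        obs = rng.normal(0, 1, 5)
        states = np.array([0, 0, 1, 1, 1])
        logb = emission_logdensity(spec.emission, obs)
        expected = (
            np.log(spec.pi[0])
            + np.log(sojourn_pmf(spec.sojourn, 0, 2))
            + np.log(spec.A[0, 1])
            + np.log(sojourn_survivor(spec.sojourn, 1, 3))
            + logb[:2, 0].sum()
            + logb[2:, 1].sum()
        )
        assert complete_likelihood(states, obs, spec) == pytest.approx(expected, abs=1e-12)

    def test_run_longer_than_M_impossible(self, rng):
        spec = random_spec(rng, J=2, M=2)
        obs = rng.normal(0, 1, 4)
        assert complete_likelihood(np.zeros(4, dtype=int), obs, spec) == -np.inf

    def test_exp_matches_product_form(self, rng):
        from hsmmseg import emission_logdensity

        spec = random_spec(rng, J=3, M=8)
        obs = rng.normal(0, 1, 6)
        states = np.array([2, 2, 0, 0, 0, 1])
        d = spec.sojourn.pmf_matrix()
        D = spec.sojourn.survivor_matrix()
        b = np.exp(emission_logdensity(spec.emission, obs))
        direct = (
            spec.pi[2] * d[2, 1] * spec.A[2, 0] * d[0, 2] * spec.A[0, 1] * D[1, 0]
            * b[0, 2] * b[1, 2] * b[2, 0] * b[3, 0] * b[4, 0] * b[5, 1]
        )
        assert np.exp(complete_likelihood(states, obs, spec)) == pytest.approx(
            direct, rel=1e-12
        )


class TestForwardBackward:
    def test_single_position_censored(self, rng):
        from hsmmseg import emission_logdensity

        spec = random_spec(rng, J=3, M=5)
        obs = rng.normal(0, 1, 1)
        b = np.exp(emission_logdensity(spec.emission, obs))[0]
        expected = np.log(np.dot(spec.pi, b))  # survivor D_j(1) = 1
        assert forward_backward(obs, spec).loglik == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("family", ["gamma", "nonparametric", "poisson"])
    def test_matches_exhaustive_enumeration(self, family, rng):
        spec = random_spec(rng, J=2, M=6, sojourn_family=family)
        obs = rng.normal(0, 1.5, 6)
        brute, _ = enumerate_loglik(obs, spec)
        assert forward_backward(obs, spec).loglik == pytest.approx(brute, abs=1e-8)

    def test_gamma_rows_sum_to_one(self, rng):
        spec = random_spec(rng, J=3, M=40)
        obs = rng.normal(0, 2, 300)
        post = forward_backward(obs, spec)
        assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_gamma_invariant_under_emission_rescaling(self, rng):
        """Multiplying all state densities at a position by a constant must
        leave the posterior unchanged (checked at the kernel level, where the
        rescaling is an additive shift of the cumulative log-densities)."""
        from hsmmseg import _kernels
        from hsmmseg.engine import _prepare

        spec = random_spec(rng, J=3, M=20)
        obs = rng.normal(0, 2, 60)
        _, cum, logd, logD, logA, logpi, umax = _prepare(obs, spec)
        shift = np.cumsum(rng.normal(0, 0.5, cum.shape[0] - 1))
        cum2 = cum.copy()
        cum2[1:] += shift[:, None]
        outs = []
        for c in (cum, cum2):
            ll, logF, logG = _kernels.forward_pass(c, logd, logD, logA, logpi, umax)
            logE, logB = _kernels.backward_pass(c, logd, logD, logA, umax)
            gamma, *_ = _kernels.posterior_pass(
                c, logd, logD, logA, logpi, umax, logF, logG, logE, logB, ll
            )
            outs.append(gamma)
        assert np.allclose(outs[0], outs[1], atol=1e-9)

    def test_underflow_reported_with_position(self):
        em = EmissionModel("pois", 1, [{"rate": 0.0}, {"rate": 0.0}])
        soj = flat_sojourn("nonparametric", 2, 4)
        spec = HSMMSpec(2, np.array([0.5, 0.5]), uniform_offdiag(2), em, soj, 4)
        with pytest.raises(FloatingPointError, match="position index 2"):
            forward_backward(np.array([0, 0, 5, 0]), spec)


class TestViterbi:
    @pytest.mark.parametrize("trial", range(4))
    def test_attains_exhaustive_maximum(self, trial, rng):
        J = 2 + trial % 2
        spec = random_spec(rng, J=J, M=6, sojourn_family=["gamma", "nbinom"][trial % 2])
        obs = rng.normal(0, 1.5, 6)
        _, best = enumerate_loglik(obs, spec)
        states, score = viterbi(obs, spec)
        assert score == pytest.approx(best, abs=1e-8)
        assert complete_likelihood(states, obs, spec) == pytest.approx(score, abs=1e-8)

    def test_dominant_emissions_recover_truth(self, rng):
        em = EmissionModel(
            "norm", 1, [{"mean": 0.0, "sd": 1.0}, {"mean": 20.0, "sd": 1.0}]
        )
        soj = SojournModel("gamma", 100, [{"shape": 2.0, "scale": 5.0}] * 2)
        spec = HSMMSpec(2, np.array([0.5, 0.5]), uniform_offdiag(2), em, soj, 100)
        truth = np.repeat([0, 1, 0, 1], [12, 9, 15, 8])
        obs = np.where(truth == 1, 20.0, 0.0) + rng.normal(0, 1, truth.size)
        states, _ = viterbi(obs, spec)
        assert np.array_equal(states, truth)

    def test_single_state_constant(self, rng):
        spec = random_spec(rng, J=1, M=30)
        obs = rng.normal(0, 1, 20)
        states, _ = viterbi(obs, spec)
        assert np.all(states == 0)

    def test_score_bounded_by_forward_loglik(self, rng):
        for _ in range(5):
            spec = random_spec(rng, J=3, M=15)
            obs = rng.normal(0, 2, 40)
            _, score = viterbi(obs, spec)
            assert score <= forward_backward(obs, spec).loglik + 1e-10


class TestDecodeSmoothed:
    def _post(self, gamma):
        g = np.asarray(gamma, dtype=float)
        return PosteriorProfile(g, 0.0, np.zeros((g.shape[1], 1)),
                                np.zeros((g.shape[1], 1)),
                                np.zeros((g.shape[1],) * 2), np.zeros(g.shape[1]))

    def test_argmax(self):
        assert decode_smoothed(self._post([[0.2, 0.5, 0.3]]))[0] == 1

    def test_tie_goes_to_lower_state(self):
        assert decode_smoothed(self._post([[0.5, 0.5]]))[0] == 0

    def test_agrees_with_viterbi_on_easy_instances(self, rng):
        em = EmissionModel(
            "norm", 1, [{"mean": m, "sd": 0.3} for m in (-4.0, 0.0, 4.0)]
        )
        soj = SojournModel("gamma", 200, [{"shape": 4.0, "scale": 5.0}] * 3)
        spec = HSMMSpec(3, np.full(3, 1 / 3), uniform_offdiag(3), em, soj, 200)
        truth = np.repeat([0, 1, 2, 1, 0, 2], 25)
        obs = np.array([-4.0, 0.0, 4.0])[truth] + rng.normal(0, 0.3, truth.size)
        v, _ = viterbi(obs, spec)
        s = decode_smoothed(forward_backward(obs, spec))
        assert (v == s).mean() >= 0.99


class TestEM:
    def test_monotone_trace_on_random_instances(self, rng):
        """EM log-likelihood never decreases (generalized-EM guard)."""
        for trial in range(15):
            fam = ["gamma", "poisson", "nbinom", "nonparametric"][trial % 4]
            spec = random_spec(rng, J=2, M=20, sojourn_family=fam)
            obs = rng.normal(0, 2, 60)
            res = em_fit(obs, spec, EMConfig(max_iter=15, tol=1e-9))
            tr = np.array(res.loglik_trace)
            assert np.all(np.diff(tr) >= -1e-6), (trial, fam)

    def test_parameter_recovery(self, rng):
        """3-state normal model with gamma sojourns is recovered from T=2000."""
        means = np.array([-2.0, 0.0, 2.0])
        state, vals = 1, []
        states = []
        while len(vals) < 2000:
            u = max(1, rng.poisson(20))
            vals.extend(rng.normal(means[state], 0.3, u))
            states.extend([state] * u)
            state = (state + rng.integers(1, 3)) % 3
        obs = np.array(vals[:2000])
        M = 1000
        spec0 = HSMMSpec(
            3, np.full(3, 1 / 3), uniform_offdiag(3),
            init_emission_quantile(obs, 3, "norm"), flat_sojourn("gamma", 3, M), M,
        )
        res = em_fit(obs, spec0)
        fitted = np.array([p["mean"] for p in res.spec.emission.params])
        assert np.allclose(fitted, means, atol=0.1)

    def test_stationary_point_converges_immediately(self, rng):
        spec = random_spec(rng, J=2, M=30)
        obs = rng.normal(0, 2, 150)
        first = em_fit(obs, spec, EMConfig(max_iter=60, tol=1e-8))
        again = em_fit(obs, first.spec, EMConfig(max_iter=60, tol=1e-8))
        assert len(again.loglik_trace) <= 2

    def test_invalid_config_rejected(self, rng):
        spec = random_spec(rng, J=2, M=10)
        with pytest.raises(ValueError):
            em_fit(np.zeros(5), spec, EMConfig(max_iter=0))

    def test_recovery_bias_shrinks_with_T(self, rng):
        biases = []
        for T in (500, 2000):
            means = np.array([-3.0, 0.0, 3.0])
            state, vals = 0, []
            while len(vals) < T:
                u = max(1, rng.poisson(15))
                vals.extend(rng.normal(means[state], 0.5, u))
                state = (state + rng.integers(1, 3)) % 3
            obs = np.array(vals[:T])
            M = min(T, 1000)
            spec0 = HSMMSpec(
                3, np.full(3, 1 / 3), uniform_offdiag(3),
                init_emission_quantile(obs, 3, "norm"), flat_sojourn("gamma", 3, M), M,
            )
            res = em_fit(obs, spec0)
            fitted = np.array([p["mean"] for p in res.spec.emission.params])
            biases.append(np.abs(fitted - means).mean())
        assert biases[1] <= biases[0] + 0.05


class TestSpecValidation:
    def test_nonzero_diagonal_rejected(self, rng):
        spec = random_spec(rng, J=2, M=5)
        A = np.array([[0.5, 0.5], [1.0, 0.0]])
        with pytest.raises(ValueError):
            HSMMSpec(2, spec.pi, A, spec.emission, spec.sojourn, 5)

    def test_pi_must_normalize(self, rng):
        spec = random_spec(rng, J=2, M=5)
        with pytest.raises(ValueError):
            HSMMSpec(2, np.array([0.7, 0.6]), spec.A, spec.emission, spec.sojourn, 5)
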