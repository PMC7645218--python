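"""Hidden-Markov state classification: oracles and parameter recovery.

Brute-force path enumeration and hmmlearn serve as independent references
for the likelihood, posteriors, and Viterbi paths.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from lipidphase import (
    HmmModel,
    PerLipidOrderSeries,
    ValidationError,
    bic,
    gen_markov_order_series,
    hmm_decode,
    hmm_fit,
    state_fractions,
)
from lipidphase.hmm import log_likelihood


@pytest.fixture(scope="module")
def toy_model():
    return HmmModel(
        n_states=3,
        initial_probs=np.array([0.5, 0.3, 0.2]),
        transition_matrix=np.array(
            [[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.25, 0.7]]
        ),
        emission_means=np.array([0.1, 0.3, 0.5]),
        emission_sds=np.array([0.05, 0.08, 0.06]),
    )


def brute_force_loglik(x_row, model):
    """Sum over every state path (exact, exponential cost)."""
    k = model.n_states
    total = 0.0
    for path in itertools.product(range(k), repeat=len(x_row)):
        p = model.initial_probs[path[0]] * norm.pdf(
            x_row[0], model.emission_means[path[0]], model.emission_sds[path[0]]
        )
        for t in range(1, len(x_row)):
            p *= model.transition_matrix[path[t - 1], path[t]] * norm.pdf(
                x_row[t], model.emission_means[path[t]], model.emission_sds[path[t]]
            )
        total += p
    return np.log(total)


def path_logprob(x_row, path, model):
    lp = np.log(model.initial_probs[path[0]]) + norm.logpdf(
        x_row[0], model.emission_means[path[0]], model.emission_sds[path[0]]
    )
    for t in range(1, len(x_row)):
        lp += np.log(model.transition_matrix[path[t - 1], path[t]]) + norm.logpdf(
            x_row[t], model.emission_means[path[t]], model.emission_sds[path[t]]
        )
    return lp


class TestOracles:
    def test_forward_likelihood_matches_enumeration(self, toy_model, rng):
        x = rng.uniform(0.0, 0.6, size=(2, 8))
        series = PerLipidOrderSeries(np.arange(2), np.arange(8), x)
        brute = sum(brute_force_loglik(row, toy_model) for row in x)
        assert log_likelihood(series, toy_model) == pytest.approx(brute, abs=1e-10)

    def test_viterbi_is_exhaustive_maximum(self, toy_model, rng):
        t_len = 10
        x = rng.uniform(0.0, 0.6, size=(1, t_len))
        series = PerLipidOrderSeries(np.arange(1), np.arange(t_len), x)
        decoded = tuple(hmm_decode(series, toy_model).state_labels[0])
        best = max(
            itertools.product(range(3), repeat=t_len),
            key=lambda p: path_logprob(x[0], p, toy_model),
        )
        assert path_logprob(x[0], decoded, toy_model) == pytest.approx(
            path_logprob(x[0], best, toy_model), abs=1e-10
        )

    def test_viterbi_beats_random_paths(self, toy_model, rng):
        t_len = 40
        x = rng.uniform(0.0, 0.6, size=(1, t_len))
        series = PerLipidOrderSeries(np.arange(1), np.arange(t_len), x)
        decoded = hmm_decode(series, toy_model).state_labels[0]
        lp_decoded = path_logprob(x[0], decoded, toy_model)
        random_paths = rng.integers(0, 3, size=(1000, t_len))
        lp_random = max(path_logprob(x[0], p, toy_model) for p in random_paths)
        assert lp_decoded >= lp_random

    def test_matches_hmmlearn(self, toy_model, rng):
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        x = rng.uniform(0.0, 0.6, size=(3, 20))
        series = PerLipidOrderSeries(np.arange(3), np.arange(20), x)
        ref = hmmlearn_hmm.GaussianHMM(3, covariance_type="diag", min_covar=1e-12)
        ref.startprob_ = toy_model.initial_probs
        ref.transmat_ = toy_model.transition_matrix
        ref.means_ = toy_model.emission_means.reshape(-1, 1)
        ref.covars_ = (toy_model.emission_sds**2).reshape(-1, 1)
        flat = x.reshape(-1, 1)
        lengths = [20, 20, 20]
        assert log_likelihood(series, toy_model) == pytest.approx(
            ref.score(flat, lengths), abs=1e-10
        )
        ours = hmm_decode(series, toy_model)
        np.testing.assert_allclose(
            ours.posterior_probs.reshape(-1, 3),
            ref.predict_proba(flat, lengths),
            atol=1e-10,
        )
        _, ref_path = ref.decode(flat, lengths)
        np.testing.assert_array_equal(ours.state_labels.ravel(), ref_path)


class TestFit:
    def test_single_state_matches_sample_moments(self, rng):
        x = rng.normal(0.3, 0.07, size=(5, 200))
        series = PerLipidOrderSeries(np.arange(5), np.arange(200), x)
        model = hmm_fit(series, n_states=1, seed=0)
        assert model.emission_means[0] == pytest.approx(x.mean(), abs=1e-9)
        assert model.emission_sds[0] == pytest.approx(x.std(), abs=1e-9)

    def test_loglik_history_nondecreasing(self):
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        series, _ = gen_markov_order_series(
            p, np.array([0.15, 0.4]), np.array([0.05, 0.05]), 20, 300, seed=4
        )
        model = hmm_fit(series, n_states=2, seed=1)
        hist = np.array(model.ll_history)
        assert np.all(np.diff(hist) >= -1e-6 * np.maximum(np.abs(hist[:-1]), 1.0))

    def test_lipid_relabeling_invariance(self):
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        series, _ = gen_markov_order_series(
            p, np.array([0.15, 0.4]), np.array([0.05, 0.05]), 30, 200, seed=9
        )
        shuffled = PerLipidOrderSeries(
            series.lipid_ids, series.times, series.order_values[::-1].copy()
        )
        a = hmm_fit(series, n_states=2, seed=3)
        b = hmm_fit(shuffled, n_states=2, seed=3)
        np.testing.assert_allclose(a.emission_means, b.emission_means, atol=1e-7)
        np.testing.assert_allclose(
            a.transition_matrix, b.transition_matrix, atol=1e-7
        )

    def test_degenerate_data_rejected(self):
        series = PerLipidOrderSeries(
            np.arange(2), np.arange(50), np.full((2, 50), 0.3)
        )
        with pytest.raises(ValidationError):
            hmm_fit(series, n_states=2, seed=0)
        with pytest.raises(ValidationError):
            hmm_fit(series, n_states=0, seed=0)

    def test_bic_prefers_true_state_count(self):
        p = np.array([[0.95, 0.05], [0.05, 0.95]])
        series, _ = gen_markov_order_series(
            p, np.array([0.15, 0.45]), np.array([0.04, 0.04]), 30, 400, seed=2
        )
        m1 = hmm_fit(series, n_states=1, seed=0)
        m2 = hmm_fit(series, n_states=2, seed=0)
        assert bic(series, m2) < bic(series, m1)


class TestDecodeAndSummaries:
    def test_uniform_single_state_model_gives_constant_labels(self, rng):
        model = HmmModel(
            1, np.array([1.0]), np.array([[1.0]]), np.array([0.3]), np.array([0.05])
        )
        x = rng.normal(0.3, 0.05, size=(3, 40))
        series = PerLipidOrderSeries(np.arange(3), np.arange(40), x)
        path = hmm_decode(series, model)
        assert np.all(path.state_labels == 0)
        np.testing.assert_allclose(path.posterior_probs.sum(axis=-1), 1.0, atol=1e-9)

    def test_all_in_one_state_fractions(self):
        from lipidphase.hmm import StatePath

        labels = np.full((4, 25), 2)
        post = np.zeros((4, 25, 3))
        post[:, :, 2] = 1.0
        path = StatePath(np.arange(4), np.arange(25), labels, post, 3)
        table = state_fractions(path)
        np.testing.assert_allclose(table["fraction"], [0.0, 0.0, 1.0])

    def test_dwell_time_of_symmetric_two_state_chain(self):
        p = np.array([[0.9, 0.1], [0.1, 0.9]])
        series, paths = gen_markov_order_series(
            p, np.array([0.1, 0.5]), np.array([0.01, 0.01]), 100, 2000, seed=11
        )
        model = hmm_fit(series, n_states=2, seed=0)
        table = state_fractions(hmm_decode(series, model))
        # geometric dwell with switch probability 0.1 -> mean 10 frames
        for dwell in table["mean_dwell_frames"]:
            assert dwell == pytest.approx(10.0, rel=0.05)

    def test_empty_path_rejected(self):
        from lipidphase.hmm import StatePath

        with pytest.raises(ValidationError):
            state_fractions(
                StatePath(
                    np.arange(0),
                    np.arange(0),
                    np.zeros((0, 0), dtype=int),
                    np.zeros((0, 0, 3)),
                    3,
                )
            )
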