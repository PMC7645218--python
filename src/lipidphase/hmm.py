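"""Gaussian-HMM classification of per-lipid order time series.

Lipids in a phase-separated bilayer visit ordered, intermediate, and
disordered packing states; the per-lipid chain-order observable switches
between state-specific levels with Markovian dwell statistics.  A hidden
Markov model with one Gaussian emission per state is fitted to the pooled
per-lipid series (all lipids share one model), states are relabelled by
ascending emission mean (disordered -> intermediate -> ordered), and the
most probable state path per lipid is decoded by the Viterbi algorithm
alongside forward-backward posteriors.

The implementation is a scaled Baum-Welch / Viterbi / forward-backward
stack vectorized across lipids: all per-lipid series share one length, so
every recursion step updates an (n_lipids, n_states) block at once.  This
keeps EM on hundreds of lipids times thousands of frames in the
seconds range.  Emission means are initialized by k-means++ with a given
seed and the best of several restarts (by final log-likelihood) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .md_order import PerLipidOrderSeries

__all__ = [
    "HmmModel",
    "StatePath",
    "hmm_fit",
    "hmm_decode",
    "state_fractions",
    "log_likelihood",
    "bic",
]

STATE_NAMES_3 = ("disordered", "intermediate", "ordered")
_TINY = 1e-300


@dataclass
class HmmModel:
    """A fitted (or constructed) Gaussian HMM, states sorted by mean."""

    n_states: int
    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    emission_means: np.ndarray
    emission_sds: np.ndarray
    log_likelihood: float = np.nan
    ll_history: tuple[float, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.emission_means = np.asarray(self.emission_means, dtype=float).ravel()
        self.emission_sds = np.asarray(self.emission_sds, dtype=float).ravel()
        k = self.n_states
        if k < 1:
            raise ValidationError("n_states must be >= 1")
        if self.initial_probs.shape != (k,) or self.transition_matrix.shape != (k, k):
            raise ValidationError("initial/transition shapes inconsistent with n_states")
        if np.any(np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("transition matrix rows must sum to 1 within 1e-9")
        if abs(self.initial_probs.sum() - 1.0) > 1e-9:
            raise ValidationError("initial probabilities must sum to 1")
        if np.any(self.emission_sds <= 0):
            raise ValidationError("emission sds must be positive")
        if np.any(np.diff(self.emission_means) < 0):
            raise ValidationError("states must be sorted by ascending emission mean")

    @property
    def state_names(self) -> tuple[str, ...]:
        if self.n_states == 3:
            return STATE_NAMES_3
        return tuple(f"state_{i}" for i in range(self.n_states))


@dataclass
class StatePath:
    """Viterbi state labels and forward-backward posteriors per lipid."""

    lipid_ids: np.ndarray
    times: np.ndarray
    state_labels: np.ndarray
    posterior_probs: np.ndarray
    n_states: int

    def __post_init__(self) -> None:
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=int)
        self.times = np.asarray(self.times)
        self.state_labels = np.asarray(self.state_labels, dtype=int)
        self.posterior_probs = np.asarray(self.posterior_probs, dtype=float)
        shape = (self.lipid_ids.size, self.times.size)
        if self.state_labels.shape != shape:
            raise ValidationError("state_labels must be (n_lipids, n_times)")
        if self.posterior_probs.shape != shape + (self.n_states,):
            raise ValidationError(
                "posterior_probs must be (n_lipids, n_times, n_states)"
            )
        if self.state_labels.size:
            if self.state_labels.min() < 0 or self.state_labels.max() >= self.n_states:
                raise ValidationError("state labels out of range")
            sums = self.posterior_probs.sum(axis=-1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValidationError("posteriors must sum to 1 within 1e-9")


# ---------------------------------------------------------------------------
# core recursions (vectorized across lipids)
# ---------------------------------------------------------------------------

def _emission_probs(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Gaussian pdf values, shape (L, T, K)."""
    z = (x[..., None] - means[None, None, :]) / sds[None, None, :]
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sds[None, None, :])


def _forward(b, startprob, transmat):
    """Scaled forward pass.  Returns (alpha, scales, total loglik)."""
    L, T, K = b.shape
    alpha = np.empty((L, T, K))
    scales = np.empty((L, T))
    a = startprob[None, :] * b[:, 0, :]
    scales[:, 0] = a.sum(axis=1) + _TINY
    alpha[:, 0, :] = a / scales[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ transmat) * b[:, t, :]
        scales[:, t] = a.sum(axis=1) + _TINY
        alpha[:, t, :] = a / scales[:, t, None]
    return alpha, scales, float(np.log(scales).sum())


def _backward(b, transmat, scales):
    L, T, K = b.shape
    beta = np.empty((L, T, K))
    beta[:, -1, :] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t, :] = (beta[:, t + 1, :] * b[:, t + 1, :]) @ transmat.T
        beta[:, t, :] /= scales[:, t + 1, None]
    return beta


def _posteriors(b, startprob, transmat):
    alpha, scales, ll = _forward(b, startprob, transmat)
    beta = _backward(b, transmat, scales)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return alpha, beta, gamma, scales, ll


def log_likelihood(series: PerLipidOrderSeries, model: HmmModel) -> float:
    """Pooled forward-algorithm log-likelihood of the series under model."""
    x = np.asarray(series.order_values, dtype=float)
    b = _emission_probs(x, model.emission_means, model.emission_sds)
    _, _, ll = _forward(b, model.initial_probs, model.transition_matrix)
    return ll


def _kmeans_init(x_flat: np.ndarray, k: int, rng: np.random.Generator):
    """k-means++ seeding plus a few Lloyd iterations on the pooled scalars."""
    # sorting makes the fit invariant to the labelling order of lipids
    sample = np.sort(x_flat)
    if sample.size > 20000:
        sample = rng.choice(sample, size=20000, replace=False)
    centers = [float(rng.choice(sample))]
    for _ in range(1, k):
        d2 = np.min((sample[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(float(rng.choice(sample)))
            continue
        centers.append(float(rng.choice(sample, p=d2 / total)))
    centers = np.sort(np.asarray(centers))
    for _ in range(15):
        assign = np.argmin(np.abs(sample[:, None] - centers[None, :]), axis=1)
        for j in range(k):
            sel = sample[assign == j]
            if sel.size:
                centers[j] = sel.mean()
        centers = np.sort(centers)
    assign = np.argmin(np.abs(sample[:, None] - centers[None, :]), axis=1)
    sds = np.empty(k)
    overall = max(sample.std(), 1e-3)
    for j in range(k):
        sel = sample[assign == j]
        sds[j] = sel.std() if sel.size > 1 and sel.std() > 0 else overall
    return centers, sds


def hmm_fit(
    series: PerLipidOrderSeries,
    n_states: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> HmmModel:
    """Fit a pooled Gaussian HMM by Baum-Welch EM, best of ``n_restarts``.

    Each restart initializes emission means by seeded k-means++; EM runs
    until the relative log-likelihood improvement falls below ``tol`` or
    ``max_iter`` iterations.  The restart with the highest final pooled
    log-likelihood wins; states are sorted by ascending emission mean.
    """
    if n_states < 1:
        raise ValidationError("n_states must be >= 1")
    x = np.asarray(series.order_values, dtype=float)
    if x.size <= 10 * n_states:
        raise ValidationError("need more than 10 observations per state")
    if np.std(x) == 0:
        raise ValidationError("degenerate (zero-variance) observations")
    rng = np.random.default_rng(seed)
    best: tuple[float, dict, list[float]] | None = None
    for _ in range(max(1, n_restarts)):
        sub = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        means, sds = _kmeans_init(x.ravel(), n_states, sub)
        # persistent-chain initialization: lipid states switch rarely
        transmat = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
        np.fill_diagonal(transmat, 0.9 if n_states > 1 else 1.0)
        startprob = np.full(n_states, 1.0 / n_states)
        params = {
            "means": means, "sds": sds,
            "transmat": transmat, "startprob": startprob,
        }
        history: list[float] = []
        prev = -np.inf
        for _it in range(max_iter):
            params, ll = _em_step(x, params)
            history.append(ll)
            if ll - prev < tol * (1.0 + abs(ll)) and _it > 0:
                break
            prev = ll
        if best is None or history[-1] > best[0]:
            best = (history[-1], params, history)
    ll, params, history = best
    order = np.argsort(params["means"], kind="stable")
    return HmmModel(
        n_states=n_states,
        initial_probs=params["startprob"][order],
        transition_matrix=params["transmat"][np.ix_(order, order)],
        emission_means=params["means"][order],
        emission_sds=params["sds"][order],
        log_likelihood=ll,
        ll_history=tuple(history),
        seed=seed,
    )


def _em_step(x: np.ndarray, params: dict) -> tuple[dict, float]:
    """One Baum-Welch iteration; returns new parameters and the
    log-likelihood of the *current* parameters."""
    means, sds = params["means"], params["sds"]
    transmat, startprob = params["transmat"], params["startprob"]
    b = _emission_probs(x, means, sds)
    alpha, beta, gamma, scales, ll = _posteriors(b, startprob, transmat)
    L, T, K = b.shape
    # transition statistics: xi[t] ~ alpha[t] . a_kj . b[t+1] beta[t+1]/c[t+1]
    bb = beta[:, 1:, :] * b[:, 1:, :] / scales[:, 1:, None]
    xi_sum = np.einsum("ltk,ltj->kj", alpha[:, :-1, :], bb) * transmat
    new_trans = xi_sum / (xi_sum.sum(axis=1, keepdims=True) + _TINY)
    new_start = gamma[:, 0, :].mean(axis=0)
    new_start = new_start / new_start.sum()
    g_sum = gamma.sum(axis=(0, 1)) + _TINY
    new_means = np.einsum("ltk,lt->k", gamma, x) / g_sum
    var = np.einsum("ltk,ltk->k", gamma, (x[..., None] - new_means) ** 2) / g_sum
    new_sds = np.sqrt(np.maximum(var, 1e-12))
    return (
        {
            "means": new_means, "sds": new_sds,
            "transmat": new_trans, "startprob": new_start,
        },
        ll,
    )


def hmm_decode(series: PerLipidOrderSeries, model: HmmModel) -> StatePath:
    """Viterbi most-probable path per lipid plus forward-backward
    posteriors; deterministic."""
    x = np.asarray(series.order_values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("observations must be finite")
    logb = _log_emission(x, model.emission_means, model.emission_sds)
    labels = _viterbi(logb, model.initial_probs, model.transition_matrix)
    b = _emission_probs(x, model.emission_means, model.emission_sds)
    _, _, gamma, _, _ = _posteriors(b, model.initial_probs, model.transition_matrix)
    return StatePath(
        lipid_ids=series.lipid_ids,
        times=series.times,
        state_labels=labels,
        posterior_probs=gamma,
        n_states=model.n_states,
    )


def _log_emission(x, means, sds):
    z = (x[..., None] - means[None, None, :]) / sds[None, None, :]
    return -0.5 * z * z - np.log(np.sqrt(2.0 * np.pi) * sds)[None, None, :]


def _viterbi(logb: np.ndarray, startprob: np.ndarray, transmat: np.ndarray):
    L, T, K = logb.shape
    with np.errstate(divide="ignore"):
        log_a = np.log(transmat + _TINY)
        log_pi = np.log(startprob + _TINY)
    delta = log_pi[None, :] + logb[:, 0, :]
    psi = np.empty((L, T, K), dtype=np.int32)
    for t in range(1, T):
        cand = delta[:, :, None] + log_a[None, :, :]
        psi[:, t, :] = np.argmax(cand, axis=1)
        delta = np.take_along_axis(cand, psi[:, t, :][:, None, :], axis=1)[:, 0, :] \
            + logb[:, t, :]
    labels = np.empty((L, T), dtype=int)
    labels[:, -1] = np.argmax(delta, axis=1)
    for t in range(T - 1, 0, -1):
        labels[:, t - 1] = np.take_along_axis(
            psi[:, t, :], labels[:, t][:, None], axis=1
        )[:, 0]
    return labels


def _dwell_lengths(labels_1d: np.ndarray, state: int) -> list[int]:
    runs = []
    count = 0
    for lab in labels_1d:
        if lab == state:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def state_fractions(path: StatePath) -> pd.DataFrame:
    """Occupancy fraction and mean dwell time (frames) per state."""
    if path.state_labels.size == 0:
        raise ValidationError("empty state path")
    total = path.state_labels.size
    rows = []
    for k in range(path.n_states):
        frac = float(np.count_nonzero(path.state_labels == k)) / total
        dwells: list[int] = []
        for lipid_labels in path.state_labels:
            dwells.extend(_dwell_lengths(lipid_labels, k))
        rows.append(
            {
                "state": k,
                "name": (
                    STATE_NAMES_3[k] if path.n_states == 3 else f"state_{k}"
                ),
                "fraction": frac,
                "mean_dwell_frames": float(np.mean(dwells)) if dwells else np.nan,
                "n_visits": len(dwells),
            }
        )
    return pd.DataFrame(rows)


def bic(series: PerLipidOrderSeries, model: HmmModel) -> float:
    """Bayesian information criterion of a fitted model on a series.

    Parameter count: (k-1) initial + k(k-1) transition + 2k emission.
    Provided for model-order comparison; three states is the default
    elsewhere, not chosen by BIC.
    """
    k = model.n_states
    n_params = (k - 1) + k * (k - 1) + 2 * k
    n = series.order_values.size
    ll = log_likelihood(series, model)
    return -2.0 * ll + n_params * np.log(n)
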