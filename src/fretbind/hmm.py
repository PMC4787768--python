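"""2-state Gaussian-emission hidden Markov model for trace idealization.

Each FRET trajectory is idealized with a hidden Markov model whose states
carry Gaussian emissions: one state at ~0 FRET (no polymerase bound) and one
at the bound-complex FRET.  Separating these two lets the 0-FRET peak be
eliminated from bound-state histograms and gives the dwell epochs for
kinetics.  Conformational sub-states *within* the bound manifold are
deliberately not HMM states — they are resolved downstream by Gaussian
decomposition of the bound-state histogram.

Fitting is maximum-likelihood Baum-Welch (EM with scaled forward-backward,
log-domain emission handling so zero-probability observations cannot
underflow); decoding is exact Viterbi with deterministic tie-breaking toward
the lower-mean state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 0.01  # FRET units; prevents emission collapse on constant data

__all__ = [
    "HmmModel",
    "StatePath",
    "BoundClassification",
    "InsufficientDataError",
    "fit_hmm",
    "viterbi",
    "loglikelihood",
    "classify_bound",
    "merge_short_events",
]


class InsufficientDataError(ValueError):
    """Too few observations to fit the requested model."""


@dataclass(frozen=True)
class HmmModel:
    """Gaussian-emission HMM parameters, states ordered by ascending mean."""

    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    emission_mean: np.ndarray
    emission_sd: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.initial_probs, dtype=float)
        t = np.asarray(self.transition_matrix, dtype=float)
        mu = np.asarray(self.emission_mean, dtype=float)
        sd = np.asarray(self.emission_sd, dtype=float)
        for name, arr in (("initial_probs", pi), ("transition_matrix", t),
                          ("emission_mean", mu), ("emission_sd", sd)):
            object.__setattr__(self, name, arr)
        k = len(mu)
        if pi.shape != (k,) or t.shape != (k, k) or sd.shape != (k,):
            raise ValueError("inconsistent parameter shapes")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(sd < SIGMA_FLOOR):
            raise ValueError(f"emission sd below floor {SIGMA_FLOOR}")
        if np.any(np.diff(mu) < 0):
            raise ValueError("states must be ordered by ascending emission mean")

    @property
    def n_states(self) -> int:
        return len(self.emission_mean)


@dataclass(frozen=True)
class StatePath:
    """Most-likely state labels over the valid frames of one trajectory."""

    states: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class BoundClassification:
    """Mapping of HMM states to unbound/bound, with degenerate-trace flags."""

    state_class: tuple[str, ...]  # per state: "unbound" or "bound"
    flag: str  # "normal" | "always_bound" | "always_unbound"

    @property
    def bound_states(self) -> list[int]:
        return [i for i, c in enumerate(self.state_class) if c == "bound"]


# ---------------------------------------------------------------------------
# Numerical kernels (numba-jitted when available)
# ---------------------------------------------------------------------------

def _identity_jit(func=None, **kwargs):
    return func if func is not None else (lambda f: f)


try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True, fastmath=False)(func)
except ImportError:  # pragma: no cover
    _jit = _identity_jit


def _forward_backward_impl(logb, pi, trans):
    """Scaled forward-backward with per-frame log-emission shifting.

    Returns (gamma, xi_sum, loglik): state posteriors per frame, summed
    transition posteriors, and the total log-likelihood.
    """
    n, k = logb.shape
    gamma = np.empty((n, k))
    alpha = np.empty((n, k))
    beta = np.empty((n, k))
    c = np.empty(n)
    shift = np.empty(n)
    b = np.empty((n, k))
    for t in range(n):
        m = logb[t, 0]
        for j in range(1, k):
            if logb[t, j] > m:
                m = logb[t, j]
        shift[t] = m
        for j in range(k):
            b[t, j] = np.exp(logb[t, j] - m)
    # forward
    s = 0.0
    for j in range(k):
        alpha[0, j] = pi[j] * b[0, j]
        s += alpha[0, j]
    c[0] = s
    for j in range(k):
        alpha[0, j] /= s
    for t in range(1, n):
        s = 0.0
        for j in range(k):
            a = 0.0
            for i in range(k):
                a += alpha[t - 1, i] * trans[i, j]
            alpha[t, j] = a * b[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(k):
            alpha[t, j] /= s
    # backward
    for j in range(k):
        beta[n - 1, j] = 1.0
    for t in range(n - 2, -1, -1):
        for i in range(k):
            a = 0.0
            for j in range(k):
                a += trans[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = a / c[t + 1]
    # posteriors
    for t in range(n):
        s = 0.0
        for j in range(k):
            gamma[t, j] = alpha[t, j] * beta[t, j]
            s += gamma[t, j]
        for j in range(k):
            gamma[t, j] /= s
    xi_sum = np.zeros((k, k))
    for t in range(n - 1):
        for i in range(k):
            for j in range(k):
                xi_sum[i, j] += (alpha[t, i] * trans[i, j] * b[t + 1, j]
                                 * beta[t + 1, j] / c[t + 1])
    loglik = 0.0
    for t in range(n):
        loglik += np.log(c[t]) + shift[t]
    return gamma, xi_sum, loglik


def _viterbi_impl(logb, logpi, logtrans):
    """Exact MAP path; ties broken toward the lower state index."""
    n, k = logb.shape
    delta = np.empty((n, k))
    psi = np.zeros((n, k), dtype=np.int64)
    for j in range(k):
        delta[0, j] = logpi[j] + logb[0, j]
    for t in range(1, n):
        for j in range(k):
            best_i = 0
            best = delta[t - 1, 0] + logtrans[0, j]
            for i in range(1, k):
                v = delta[t - 1, i] + logtrans[i, j]
                if v > best:  # strict: ties keep the lower index
                    best = v
                    best_i = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = best_i
    states = np.empty(n, dtype=np.int64)
    best_j = 0
    best = delta[n - 1, 0]
    for j in range(1, k):
        if delta[n - 1, j] > best:
            best = delta[n - 1, j]
            best_j = j
    states[n - 1] = best_j
    for t in range(n - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states, best


_forward_backward = _jit(_forward_backward_impl)
_viterbi_kernel = _jit(_viterbi_impl)


def _log_emissions(obs: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (obs[:, None] - mu[None, :]) / sd[None, :]
    return -0.5 * z**2 - np.log(sd[None, :]) - 0.5 * np.log(2.0 * np.pi)


def _as_sequences(observations) -> list[np.ndarray]:
    if isinstance(observations, (list, tuple)):
        seqs = [np.asarray(o, dtype=float).ravel() for o in observations]
    else:
        seqs = [np.asarray(observations, dtype=float).ravel()]
    seqs = [s for s in seqs if s.size]
    for s in seqs:
        if not np.all(np.isfinite(s)):
            raise ValueError("observations must be finite")
    return seqs


def default_init(obs: np.ndarray, n_states: int = 2) -> HmmModel:
    """Default initialization: state means at the 10th and 90th percentiles
    (evenly spaced percentiles for >2 states), sd 0.1, uniform pi, 0.95
    self-transition."""
    qs = np.linspace(10, 90, n_states)
    mu = np.percentile(obs, qs).astype(float)
    mu = np.sort(mu)
    # break exact ties so EM can differentiate states on degenerate input
    for i in range(1, n_states):
        if mu[i] - mu[i - 1] < 1e-12:
            mu[i] = mu[i - 1] + 1e-6
    sd = np.full(n_states, 0.1)
    pi = np.full(n_states, 1.0 / n_states)
    trans = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
    np.fill_diagonal(trans, 0.95)
    return HmmModel(pi, trans, mu, sd)


def fit_hmm(
    observations,
    n_states: int = 2,
    init: HmmModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[HmmModel, list[float]]:
    """Baum-Welch maximum-likelihood fit.

    ``observations`` may be one 1-D array (per-molecule fit, the default
    analysis mode) or a list of arrays (pooled-emission fit across
    molecules, for traces too short to fit alone).  Iterates until the
    relative log-likelihood change drops below ``tol`` or ``max_iter``;
    the log-likelihood is checked to be non-decreasing (EM guarantee).

    Returns the fitted model (states sorted by mean) and the per-iteration
    log-likelihood history.
    """
    seqs = _as_sequences(observations)
    n_total = sum(len(s) for s in seqs)
    if n_total < max(10, 2 * n_states):
        raise InsufficientDataError(
            f"need at least {max(10, 2 * n_states)} observations, got {n_total}")
    pooled = np.concatenate(seqs)

    model = init if init is not None else default_init(pooled, n_states)
    pi = model.initial_probs.copy()
    trans = model.transition_matrix.copy()
    mu = model.emission_mean.copy()
    sd = np.maximum(model.emission_sd.copy(), SIGMA_FLOOR)

    history: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        gamma_sum = np.zeros(n_states)
        gamma_first = np.zeros(n_states)
        xi_sum = np.zeros((n_states, n_states))
        mu_num = np.zeros(n_states)
        var_num = np.zeros(n_states)
        ll = 0.0
        gammas = []
        for s in seqs:
            logb = _log_emissions(s, mu, sd)
            gamma, xi, ll_s = _forward_backward(logb, pi, trans)
            ll += ll_s
            gammas.append(gamma)
            gamma_first += gamma[0]
            gamma_sum += gamma.sum(axis=0)
            xi_sum += xi
            mu_num += gamma.T @ s
        if history and ll < prev_ll - 1e-9 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        history.append(ll)
        if history[:-1] and abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            prev_ll = ll
            break
        prev_ll = ll
        # M-step
        pi = gamma_first / gamma_first.sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        trans = np.where(denom > 0, xi_sum / np.maximum(denom, 1e-300), trans)
        trans /= trans.sum(axis=1, keepdims=True)
        mu = mu_num / np.maximum(gamma_sum, 1e-300)
        for s, gamma in zip(seqs, gammas):
            var_num += (gamma * (s[:, None] - mu[None, :]) ** 2).sum(axis=0)
        sd = np.sqrt(var_num / np.maximum(gamma_sum, 1e-300))
        sd = np.maximum(sd, SIGMA_FLOOR)

    order = np.argsort(mu, kind="stable")
    model = HmmModel(
        initial_probs=pi[order],
        transition_matrix=trans[np.ix_(order, order)],
        emission_mean=mu[order],
        emission_sd=sd[order],
    )
    return model, history


def loglikelihood(model: HmmModel, observations: np.ndarray) -> float:
    """Total log-likelihood of ``observations`` under ``model`` (forward
    algorithm)."""
    obs = np.asarray(observations, dtype=float).ravel()
    if obs.size == 0:
        return 0.0
    logb = _log_emissions(obs, model.emission_mean, model.emission_sd)
    _, _, ll = _forward_backward(logb, model.initial_probs, model.transition_matrix)
    return float(ll)


def viterbi(model: HmmModel, observations: np.ndarray) -> StatePath:
    """Exact maximum a posteriori state path; empty input gives an empty
    path, and ties resolve deterministically toward the lower-mean state."""
    obs = np.asarray(observations, dtype=float).ravel()
    if obs.size == 0:
        return StatePath(states=np.empty(0, dtype=np.int64), log_likelihood=0.0)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations must be finite")
    logb = _log_emissions(obs, model.emission_mean, model.emission_sd)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.initial_probs)
        logtrans = np.log(model.transition_matrix)
    states, logp = _viterbi_kernel(logb, logpi, logtrans)
    return StatePath(states=states, log_likelihood=float(logp))


def classify_bound(model: HmmModel, bound_threshold: float = 0.25) -> BoundClassification:
    """Map HMM states to unbound/bound by emission mean.

    The state with mean closest to 0 is "unbound" provided its mean is below
    ``bound_threshold``; if both means exceed the threshold the molecule was
    bound throughout (both states are conformations); if all means fall
    below it the molecule never bound and should be excluded.
    """
    mu = model.emission_mean
    below = mu < bound_threshold
    if not below.any():
        return BoundClassification(tuple("bound" for _ in mu), "always_bound")
    if below.all():
        logger.warning("all HMM states below bound threshold %.2f: always unbound",
                       bound_threshold)
        return BoundClassification(tuple("unbound" for _ in mu), "always_unbound")
    unbound = int(np.argmin(np.abs(mu)))
    cls = tuple("unbound" if i == unbound else "bound" for i in range(len(mu)))
    return BoundClassification(cls, "normal")


def merge_short_events(states: np.ndarray, min_frames: int = 2) -> np.ndarray:
    """Merge idealized events shorter than ``min_frames`` into a neighbor.

    Suppresses single-frame shot-noise flickers.  Short runs are absorbed
    into the longer adjacent run (the preceding run on ties); repeats until
    stable.
    """
    s = np.asarray(states).copy()
    if s.size == 0 or min_frames <= 1:
        return s
    while True:
        runs = _runs(s)
        if len(runs) <= 1:
            return s
        short = [i for i, (_, lo, hi) in enumerate(runs) if hi - lo < min_frames]
        if not short:
            return s
        # merge the shortest first for determinism
        i = min(short, key=lambda i: (runs[i][2] - runs[i][1], i))
        _, lo, hi = runs[i]
        if i == 0:
            s[lo:hi] = runs[1][0]
        elif i == len(runs) - 1:
            s[lo:hi] = runs[i - 1][0]
        else:
            prev_len = runs[i - 1][2] - runs[i - 1][1]
            next_len = runs[i + 1][2] - runs[i + 1][1]
            s[lo:hi] = runs[i - 1][0] if prev_len >= next_len else runs[i + 1][0]


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (value, start, stop)."""
    s = np.asarray(states)
    if s.size == 0:
        return []
    bounds = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], bounds))
    stops = np.concatenate((bounds, [s.size]))
    return [(int(s[a]), int(a), int(b)) for a, b in zip(starts, stops)]
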