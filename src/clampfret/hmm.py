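"""Gaussian-emission hidden Markov models for E* time traces.

Maximum-likelihood Baum–Welch EM over pooled molecules (all traces share
one parameter set, each trace an independent realization), Viterbi
decoding, and AIC-based selection of the number of FRET states K.  The
converged log-likelihood plays the role of the model-comparison bound.

Numerics: the forward/backward passes run in scaled linear space with a
per-frame max-shift on the log emission densities, so they are stable for
arbitrarily small emission widths; emission sigmas are floored to prevent
variance collapse.  Hot loops are compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "HmmConfig",
    "HmmFit",
    "fit_hmm",
    "forward_loglik",
    "select_model",
    "decode_path",
    "aic_n_params",
]


@dataclass
class HmmConfig:
    """Fitting settings.

    ``prior_center_min``/``prior_center_max`` set the spread of the initial
    state means (0.2–0.4, bracketing the clamp FRET states), ``noise_init``
    the initial emission std, and ``n_restarts`` the number of EM
    initializations (five by default).
    """

    k_range: tuple = (2, 3, 4, 5, 6)
    prior_center_min: float = 0.2
    prior_center_max: float = 0.4
    noise_init: float = 0.05
    n_restarts: int = 5
    restart_iterations: int = 10  # short-run EM length for restart screening
    max_em_iterations: int = 200
    tol: float = 0.05  # absolute change in total log-likelihood
    sigma_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.k_range) == 0:
            raise ValueError("k_range must be nonempty")
        if self.noise_init <= 0 or self.tol <= 0 or self.sigma_floor <= 0:
            raise ValueError("noise_init, tol and sigma_floor must be positive")


@dataclass
class HmmFit:
    """One fitted K-state model, states sorted by ascending emission mean."""

    k: int
    means: np.ndarray
    sigmas: np.ndarray
    pi: np.ndarray
    transition_matrix: np.ndarray  # per-frame transition probabilities
    log_likelihood: float
    n_obs: int
    converged: bool = True
    degenerate: bool = False
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def aic(self) -> float:
        return 2.0 * aic_n_params(self.k) - 2.0 * self.log_likelihood


def aic_n_params(k: int) -> int:
    """Free parameters of a K-state Gaussian HMM:
    (K-1) initial probabilities + K(K-1) transition probabilities
    + 2K emission means/sigmas."""
    return (k - 1) + k * (k - 1) + 2 * k


def _pack(sequences):
    seqs = [np.asarray(s, dtype=float).ravel() for s in sequences]
    if any(len(s) == 0 for s in seqs):
        seqs = [s for s in seqs if len(s) > 0]
    if not seqs:
        raise ValueError("no nonempty sequences to fit")
    flat = np.concatenate(seqs)
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(s) for s in seqs])
    if not np.all(np.isfinite(flat)):
        raise ValueError("sequences contain non-finite values")
    return flat, offsets


@njit(cache=False)
def _log_emission(x, means, sigmas):
    k = means.shape[0]
    out = np.empty(k)
    for j in range(k):
        z = (x - means[j]) / sigmas[j]
        out[j] = -0.5 * z * z - np.log(sigmas[j]) - 0.9189385332046727
    return out


@njit(cache=False)
def _forward_one(obs, pi, a, means, sigmas):
    """Scaled forward pass for one sequence; returns log-likelihood."""
    t_len = obs.shape[0]
    k = means.shape[0]
    alpha = np.empty(k)
    loglik = 0.0
    for t in range(t_len):
        logb = _log_emission(obs[t], means, sigmas)
        shift = logb.max()
        b = np.exp(logb - shift)
        if t == 0:
            for j in range(k):
                alpha[j] = pi[j] * b[j]
        else:
            new = np.zeros(k)
            for i in range(k):
                ai = alpha[i]
                for j in range(k):
                    new[j] += ai * a[i, j]
            for j in range(k):
                new[j] *= b[j]
            alpha = new
        c = alpha.sum()
        if c <= 0:
            return -np.inf
        alpha /= c
        loglik += np.log(c) + shift
    return loglik


@njit(cache=False)
def _estep(flat, offsets, pi, a, means, sigmas):
    """One E-step over all sequences; returns loglik and sufficient stats."""
    k = means.shape[0]
    n_seq = offsets.shape[0] - 1
    s0 = np.zeros(k)  # sum of posteriors per state
    s1 = np.zeros(k)  # sum of posterior-weighted observations
    s2 = np.zeros(k)  # ... squared observations
    xi = np.zeros((k, k))
    g0 = np.zeros(k)  # posterior at t=0, summed over sequences
    total_ll = 0.0
    for n in range(n_seq):
        obs = flat[offsets[n]:offsets[n + 1]]
        t_len = obs.shape[0]
        alpha = np.empty((t_len, k))
        shifts = np.empty(t_len)
        cs = np.empty(t_len)
        bmat = np.empty((t_len, k))
        for t in range(t_len):
            logb = _log_emission(obs[t], means, sigmas)
            shift = logb.max()
            shifts[t] = shift
            for j in range(k):
                bmat[t, j] = np.exp(logb[j] - shift)
        # forward
        for j in range(k):
            alpha[0, j] = pi[j] * bmat[0, j]
        c = alpha[0].sum()
        if c <= 0:
            return -np.inf, s0, s1, s2, xi, g0
        alpha[0] /= c
        cs[0] = c
        for t in range(1, t_len):
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    acc += alpha[t - 1, i] * a[i, j]
                alpha[t, j] = acc * bmat[t, j]
            c = alpha[t].sum()
            if c <= 0:
                return -np.inf, s0, s1, s2, xi, g0
            alpha[t] /= c
            cs[t] = c
        for t in range(t_len):
            total_ll += np.log(cs[t]) + shifts[t]
        # backward + accumulation
        beta = np.ones(k)
        gamma_t = alpha[t_len - 1].copy()
        for j in range(k):
            s0[j] += gamma_t[j]
            s1[j] += gamma_t[j] * obs[t_len - 1]
            s2[j] += gamma_t[j] * obs[t_len - 1] * obs[t_len - 1]
        for t in range(t_len - 2, -1, -1):
            bb = np.empty(k)
            for j in range(k):
                bb[j] = bmat[t + 1, j] * beta[j]
            # xi contribution (normalized by the same scale as gamma)
            denom = 0.0
            for i in range(k):
                for j in range(k):
                    denom += alpha[t, i] * a[i, j] * bb[j]
            if denom > 0:
                for i in range(k):
                    for j in range(k):
                        xi[i, j] += alpha[t, i] * a[i, j] * bb[j] / denom
            new_beta = np.empty(k)
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += a[i, j] * bb[j]
                new_beta[i] = acc / cs[t + 1]
            beta = new_beta
            norm = 0.0
            for j in range(k):
                gamma_t[j] = alpha[t, j] * beta[j]
                norm += gamma_t[j]
            if norm > 0:
                for j in range(k):
                    gamma_t[j] /= norm
            for j in range(k):
                s0[j] += gamma_t[j]
                s1[j] += gamma_t[j] * obs[t]
                s2[j] += gamma_t[j] * obs[t] * obs[t]
            if t == 0:
                for j in range(k):
                    g0[j] += gamma_t[j]
    return total_ll, s0, s1, s2, xi, g0


@njit(cache=False)
def _viterbi_one(obs, pi, a, means, sigmas):
    t_len = obs.shape[0]
    k = means.shape[0]
    log_a = np.log(a + 1e-300)
    delta = np.empty(k)
    psi = np.empty((t_len, k), dtype=np.int64)
    logb = _log_emission(obs[0], means, sigmas)
    for j in range(k):
        delta[j] = np.log(pi[j] + 1e-300) + logb[j]
    for t in range(1, t_len):
        logb = _log_emission(obs[t], means, sigmas)
        new = np.empty(k)
        for j in range(k):
            best = -np.inf
            arg = 0
            for i in range(k):
                v = delta[i] + log_a[i, j]
                if v > best:
                    best = v
                    arg = i
            new[j] = best + logb[j]
            psi[t, j] = arg
        delta = new
    path = np.empty(t_len, dtype=np.int64)
    best = -np.inf
    arg = 0
    for j in range(k):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path[t_len - 1] = arg
    for t in range(t_len - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def forward_loglik(sequence, pi, transition_matrix, means, sigmas) -> float:
    """Log-likelihood of one observation sequence under a Gaussian HMM
    (scaled forward algorithm)."""
    obs = np.asarray(sequence, dtype=float).ravel()
    pi = np.asarray(pi, dtype=float)
    a = np.asarray(transition_matrix, dtype=float)
    means = np.asarray(means, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if a.shape != (len(pi), len(pi)) or len(means) != len(pi):
        raise ValueError("inconsistent parameter shapes")
    return float(_forward_one(obs, pi, a, means, sigmas))


def total_loglik(sequences, pi, transition_matrix, means, sigmas) -> float:
    """Sum of forward log-likelihoods over independent sequences."""
    return float(
        sum(forward_loglik(s, pi, transition_matrix, means, sigmas) for s in sequences)
    )


def _init_params(k, config: HmmConfig, rng, restart: int):
    lo, hi = config.prior_center_min, config.prior_center_max
    if k == 1:
        means = np.array([(lo + hi) / 2.0])
    else:
        means = np.linspace(lo, hi, k)
    if restart > 0:
        means = means + rng.normal(0.0, 0.25 * (hi - lo) / max(k - 1, 1), k)
        means.sort()
    sigmas = np.full(k, config.noise_init)
    pi = np.full(k, 1.0 / k)
    a = np.full((k, k), 0.1 / max(k - 1, 1))
    np.fill_diagonal(a, 0.9 if k > 1 else 1.0)
    if restart > 0 and k > 1:
        a = a + rng.uniform(0.0, 0.02, (k, k))
        a /= a.sum(axis=1, keepdims=True)
    return pi, a, means, sigmas


def _em_run(flat, offsets, k, config: HmmConfig, pi, a, means, sigmas,
            max_iterations: int | None = None):
    history = []
    prev_ll = -np.inf
    converged = False
    degenerate = False
    if max_iterations is None:
        max_iterations = config.max_em_iterations
    for _ in range(max_iterations):
        ll, s0, s1, s2, xi, g0 = _estep(flat, offsets, pi, a, means, sigmas)
        if not np.isfinite(ll):
            return None
        history.append(ll)
        if np.any(s0 < 1.0):
            degenerate = True
            break
        # M-step
        pi = g0 / g0.sum()
        if k > 1:
            rows = xi.sum(axis=1, keepdims=True)
            a = np.where(rows > 0, xi / np.where(rows > 0, rows, 1.0), 1.0 / k)
            a /= a.sum(axis=1, keepdims=True)
        means = s1 / s0
        var = s2 / s0 - means**2
        sigmas = np.sqrt(np.clip(var, config.sigma_floor**2, None))
        if ll - prev_ll < config.tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    final_ll = total_loglik_flat(flat, offsets, pi, a, means, sigmas)
    return dict(
        pi=pi, a=a, means=means, sigmas=sigmas, loglik=final_ll,
        history=np.asarray(history), converged=converged, degenerate=degenerate,
    )


def total_loglik_flat(flat, offsets, pi, a, means, sigmas) -> float:
    ll = 0.0
    for n in range(len(offsets) - 1):
        ll += _forward_one(flat[offsets[n]:offsets[n + 1]], pi, a, means, sigmas)
    return float(ll)


def fit_hmm(sequences, k: int, config: HmmConfig | None = None) -> HmmFit:
    """Fit a K-state Gaussian HMM to pooled E* traces by Baum–Welch EM.

    All traces share one parameter set.  ``config.n_restarts`` EM runs are
    started from means spread over [prior_center_min, prior_center_max]
    (jittered after the first) and the best-likelihood solution is kept;
    degenerate solutions (a state claiming less than one frame of
    posterior mass) are discarded in favour of non-degenerate restarts and
    flagged if nothing better is found.  States are returned sorted by
    ascending emission mean.
    """
    if config is None:
        config = HmmConfig()
    flat, offsets = _pack(sequences)
    if len(flat) < 2:
        raise ValueError("need at least 2 observed frames")
    rng = np.random.default_rng(config.seed)
    n_restarts = max(config.n_restarts, 1)
    best = None
    for restart in range(n_restarts):
        pi, a, means, sigmas = _init_params(k, config, rng, restart)
        # screen restarts with short EM runs; the winner is refined below
        short = None if n_restarts == 1 else config.restart_iterations
        result = _em_run(flat, offsets, k, config, pi, a, means, sigmas,
                         max_iterations=short)
        if result is None:
            continue
        if best is None:
            best = result
        else:
            # prefer non-degenerate fits; among equals, higher likelihood
            key = (not result["degenerate"], result["loglik"])
            best_key = (not best["degenerate"], best["loglik"])
            if key > best_key:
                best = result
    if best is None:
        raise RuntimeError("all EM restarts failed (non-finite likelihood)")
    if n_restarts > 1 and not best["converged"] and not best["degenerate"]:
        refined = _em_run(
            flat, offsets, k, config,
            best["pi"], best["a"], best["means"], best["sigmas"],
        )
        if refined is not None:
            refined["history"] = np.concatenate([best["history"], refined["history"]])
            best = refined
    order = np.argsort(best["means"])
    fit = HmmFit(
        k=k,
        means=best["means"][order],
        sigmas=best["sigmas"][order],
        pi=best["pi"][order],
        transition_matrix=best["a"][np.ix_(order, order)],
        log_likelihood=best["loglik"],
        n_obs=len(flat),
        converged=best["converged"],
        degenerate=best["degenerate"],
        loglik_history=best["history"],
    )
    return fit


def select_model(fits) -> tuple[HmmFit, "pd.DataFrame"]:
    """Choose the state count K by minimum AIC (ties -> smaller K).

    Returns the chosen fit and the comparison table of (K, logL, AIC),
    which also exposes the likelihood-vs-K curve for the elbow diagnostic.
    """
    import pandas as pd

    fits = sorted(fits, key=lambda f: f.k)
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fitted models")
    table = pd.DataFrame(
        {
            "K": [f.k for f in fits],
            "log_likelihood": [f.log_likelihood for f in fits],
            "AIC": [f.aic for f in fits],
            "degenerate": [f.degenerate for f in fits],
        }
    )
    # stable sort keeps ascending-K order, so the smallest K wins ties
    best = min(fits, key=lambda f: (f.aic, f.k))
    return best, table


def state_posteriors(sequence, fit: HmmFit) -> np.ndarray:
    """Posterior marginal state probabilities, shape (T, K), for one trace
    (log-space forward-backward)."""
    from scipy.stats import norm

    obs = np.asarray(sequence, dtype=float).ravel()
    t_len = len(obs)
    k = fit.k
    logb = norm.logpdf(obs[:, None], fit.means[None, :], fit.sigmas[None, :])
    log_a = np.log(fit.transition_matrix + 1e-300)
    log_alpha = np.empty((t_len, k))
    log_beta = np.zeros((t_len, k))
    log_alpha[0] = np.log(fit.pi + 1e-300) + logb[0]
    from scipy.special import logsumexp

    for t in range(1, t_len):
        log_alpha[t] = logsumexp(log_alpha[t - 1][:, None] + log_a, axis=0) + logb[t]
    for t in range(t_len - 2, -1, -1):
        log_beta[t] = logsumexp(log_a + (logb[t + 1] + log_beta[t + 1])[None, :], axis=1)
    lg = log_alpha + log_beta
    lg -= logsumexp(lg, axis=1, keepdims=True)
    return np.exp(lg)


def decode_path(sequence, fit: HmmFit) -> np.ndarray:
    """Viterbi decoding: most probable state path for one trace.

    Path values index into the fit's sorted states.
    """
    obs = np.asarray(sequence, dtype=float).ravel()
    if len(obs) == 0:
        return np.empty(0, dtype=int)
    return np.asarray(
        _viterbi_one(obs, fit.pi, fit.transition_matrix, fit.means, fit.sigmas),
        dtype=int,
    )
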