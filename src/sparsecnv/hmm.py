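"""Gaussian hidden Markov model for copy-number segmentation.

A 6-state chain over genome bins with fixed state means anchored at
log2(max(cn, 0.5) / 2) for cn = 0..5, a shared per-unit emission standard
deviation, and a transition matrix initialized with stay probability ``e``
on the diagonal and (1 - e) / (n_states - 1) off it. EM refits the shared
SD (and, under a Dirichlet prior of weight ``strength`` on the initial
transition rows, the transition matrix; large ``strength`` freezes it at
its initialization). Decoding is by Viterbi, run independently per
chromosome so state runs never cross chromosome boundaries.

All routines are vectorized across units (cells or metacells) sharing one
configuration, which is what makes genome-wide per-cell decoding on
thousands of sparse cells tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

# Above this prior weight the EM transition update is numerically frozen at
# the initial matrix (relative movement < 1e-3 for genome-scale chains), which
# is exactly the strength -> infinity semantics; skip the update entirely.
FROZEN_STRENGTH = 1e6

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class HMMConfig:
    """Segmentation HMM parameters.

    ``e`` is the prior probability of staying in the current copy-number
    segment at each bin; ``strength`` pins the transition matrix to its
    initialization during EM. ``fixed_sd`` bypasses the SD fit (useful for
    oracle comparisons); otherwise the shared SD starts at ``init_sd`` (or,
    by default, at each unit's own profile SD) and is refit by EM.
    """

    n_states: int = 6
    e: float = 0.995
    strength: float = 1e7
    fixed_sd: float | None = None
    init_sd: float | None = None  # None: start at each unit's own profile SD
    max_iter: int = 10
    tol: float = 5e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.e < 1.0):
            raise InvalidArgumentError(f"stay probability e must be in (0, 1), got {self.e}")
        if self.strength < 0:
            raise InvalidArgumentError("strength must be non-negative")
        if self.n_states < 2:
            raise InvalidArgumentError("need at least 2 states")

    @property
    def state_means(self) -> np.ndarray:
        """log2 ratio anchors: log2(max(cn, 0.5) / 2) for cn = 0..n_states-1."""
        cn = np.arange(self.n_states, dtype=float)
        return np.log2(np.maximum(cn, 0.5) / 2.0)

    def transition_matrix(self) -> np.ndarray:
        T = np.full((self.n_states, self.n_states),
                    (1.0 - self.e) / (self.n_states - 1))
        np.fill_diagonal(T, self.e)
        return T


def _emission_loglik(x: np.ndarray, means: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """(U, B, S) Gaussian log density; sd is per unit."""
    z = (x[:, :, None] - means[None, None, :]) / sd[:, None, None]
    return -0.5 * z * z - np.log(sd)[:, None, None] - 0.5 * _LOG2PI


def _chains(chrom_index: np.ndarray) -> list[slice]:
    """Contiguous runs of equal chromosome index, as slices."""
    ci = np.asarray(chrom_index)
    change = np.flatnonzero(np.diff(ci)) + 1
    bounds = np.concatenate(([0], change, [len(ci)]))
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def _forward_backward(ll: np.ndarray, T: np.ndarray, chains: list[slice],
                      need_xi: bool = False):
    """Scaled forward-backward per chain; returns (gamma, xi_sum, loglik).

    gamma: (U, B, S) posteriors; xi_sum: (U, S, S) expected transition
    counts pooled over all chains (zeros unless ``need_xi``); loglik: (U,)
    total log-likelihood.
    """
    U, B, S = ll.shape
    pi = np.full(S, 1.0 / S)
    gamma = np.empty_like(ll)
    xi = np.zeros((U, S, S))
    loglik = np.zeros(U)
    for sl in chains:
        sub = ll[:, sl, :]
        m = sub.max(axis=2, keepdims=True)
        like = np.exp(sub - m)  # (U, L, S)
        L = sub.shape[1]
        alpha = np.empty((U, L, S))
        scale = np.empty((U, L))
        a = pi[None, :] * like[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0, None]
        for b in range(1, L):
            a = (alpha[:, b - 1, :] @ T) * like[:, b, :]
            scale[:, b] = a.sum(axis=1)
            alpha[:, b, :] = a / scale[:, b, None]
        beta = np.empty((U, L, S))
        beta[:, L - 1, :] = 1.0
        for b in range(L - 2, -1, -1):
            nb = beta[:, b + 1, :] * like[:, b + 1, :]
            beta[:, b, :] = (nb @ T.T) / scale[:, b + 1, None]
            if need_xi:
                # xi_b(i,j) ∝ alpha_b(i) T(i,j) like_{b+1}(j) beta_{b+1}(j)
                xi += (alpha[:, b, :, None] * T[None] * nb[:, None, :]
                       / scale[:, b + 1, None, None])
        g = alpha * beta
        g /= g.sum(axis=2, keepdims=True)
        gamma[:, sl, :] = g
        loglik += np.log(scale).sum(axis=1) + m[:, :, 0].sum(axis=1)
    return gamma, xi, loglik


def _viterbi(ll: np.ndarray, T: np.ndarray, chains: list[slice]) -> np.ndarray:
    """Most likely state path per unit, per chain. Returns (U, B) int8."""
    U, B, S = ll.shape
    logT = np.log(T)
    log_pi = np.full(S, -np.log(S))
    path = np.empty((U, B), dtype=np.int8)
    for sl in chains:
        sub = ll[:, sl, :]
        L = sub.shape[1]
        delta = log_pi[None, :] + sub[:, 0, :]
        psi = np.empty((U, L, S), dtype=np.int8)
        for b in range(1, L):
            cand = delta[:, :, None] + logT[None, :, :]  # (U, S_prev, S)
            psi[:, b, :] = np.argmax(cand, axis=1)
            delta = np.max(cand, axis=1) + sub[:, b, :]
        last = np.argmax(delta, axis=1).astype(np.int8)
        out = np.empty((U, L), dtype=np.int8)
        out[:, L - 1] = last
        rows = np.arange(U)
        for b in range(L - 2, -1, -1):
            out[:, b] = psi[rows, b + 1, out[:, b + 1]]
        path[:, sl] = out
    return path


def hmm_segment(profile: np.ndarray, chrom_index: np.ndarray,
                config: HMMConfig) -> np.ndarray:
    """Decode integer copy-number states for one or more log2-ratio profiles.

    ``profile`` is (B,) or (U, B) of finite log2 ratios; ``chrom_index``
    gives each bin's chromosome so decoding restarts at every boundary.
    Returns states with the same leading shape, values in [0, n_states).
    """
    x = np.atleast_2d(np.asarray(profile, dtype=float))
    squeeze = np.asarray(profile).ndim == 1
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("profile contains non-finite values")
    if x.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 bins to segment")
    if x.shape[1] != len(chrom_index):
        raise InvalidArgumentError("chrom_index length must match bin count")
    chains = _chains(chrom_index)
    means = config.state_means
    T = config.transition_matrix()
    U, B = x.shape

    fit_sd = config.fixed_sd is None
    fit_T = config.strength < FROZEN_STRENGTH
    if config.fixed_sd is not None:
        sd = np.full(U, config.fixed_sd)
    elif config.init_sd is not None:
        sd = np.full(U, config.init_sd)
    else:
        # warm start at each unit's own dispersion: EM then converges in a
        # few sweeps even on genome-scale chains
        sd = np.clip(x.std(axis=1), 0.05, 1.5)

    if fit_sd or fit_T:
        prior = config.strength * config.transition_matrix()
        resid2 = (x[:, :, None] - means[None, None, :]) ** 2
        for _ in range(config.max_iter):
            ll = _emission_loglik(x, means, sd)
            gamma, xi, _ = _forward_backward(ll, T, chains, need_xi=fit_T)
            converged = True
            if fit_sd:
                sd_new = np.maximum(
                    np.sqrt((gamma * resid2).sum(axis=(1, 2)) / B), 1e-3)
                converged &= bool(np.all(np.abs(sd_new - sd) / sd < config.tol))
                sd = sd_new
            if fit_T:
                counts = xi.sum(axis=0) + prior
                T_new = counts / counts.sum(axis=1, keepdims=True)
                converged &= bool(np.max(np.abs(T_new - T)) < config.tol)
                T = T_new
            if converged:
                break

    states = _viterbi(_emission_loglik(x, means, sd), T, chains)
    return states[0] if squeeze else states
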