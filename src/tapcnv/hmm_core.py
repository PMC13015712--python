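"""Log-space forward-backward and Viterbi for batches of short chains.

All routines take pre-computed per-step log emission scores, so they are
agnostic to the emission model.  Chains are stacked into a padded array
``(batch, max_len, n_states)``; padded steps must carry log-emission 0
(probability 1 for every state), which leaves the likelihood, the posteriors
at real steps, and the decoded prefix unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PosteriorSet", "forward_backward", "forward_backward_batch", "viterbi", "viterbi_batch"]


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = m.squeeze(axis) + np.log(np.sum(np.exp(a - m), axis=axis))
    return out


@dataclass
class PosteriorSet:
    """Forward-backward output: state and transition posteriors plus likelihood.

    ``gamma[t, k] = P(z_t = k | Y)`` and ``xi[t, j, k] = P(z_t = j, z_{t+1} = k | Y)``.
    """

    gamma: np.ndarray           # (n, K)
    xi: np.ndarray              # (n-1, K, K)
    log_likelihood: float


def forward_backward_batch(
    log_emit: np.ndarray, log_T: np.ndarray, log_pi: np.ndarray, lengths: np.ndarray
):
    """Batched forward-backward on padded chains.

    Parameters
    ----------
    log_emit : (B, L, K) log emission scores, 0 beyond each chain's length.
    log_T : (K, K) or (B, K, K) log transition matrix.
    log_pi : (K,) or (B, K) log initial distribution.
    lengths : (B,) true chain lengths (1..L).

    Returns ``(gamma, xi, loglik)`` with shapes (B, L, K), (B, L-1, K, K) and
    (B,).  Entries beyond a chain's length are not meaningful and must be
    masked by the caller.
    """
    log_emit = np.asarray(log_emit, dtype=float)
    B, L, K = log_emit.shape
    log_T = np.broadcast_to(np.asarray(log_T, dtype=float), (B, K, K))
    log_pi = np.broadcast_to(np.asarray(log_pi, dtype=float), (B, K))
    lengths = np.asarray(lengths, dtype=int)

    la = np.empty((B, L, K))
    la[:, 0] = log_pi + log_emit[:, 0]
    for t in range(1, L):
        la[:, t] = log_emit[:, t] + _logsumexp(la[:, t - 1, :, None] + log_T, axis=1)
    lb = np.zeros((B, L, K))
    for t in range(L - 2, -1, -1):
        lb[:, t] = _logsumexp(log_T + (log_emit[:, t + 1] + lb[:, t + 1])[:, None, :], axis=2)

    # padded tail emissions are 0, so the total mass at L-1 equals the chain
    # likelihood regardless of padding
    loglik = _logsumexp(la[:, L - 1], axis=1)
    if not np.all(np.isfinite(loglik)):
        raise FloatingPointError("non-finite chain likelihood (all-impossible observations?)")
    gamma = la + lb - loglik[:, None, None]
    gamma = np.exp(gamma)
    gamma /= gamma.sum(axis=2, keepdims=True)

    if L > 1:
        xi = (
            la[:, :-1, :, None]
            + log_T[:, None]
            + (log_emit[:, 1:] + lb[:, 1:])[:, :, None, :]
            - loglik[:, None, None, None]
        )
        xi = np.exp(xi)
        xi /= xi.sum(axis=(2, 3), keepdims=True)
    else:
        xi = np.zeros((B, 0, K, K))
    return gamma, xi, loglik


def forward_backward(log_emit: np.ndarray, log_T: np.ndarray, log_pi: np.ndarray) -> PosteriorSet:
    """Forward-backward posteriors for a single chain of log emissions."""
    log_emit = np.atleast_2d(np.asarray(log_emit, dtype=float))
    n = log_emit.shape[0]
    gamma, xi, ll = forward_backward_batch(log_emit[None], log_T, log_pi, np.array([n]))
    return PosteriorSet(gamma[0], xi[0], float(ll[0]))


def viterbi_batch(
    log_emit: np.ndarray, log_T: np.ndarray, log_pi: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """Most probable state path per padded chain (ties broken to lowest state).

    Returns an int array (B, L); entries beyond a chain's length repeat the
    final decoded state and should be ignored.
    """
    log_emit = np.asarray(log_emit, dtype=float)
    B, L, K = log_emit.shape
    log_T = np.broadcast_to(np.asarray(log_T, dtype=float), (B, K, K))
    log_pi = np.broadcast_to(np.asarray(log_pi, dtype=float), (B, K))
    lengths = np.asarray(lengths, dtype=int)

    delta = np.empty((B, L, K))
    back = np.zeros((B, L, K), dtype=int)
    delta[:, 0] = log_pi + log_emit[:, 0]
    for t in range(1, L):
        cand = delta[:, t - 1, :, None] + log_T  # (B, prev, next)
        back[:, t] = np.argmax(cand, axis=1)
        delta[:, t] = log_emit[:, t] + np.max(cand, axis=1)

    path = np.zeros((B, L), dtype=int)
    rows = np.arange(B)
    last = lengths - 1
    path[rows, last] = np.argmax(delta[rows, last], axis=1)
    for t in range(L - 2, -1, -1):
        prev = back[rows, t + 1, path[rows, t + 1]]
        # backtrack where t is inside the chain; padded tail repeats the
        # terminal state (callers ignore it)
        path[:, t] = np.where(t < last, prev, path[rows, last])
    return path


def viterbi(log_emit: np.ndarray, log_T: np.ndarray, log_pi: np.ndarray) -> np.ndarray:
    """Most probable state path for one chain (ties broken to lowest state)."""
    log_emit = np.atleast_2d(np.asarray(log_emit, dtype=float))
    n = log_emit.shape[0]
    return viterbi_batch(log_emit[None], log_T, log_pi, np.array([n]))[0, :n]
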