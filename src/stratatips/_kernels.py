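"""Compiled inner loops: Felsenstein pruning and the serially-sampled
birth-death log-density on the flat array representation used by the
sampler. Pure-python/numpy reference implementations of the same
quantities live in :mod:`stratatips.models`; the test suite pins the two
together and against independent oracles.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

KMAX = 9  # largest supported character state space


@njit(cache=True)
def update_partials(
    dirty: np.ndarray,        # internal node ids, children-before-parents
    children: np.ndarray,     # (n_nodes, 2) child ids, -1 at tips
    age: np.ndarray,          # (n_nodes,) Ma
    rate_mult: np.ndarray,    # (n_nodes,) branch-rate multiplier of branch above node
    clock_rate: float,
    tipstate: np.ndarray,     # (n_tips, n_pat) int8, -1 = missing
    kvec: np.ndarray,         # (n_pat,) states per pattern
    cat_rates: np.ndarray,    # (ncat,) discrete-gamma rates
    partial: np.ndarray,      # (n_nodes, n_pat, ncat, kmax) conditional likelihoods
) -> None:
    """Recompute conditional likelihoods for the listed internal nodes.

    Branch length of the branch above node n is
    (age[parent] - age[n]) * clock_rate * rate_mult[n] * cat_rate.
    Under Mk(k) the transition probabilities are
    P_stay = 1/k + (k-1)/k * exp(-k t/(k-1)), P_move = 1/k - 1/k * exp(-k t/(k-1)).
    """
    n_tips = tipstate.shape[0]
    n_pat = kvec.shape[0]
    ncat = cat_rates.shape[0]
    estay = np.empty(KMAX + 1)
    for di in range(dirty.shape[0]):
        node = dirty[di]
        prow = partial[node]
        for ci in range(2):
            ch = children[node, ci]
            dur = age[node] - age[ch]
            for c in range(ncat):
                t = dur * clock_rate * rate_mult[ch] * cat_rates[c]
                for k in range(2, KMAX + 1):
                    estay[k] = math.exp(-k * t / (k - 1.0))
                if ch < n_tips:
                    for p in range(n_pat):
                        k = kvec[p]
                        ek = estay[k]
                        pii = 1.0 / k + (k - 1.0) / k * ek
                        pij = 1.0 / k - ek / k
                        s = tipstate[ch, p]
                        if ci == 0:
                            if s < 0:
                                for i in range(k):
                                    prow[p, c, i] = 1.0
                            else:
                                for i in range(k):
                                    prow[p, c, i] = pij
                                prow[p, c, s] = pii
                        else:
                            if s >= 0:
                                for i in range(k):
                                    if i == s:
                                        prow[p, c, i] *= pii
                                    else:
                                        prow[p, c, i] *= pij
                else:
                    crow = partial[ch]
                    for p in range(n_pat):
                        k = kvec[p]
                        ek = estay[k]
                        pij = 1.0 / k - ek / k
                        tot = 0.0
                        for j in range(k):
                            tot += crow[p, c, j]
                        if ci == 0:
                            for i in range(k):
                                prow[p, c, i] = pij * tot + ek * crow[p, c, i]
                        else:
                            for i in range(k):
                                prow[p, c, i] *= pij * tot + ek * crow[p, c, i]


@njit(cache=True)
def pattern_mixture(
    root_partial: np.ndarray,  # (n_pat, ncat, kmax)
    kvec: np.ndarray,
) -> np.ndarray:
    """Per-pattern likelihood: gamma-mixture average of the root sum with
    stationary root frequencies 1/k."""
    n_pat = kvec.shape[0]
    ncat = root_partial.shape[1]
    out = np.empty(n_pat)
    for p in range(n_pat):
        k = kvec[p]
        acc = 0.0
        for c in range(ncat):
            for i in range(k):
                acc += root_partial[p, c, i]
        out[p] = acc / (k * ncat)
    return out


@njit(cache=True)
def assemble_loglik(
    pat_lik: np.ndarray,      # (n_pat,) mixture likelihood per pattern
    kvec: np.ndarray,
    n_real: int,              # patterns [0, n_real) are data characters
    const_start: np.ndarray,  # (KMAX+1,) start of the k all-constant pseudo
                              # patterns for state space k, -1 if absent
    variable_only: bool,
) -> float:
    """Total log-likelihood, optionally with the Mkv variable-characters
    conditioning 1 - P(constant) applied per character state space."""
    log_denom = np.zeros(KMAX + 1)
    if variable_only:
        for k in range(2, KMAX + 1):
            s = const_start[k]
            if s >= 0:
                pconst = 0.0
                for i in range(k):
                    pconst += pat_lik[s + i]
                if pconst >= 1.0:
                    return -np.inf
                log_denom[k] = math.log1p(-pconst)
    total = 0.0
    for p in range(n_real):
        lp = pat_lik[p]
        if not lp > 0.0:
            return -np.inf
        total += math.log(lp) - log_denom[kvec[p]]
    return total


@njit(cache=True)
def bdss_log_density_arrays(
    age: np.ndarray,          # (n_nodes,) node ages, tips first
    n_tips: int,
    origin_age: float,
    lam: float,
    mu: float,
    psi: float,
) -> float:
    """Log-density of a dated tree under the serially-sampled birth-death
    process conditioned on the origin time (rho = 0, sampled lineages
    removed). Telescoped product of branch propagators:

        f = lam^(m-1) psi^m q(x0) prod_internal q(x_i) / prod_tips q(y_j)

    with log q(t) = -c1 t - 2 log((1-c2) e^(-c1 t) + (1+c2)).
    """
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi)
    c2 = -(lam - mu - psi) / c1

    n_nodes = age.shape[0]
    m = n_tips
    total = (m - 1) * math.log(lam) + m * math.log(psi)

    # q contributions; constant factors of q cancel (m in numerator,
    # m in denominator) but we keep the exact form.
    def _logq(t: float) -> float:
        return -c1 * t - 2.0 * math.log((1.0 - c2) * math.exp(-c1 * t) + (1.0 + c2))

    total += _logq(origin_age)
    for n in range(n_nodes):
        if n < n_tips:
            total -= _logq(age[n])
        else:
            total += _logq(age[n])
    return total
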