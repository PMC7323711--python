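"""Independent oracle implementations used only by the tests.

Nothing here shares code with the package's likelihood, prior, or
proposal machinery: the Mk likelihood is computed by brute-force
enumeration of ancestral states, the birth-death-sampling density by
numerical ODE integration, and HPD intervals by exhaustive window search.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad, solve_ivp

from stratatips.datamodel import MISSING, CharacterMatrix, DatedTree


def _ptrans(k: int, t: float) -> np.ndarray:
    """Mk transition matrix, written out independently."""
    out = np.empty((k, k))
    e = math.exp(-k * t / (k - 1))
    for i in range(k):
        for j in range(k):
            out[i, j] = 1.0 / k + (k - 1) / k * e if i == j else (1 - e) / k
    return out


def enumeration_loglik(
    tree: DatedTree,
    matrix: CharacterMatrix,
    clock_rate: float = 1.0,
    branch_rate_mult: dict[int, float] | None = None,
    gamma_rates=(1.0,),
    conditioning: str = "none",
) -> float:
    """Sum over all joint ancestral/missing-state assignments and gamma
    categories; O(k^nodes) so only usable on tiny trees."""
    mult = branch_rate_mult or {}
    nodes = tree.postorder()
    tip_of = tree.tip_by_label()
    total = 0.0
    for c in range(matrix.n_char):
        k = int(matrix.k[c])
        obs = {
            tip_of[t]: int(matrix.data[i, c])
            for i, t in enumerate(matrix.taxa)
        }
        free = [n for n in nodes if obs.get(n, MISSING) == MISSING]
        lik_by_cat = []
        for rate in gamma_rates:
            lik = 0.0
            for combo in itertools.product(range(k), repeat=len(free)):
                state = dict(zip(free, combo))
                state.update({n: s for n, s in obs.items() if s != MISSING})
                p = 1.0 / k  # stationary root frequency
                for n in nodes:
                    if n == tree.root:
                        continue
                    t = (tree.age[tree.parent[n]] - tree.age[n]) \
                        * clock_rate * mult.get(n, 1.0) * rate
                    p *= _ptrans(k, t)[state[tree.parent[n]], state[n]]
                lik += p
            lik_by_cat.append(lik)
        lik = float(np.mean(lik_by_cat))
        if conditioning == "variable":
            pconst_by_cat = []
            for rate in gamma_rates:
                pconst = 0.0
                for s in range(k):
                    for combo in itertools.product(range(k), repeat=len(
                        [n for n in nodes if tree.children.get(n)]
                    )):
                        internal = [n for n in nodes if tree.children.get(n)]
                        state = dict(zip(internal, combo))
                        state.update({t: s for t in tree.tips()})
                        p = 1.0 / k
                        for n in nodes:
                            if n == tree.root:
                                continue
                            t = (tree.age[tree.parent[n]] - tree.age[n]) \
                                * clock_rate * mult.get(n, 1.0) * rate
                            p *= _ptrans(k, t)[state[tree.parent[n]], state[n]]
                        pconst += p
                pconst_by_cat.append(pconst)
            lik /= 1.0 - float(np.mean(pconst_by_cat))
        total += math.log(lik)
    return total


# ----------------------------------------------------------------------
def bdss_loglik_ode(tree: DatedTree, lam: float, mu: float, psi: float,
                    origin_age: float) -> float:
    """Serially-sampled birth-death log-density via numerical integration
    of the extinction probability Riccati ODE and the per-branch
    propagator, with event factors lam (bifurcations) and psi (tips)."""
    tmax = origin_age + 1.0
    sol = solve_ivp(
        lambda t, y: [-(lam + mu + psi) * y[0] + mu + lam * y[0] ** 2],
        (0.0, tmax), [1.0], dense_output=True, rtol=1e-12, atol=1e-14,
    ).sol

    def branch(t_child: float, t_parent: float) -> float:
        val, _ = quad(
            lambda s: -(lam + mu + psi) + 2.0 * lam * sol(s)[0],
            t_child, t_parent, limit=300, epsabs=1e-12, epsrel=1e-12,
        )
        return val

    tips = set(tree.tips())
    logf = 0.0
    for n in tree.nodes:
        if n in tips:
            logf += math.log(psi)
        else:
            logf += math.log(lam)
        t_parent = origin_age if n == tree.root else tree.age[tree.parent[n]]
        logf += branch(tree.age[n], t_parent)
    return logf


# ----------------------------------------------------------------------
def hpd_exhaustive(samples, level: float) -> tuple[float, float]:
    """Smallest window over sorted samples containing ceil(level*n) points,
    found by checking every window."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = int(math.ceil(level * n))
    best = (math.inf, 0)
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if w < best[0]:
            best = (w, i)
    i = best[1]
    return float(x[i]), float(x[i + m - 1])


def max_two_uniforms_cdf(lo: float, hi: float):
    def cdf(x):
        u = np.clip((np.asarray(x) - lo) / (hi - lo), 0.0, 1.0)
        return u ** 2
    return cdf


def min_two_uniforms_cdf(lo: float, hi: float):
    def cdf(x):
        u = np.clip((np.asarray(x) - lo) / (hi - lo), 0.0, 1.0)
        return 2 * u - u ** 2
    return cdf
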