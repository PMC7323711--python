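"""Model stack: Mk/Mkv morphological likelihood with discrete-gamma rate
heterogeneity, the serially-sampled birth-death tree prior, and the
hyperprior densities on every free parameter.

The Mk model is the k-state symmetric CTMC with unit total rate away from
each state (expected substitutions per unit branch length = 1), stationary
frequencies 1/k. The "v" (variable-only) conditioning divides each
character's likelihood by 1 - P(all-constant pattern), computed with that
character's own state space and the same branch lengths and gamma mixture —
the ascertainment correction for matrices that omit invariant characters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammainc

from . import _kernels
from .datamodel import MISSING, CharacterMatrix, DatedTree, ModelParams


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GammaCategories:
    """Discrete-gamma among-character rate variation (equal-weight bins).

    ``rates`` are the means of the ``ncat`` equal-probability bins of
    Gamma(shape, rate=shape); their (equal-weight) mean is exactly 1.
    """

    shape: float
    ncat: int
    rates: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.ncat, 1.0 / self.ncat)


def discrete_gamma_rates(shape: float, ncat: int = 4) -> GammaCategories:
    """Mean-of-bin discretisation of Gamma(shape, shape) into ``ncat``
    equal-probability categories, renormalised so the mean is exactly 1.

    For Gamma(a, scale=1/a) the partial expectation over a quantile bin
    [q_lo, q_hi) is F_{a+1}(q_hi) - F_{a+1}(q_lo) (regularised incomplete
    gamma with shape a+1), so each bin mean is ncat times that mass.
    """
    if not shape > 0:
        raise ValueError("gamma shape must be > 0")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return GammaCategories(shape, 1, np.array([1.0]))
    a = float(shape)
    edges = stats.gamma.ppf(np.linspace(0.0, 1.0, ncat + 1), a, scale=1.0 / a)
    # E[X; X in bin] for Gamma(a, scale=1/a): (a * 1/a) * [F_{a+1}(hi)-F_{a+1}(lo)]
    cdf_hi = gammainc(a + 1.0, np.where(np.isfinite(edges[1:]), edges[1:] * a, np.inf))
    cdf_lo = gammainc(a + 1.0, edges[:-1] * a)
    rates = ncat * (cdf_hi - cdf_lo)
    rates = rates / rates.mean()  # exact normalisation against ppf round-off
    return GammaCategories(a, ncat, rates)


# ----------------------------------------------------------------------
def mk_transition_prob(k: int, t: float) -> np.ndarray:
    """Mk(k) transition probability matrix after branch length ``t``.

    P_ii = 1/k + (k-1)/k * exp(-k t / (k-1)); off-diagonals all equal.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e = math.exp(-k * t / (k - 1.0))
    pii = 1.0 / k + (k - 1.0) / k * e
    pij = 1.0 / k - e / k
    out = np.full((k, k), pij)
    np.fill_diagonal(out, pii)
    return out


# ----------------------------------------------------------------------
def _tree_arrays(tree: DatedTree):
    """Flat array view of a DatedTree: tips first, then internals.

    Returns (node_order, index_of, children, parent, age, n_tips) where
    ``node_order[i]`` is the DatedTree node id at flat index i.
    """
    tips = tree.tips()
    internals = [n for n in tree.postorder() if tree.children.get(n)]
    node_order = tips + internals
    index_of = {n: i for i, n in enumerate(node_order)}
    n = len(node_order)
    children = np.full((n, 2), -1, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    age = np.empty(n)
    for nd, i in index_of.items():
        age[i] = tree.age[nd]
        kids = tree.children.get(nd, ())
        for j, c in enumerate(kids):
            children[i, j] = index_of[c]
        p = tree.parent.get(nd)
        if p is not None:
            parent[i] = index_of[p]
    return node_order, index_of, children, parent, age, len(tips)


def build_pattern_arrays(matrix: CharacterMatrix, tip_taxa: list[str]):
    """Tip-state patterns for the pruning kernel, with the all-constant
    pseudo-patterns (one block of k patterns per distinct state space k)
    appended for the Mkv conditioning.

    Taxa present in ``tip_taxa`` but absent from the matrix contribute
    all-missing rows. Returns (tipstate, kvec, n_real, const_start).
    """
    missing_from_tree = set(matrix.taxa) - set(tip_taxa)
    if missing_from_tree:
        raise ValueError(
            "matrix taxa absent from tree: " + ", ".join(sorted(missing_from_tree))
        )
    n_real = matrix.n_char
    ks = sorted(set(int(k) for k in matrix.k))
    n_pat = n_real + sum(ks)
    n_tips = len(tip_taxa)
    tipstate = np.full((n_tips, n_pat), MISSING, dtype=np.int8)
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    for i, taxon in enumerate(tip_taxa):
        r = row_of.get(taxon)
        if r is not None:
            tipstate[i, :n_real] = matrix.data[r]
    kvec = np.empty(n_pat, dtype=np.int8)
    kvec[:n_real] = matrix.k
    const_start = np.full(_kernels.KMAX + 1, -1, dtype=np.int64)
    pos = n_real
    for k in ks:
        const_start[k] = pos
        for s in range(k):
            tipstate[:, pos] = s
            kvec[pos] = k
            pos += 1
    return tipstate, kvec, n_real, const_start


def mk_log_likelihood(
    tree: DatedTree,
    matrix: CharacterMatrix,
    clock_rate: float = 1.0,
    branch_rate_mult: dict[int, float] | None = None,
    gamma: GammaCategories | None = None,
    conditioning: str = "none",
) -> float:
    """Pruning log-likelihood of the matrix on the dated tree.

    Branch length of the branch above node n is
    ``branch_duration(tree, n) * clock_rate * branch_rate_mult[n]``, further
    scaled by each gamma category rate. Missing states contribute partial
    likelihood 1 for every state; root frequencies are stationary (1/k).
    ``conditioning`` is ``"none"`` (Mk) or ``"variable"`` (Mkv).
    """
    if conditioning not in ("none", "variable"):
        raise ValueError("conditioning must be 'none' or 'variable'")
    if gamma is None:
        gamma = GammaCategories(1.0, 1, np.array([1.0]))
    node_order, index_of, children, parent, age, n_tips = _tree_arrays(tree)
    rate_mult = np.ones(len(node_order))
    if branch_rate_mult:
        for nd, m in branch_rate_mult.items():
            rate_mult[index_of[nd]] = m
    tip_taxa = [tree.labels[n] for n in node_order[:n_tips]]
    tipstate, kvec, n_real, const_start = build_pattern_arrays(matrix, tip_taxa)
    ncat = gamma.ncat
    partial = np.empty((len(node_order), len(kvec), ncat, _kernels.KMAX))
    dirty = np.arange(n_tips, len(node_order), dtype=np.int64)  # postorder
    _kernels.update_partials(
        dirty, children, age, rate_mult, float(clock_rate),
        tipstate, kvec, np.asarray(gamma.rates, dtype=float), partial,
    )
    root_idx = index_of[tree.root]
    pat_lik = _kernels.pattern_mixture(partial[root_idx], kvec)
    return _kernels.assemble_loglik(
        pat_lik, kvec, n_real, const_start, conditioning == "variable"
    )


# ----------------------------------------------------------------------
def bdss_log_density(
    tree: DatedTree,
    birth_rate: float,
    death_rate: float,
    sampling_rate: float,
    origin_age: float,
) -> float:
    """Log-density of the dated tree under the serially-sampled birth-death
    process (birth lam, death mu, Poisson psi-sampling with removal),
    conditioned on the origin time. All tips are psi-samples; there is no
    extant (rho) sampling. Invariant under tip relabelling at fixed ages.
    """
    for name, val in (("birth_rate", birth_rate), ("death_rate", death_rate),
                      ("sampling_rate", sampling_rate)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0")
    root_age = tree.age[tree.root]
    if not origin_age > root_age:
        raise ValueError(
            f"origin_age {origin_age} must exceed root age {root_age}"
        )
    _, _, _, _, age, n_tips = _tree_arrays(tree)
    return _kernels.bdss_log_density_arrays(
        age, n_tips, float(origin_age),
        float(birth_rate), float(death_rate), float(sampling_rate),
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior hyperparameters (defaults: the analysis defaults).

    The birth-rate lognormal is parameterised by its mean in real space:
    E[X] = mean_real with sdlog = birth_sdlog, i.e.
    mulog = ln(mean_real) - sdlog^2 / 2.
    """

    clock_rate_mean: float = 0.003
    clock_rate_offset: float = 0.0016
    clock_sd_mean: float = 1.0
    shape_max: float = 10.0
    birth_mean_real: float = 0.14
    birth_sdlog: float = 0.9
    death_mean: float = 0.1
    sampling_mean: float = 0.03

    def __post_init__(self) -> None:
        for name in ("clock_rate_mean", "clock_sd_mean", "shape_max",
                     "birth_mean_real", "birth_sdlog", "death_mean",
                     "sampling_mean"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.clock_rate_offset < 0:
            raise ValueError("clock_rate_offset must be >= 0")

    @property
    def birth_mulog(self) -> float:
        return math.log(self.birth_mean_real) - self.birth_sdlog ** 2 / 2.0


def _exp_logpdf(x: float, mean: float, offset: float = 0.0) -> float:
    if x < offset:
        return -math.inf
    return -math.log(mean) - (x - offset) / mean


def _lognormal_logpdf(x: float, mulog: float, sdlog: float) -> float:
    if not x > 0:
        return -math.inf
    z = (math.log(x) - mulog) / sdlog
    return -math.log(x * sdlog) - 0.5 * math.log(2.0 * math.pi) - 0.5 * z * z


def hyperprior_terms(params: ModelParams, priors: PriorConfig) -> dict[str, float]:
    """Per-component log-densities of the scalar hyperpriors."""
    shape_ok = 0.0 < params.gamma_shape <= priors.shape_max
    return {
        "clock_rate": _exp_logpdf(params.clock_rate, priors.clock_rate_mean,
                                  priors.clock_rate_offset),
        "clock_sd": _exp_logpdf(params.clock_sd, priors.clock_sd_mean),
        "gamma_shape": (-math.log(priors.shape_max) if shape_ok else -math.inf),
        "birth_rate": _lognormal_logpdf(params.birth_rate, priors.birth_mulog,
                                        priors.birth_sdlog),
        "death_rate": _exp_logpdf(params.death_rate, priors.death_mean),
        "sampling_rate": _exp_logpdf(params.sampling_rate, priors.sampling_mean),
    }


def branch_rate_log_prior(mults, clock_sd: float) -> float:
    """iid lognormal prior on branch-rate multipliers with mean 1 in real
    space and sdlog = clock_sd (so mulog = -clock_sd^2 / 2)."""
    mulog = -clock_sd ** 2 / 2.0
    vals = np.asarray(
        list(mults.values()) if isinstance(mults, dict) else mults, dtype=float
    )
    if vals.size == 0:
        return 0.0
    if np.any(vals <= 0):
        return -math.inf
    z = (np.log(vals) - mulog) / clock_sd
    return float(
        np.sum(-np.log(vals * clock_sd) - 0.5 * math.log(2.0 * math.pi) - 0.5 * z * z)
    )


def log_prior(params: ModelParams, priors: PriorConfig | None = None) -> float:
    """Joint log-density of all scalar hyperpriors plus the branch-rate
    multiplier prior; -inf encodes out-of-support (never raises)."""
    if priors is None:
        priors = PriorConfig()
    total = sum(hyperprior_terms(params, priors).values())
    total += branch_rate_log_prior(params.branch_rate_mult, params.clock_sd)
    return total
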