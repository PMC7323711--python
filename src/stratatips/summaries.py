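"""Posterior summarisation: HPD intervals, medians, paired inter-site age
comparisons, per-sample age spreads, autocorrelation-based effective
sample sizes, and rooted 50% majority-rule consensus trees with clade
posterior probabilities.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DatedTree


# ----------------------------------------------------------------------
def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(level * n) sorted samples
    (the Chen-Shao empirical HPD)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for an HPD interval")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    m = int(math.ceil(level * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def prob_younger(ages_a, ages_b) -> float:
    """Fraction of paired posterior samples in which A is younger
    (numerically smaller age) than B; exact ties count 1/2."""
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("age series must be 1-D and equal length")
    return float(np.mean((a < b) + 0.5 * (a == b)))


def per_sample_age_range(trace, taxa: list[str]) -> float:
    """Mean over samples of the within-sample spread (max - min, Ma) of
    the named taxa's ages. Taxa must have independent age columns
    (``age_<taxon>``); in a linked-ages run the spread is 0 by
    construction."""
    if not taxa:
        raise ValueError("no taxa given")
    cols = []
    for t in taxa:
        cols.append(trace.column(f"age_{t}"))  # KeyError for unknown taxon
    arr = np.column_stack(cols)
    return float(np.mean(arr.max(axis=1) - arr.min(axis=1)))


# ----------------------------------------------------------------------
def ess(samples) -> float:
    """Effective sample size n / (1 + 2 sum rho_k) with Geyer's
    initial-positive-sequence truncation. A constant series has no
    information; it reports 0 with a warning."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    v = x.var()
    if v == 0:
        warnings.warn("constant series: ESS undefined, reporting 0",
                      stacklevel=2)
        return 0.0
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs while their sum stays positive
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(n / tau)


@dataclass(frozen=True)
class IntervalSummary:
    """Median and HPD interval of one scalar series."""

    median: float
    lower: float
    upper: float
    level: float = 0.95
    ess: float = float("nan")

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("HPD lower bound exceeds upper bound")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def summarize_series(samples, level: float = 0.95) -> IntervalSummary:
    x = np.asarray(samples, dtype=float)
    lo, hi = hpd_interval(x, level)
    e = ess(x) if x.size >= 10 else float("nan")
    return IntervalSummary(float(np.median(x)), lo, hi, level, e)


def summarize_trace(trace, burnin: float = 0.1, level: float = 0.95) -> pd.DataFrame:
    """One row (median, HPD bounds, ESS) per logged quantity, after
    discarding the burn-in fraction."""
    post = trace.burnin(burnin)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns: ESS 0 is fine here
        for name in post.columns:
            if name == "generation":
                continue
            s = summarize_series(post.column(name), level)
            rows.append({
                "parameter": name, "median": s.median,
                f"hpd{int(level * 100)}_lower": s.lower,
                f"hpd{int(level * 100)}_upper": s.upper,
                "ess": s.ess,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Majority-rule consensus (rooted, clade-based)
# ----------------------------------------------------------------------
@dataclass
class ConsensusNode:
    """Node of a (possibly multifurcating) consensus tree."""

    taxa: frozenset[str]
    support: float
    children: list["ConsensusNode"]

    @property
    def is_tip(self) -> bool:
        return len(self.taxa) == 1


@dataclass
class ConsensusTree:
    root: ConsensusNode
    n_trees: int

    def clade_support(self) -> dict[frozenset[str], float]:
        out: dict[frozenset[str], float] = {}
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if not nd.is_tip:
                out[nd.taxa] = nd.support
            stack.extend(nd.children)
        return out

    def newick(self) -> str:
        def rec(nd: ConsensusNode) -> str:
            if nd.is_tip:
                return next(iter(nd.taxa))
            inner = ",".join(rec(c) for c in sorted(
                nd.children, key=lambda c: min(c.taxa)
            ))
            return f"({inner})[&support={nd.support:.3f}]"

        return rec(self.root) + ";"


def majority_consensus(trees: list[DatedTree], threshold: float = 0.5) -> ConsensusTree:
    """Rooted majority-rule consensus: clades with frequency strictly
    above ``threshold`` are kept (plus trivial clades), each labelled
    with its frequency. With threshold >= 0.5 the kept clades cannot
    conflict; below that, clades are admitted greedily by frequency,
    skipping incompatible ones, so the output is always a tree."""
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    taxa = frozenset(trees[0].taxa())
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        if frozenset(t.taxa()) != taxa:
            raise ValueError("all trees must share one taxon set")
        for clade in t.clades():
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    kept: list[tuple[frozenset[str], float]] = [(taxa, 1.0)]
    candidates = sorted(
        ((c, cnt / n) for c, cnt in counts.items()
         if cnt / n > threshold and c != taxa and len(c) > 1),
        key=lambda cf: (-cf[1], -len(cf[0]), sorted(cf[0])),
    )
    for clade, freq in candidates:
        if all(c <= clade or clade <= c or not (c & clade) for c, _ in kept):
            kept.append((clade, freq))
    # nest kept clades (they are pairwise compatible)
    kept.sort(key=lambda cf: -len(cf[0]))
    nodes = [ConsensusNode(c, f, []) for c, f in kept]
    nodes += [ConsensusNode(frozenset([t]), 1.0, []) for t in sorted(taxa)]
    for i, nd in enumerate(nodes):
        if nd.taxa == taxa:
            continue
        best = None
        for j, other in enumerate(nodes):
            if i == j or not nd.taxa < other.taxa:
                continue
            if best is None or len(other.taxa) < len(best.taxa):
                best = other
        best.children.append(nd)
    root = next(nd for nd in nodes if nd.taxa == taxa)
    return ConsensusTree(root, n)


def write_consensus_nexus(ctree: ConsensusTree, path) -> None:
    """Consensus topology as a NEXUS trees block with clade posterior
    probabilities as node comments."""
    from pathlib import Path

    text = "\n".join([
        "#NEXUS", "BEGIN TREES;",
        f"  tree CONSENSUS = [&R] {ctree.newick()}",
        "END;", "",
    ])
    Path(path).write_text(text)
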