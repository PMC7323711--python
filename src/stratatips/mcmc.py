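"""Metropolis-Hastings driver for the tip-dating model stack.

One generation = one proposal. The state is kept in flat numpy arrays
(tips first, internals after) so the compiled pruning kernel can update
only the nodes whose conditional likelihoods a proposal actually dirties
(the changed nodes and their root-ward ancestors).

Sampling from the prior (``prior_only``) replaces the data likelihood by
the constant 1 and runs the identical machinery — this is how the
*effective* prior that the operators induce on site ages is examined.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels, operators
from .datamodel import (
    DatedTree, CharacterMatrix, FossilSite, ModelParams, StratSequence,
)
from .models import (
    PriorConfig, branch_rate_log_prior, discrete_gamma_rates,
    build_pattern_arrays, hyperprior_terms,
)

_PARAM_NAMES = ("clock_rate", "clock_sd", "gamma_shape", "birth_rate",
                "death_rate", "sampling_rate")


# ----------------------------------------------------------------------
class Trace:
    """Logged sample series: one labelled column per quantity, one row per
    log interval, first column the generation index."""

    def __init__(self, columns: list[str], values: np.ndarray) -> None:
        if values.ndim != 2 or values.shape[1] != len(columns):
            raise ValueError("values must be (n_samples, n_columns)")
        self.columns = list(columns)
        self.values = values

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trace":
        return cls(list(df.columns), df.to_numpy(dtype=float))

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.columns.index(name)
        except ValueError:
            raise KeyError(f"no trace column {name!r}") from None
        return self.values[:, j]

    def burnin(self, fraction: float) -> "Trace":
        """Drop the first ``fraction`` of samples (summary-time burn-in)."""
        if not 0 <= fraction < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")
        start = int(math.ceil(self.n_samples * fraction))
        return Trace(self.columns, self.values[start:])

    def __len__(self) -> int:
        return self.n_samples


@dataclass
class MCMCResult:
    trace: Trace
    trees: list[DatedTree] | None
    acceptance: dict[str, tuple[int, int]]  # kind -> (proposed, accepted)
    site_ids: list[str]
    final_tree: DatedTree | None = None


@dataclass
class AnalysisData:
    """In-memory inputs of one analysis."""

    matrix: CharacterMatrix | None
    sites: list[FossilSite]
    seq: StratSequence = field(default_factory=StratSequence)
    tree: DatedTree | None = None
    params: ModelParams | None = None


# ----------------------------------------------------------------------
class ChainState:
    """Flat mutable sampler state (arrays indexed tips-first)."""

    def __init__(self) -> None:
        # filled by from_inputs
        self.age = np.empty(0)
        self.parent = np.empty(0, dtype=np.int64)
        self.children = np.empty((0, 2), dtype=np.int64)
        self.root = -1
        self.n_tips = 0
        self.tip_labels: list[str] = []
        self.rate_mult = np.empty(0)
        self.internal_nonroot = np.empty(0, dtype=np.int64)
        self.clock_rate = 0.0
        self.clock_sd = 0.0
        self.gamma_shape = 0.0
        self.birth_rate = 0.0
        self.death_rate = 0.0
        self.sampling_rate = 0.0
        self.origin_age = 0.0
        self.site_ids: list[str] = []
        self.site_tips: list[np.ndarray] = []
        self.site_min = np.empty(0)
        self.site_max = np.empty(0)
        self.site_age = np.empty(0)
        self.site_below: list[tuple[int, ...]] = []
        self.site_above: list[tuple[int, ...]] = []
        self.prior_only = True
        self.conditioning = "variable"
        self.ncat = 4
        self.cat_rates = np.array([1.0])
        self.tipstate = np.empty((0, 0), dtype=np.int8)
        self.kvec = np.empty(0, dtype=np.int8)
        self.n_real = 0
        self.const_start = np.empty(0, dtype=np.int64)
        self.partial = np.empty((0, 0, 0, 0))
        self._postorder_internal = np.empty(0, dtype=np.int64)
        self._pos = np.empty(0, dtype=np.int64)
        self._stamp = np.empty(0, dtype=np.int64)
        self._stamp_ctr = 0
        # cached log terms
        self.loglik = 0.0
        self.log_tree_prior = 0.0
        self.hp_terms: dict[str, float] = {}
        self.log_ratemult_prior = 0.0
        self.log_site_uniform = 0.0
        self.priors = PriorConfig()

    # ------------------------------------------------------------------
    @classmethod
    def from_inputs(
        cls,
        tree: DatedTree,
        sites: list[FossilSite],
        seq: StratSequence,
        params: ModelParams,
        matrix: CharacterMatrix | None,
        priors: PriorConfig,
        ncat: int = 4,
        conditioning: str = "variable",
        prior_only: bool = False,
    ) -> "ChainState":
        st = cls()
        st.priors = priors
        tips = tree.tips()
        internals = [n for n in tree.postorder() if tree.children.get(n)]
        node_order = tips + internals
        idx = {n: i for i, n in enumerate(node_order)}
        n = len(node_order)
        st.n_tips = len(tips)
        st.tip_labels = [tree.labels[t] for t in tips]
        st.age = np.array([tree.age[nd] for nd in node_order])
        st.parent = np.array(
            [idx.get(tree.parent.get(nd), -1) for nd in node_order], dtype=np.int64
        )
        st.children = np.full((n, 2), -1, dtype=np.int64)
        for nd, i in idx.items():
            for j, c in enumerate(tree.children.get(nd, ())):
                st.children[i, j] = idx[c]
        st.root = idx[tree.root]
        st.internal_nonroot = np.array(
            [i for i in range(st.n_tips, n) if i != st.root], dtype=np.int64
        )
        st.rate_mult = np.ones(n)
        for nd, m in params.branch_rate_mult.items():
            st.rate_mult[idx[nd]] = m
        for name in _PARAM_NAMES:
            setattr(st, name, float(getattr(params, name)))
        st.origin_age = float(params.origin_age)

        tip_idx = {lab: i for i, lab in enumerate(st.tip_labels)}
        covered: set[str] = set()
        site_list = list(sites)
        for s in site_list:
            covered.update(s.taxa)
        for lab in st.tip_labels:  # uncovered taxa: fixed single-taxon sites
            if lab not in covered:
                a = st.age[tip_idx[lab]]
                site_list.append(FossilSite(lab, (lab,), a, a, a))
        st.site_ids = [s.site_id for s in site_list]
        st.site_tips = [
            np.array([tip_idx[t] for t in s.taxa], dtype=np.int64)
            for s in site_list
        ]
        st.site_min = np.array([s.min_age for s in site_list])
        st.site_max = np.array([s.max_age for s in site_list])
        st.site_age = np.array([s.age for s in site_list])
        sidx = {s: i for i, s in enumerate(st.site_ids)}
        below: list[list[int]] = [[] for _ in site_list]
        above: list[list[int]] = [[] for _ in site_list]
        for lower, upper in seq.relations:
            if lower not in sidx or upper not in sidx:
                raise ValueError(
                    f"stratigraphic relation names unknown site: {lower}/{upper}"
                )
            below[sidx[upper]].append(sidx[lower])
            above[sidx[lower]].append(sidx[upper])
        st.site_below = [tuple(b) for b in below]
        st.site_above = [tuple(a) for a in above]
        # sync tip ages to site ages
        for i, tips_i in enumerate(st.site_tips):
            st.age[tips_i] = st.site_age[i]

        st.ncat = ncat
        st.conditioning = conditioning
        st.cat_rates = discrete_gamma_rates(st.gamma_shape, ncat).rates
        st.prior_only = prior_only or matrix is None
        if not st.prior_only:
            st.tipstate, st.kvec, st.n_real, st.const_start = (
                build_pattern_arrays(matrix, st.tip_labels)
            )
            kmax = int(st.kvec.max())
            st.partial = np.empty((n, st.kvec.shape[0], ncat, kmax))
        st._pos = np.empty(n, dtype=np.int64)
        st._stamp = np.zeros(n, dtype=np.int64)
        st.refresh_postorder()
        st.recompute_all()
        return st

    # ------------------------------------------------------------------
    def refresh_postorder(self) -> None:
        order: list[int] = []
        stack = [self.root]
        children = self.children
        while stack:
            nd = stack.pop()
            order.append(nd)
            if children[nd, 0] >= 0:
                stack.append(children[nd, 0])
                stack.append(children[nd, 1])
        order.reverse()
        self._postorder_internal = np.array(
            [nd for nd in order if self.children[nd, 0] >= 0], dtype=np.int64
        )
        for p, nd in enumerate(order):
            self._pos[nd] = p

    def full_loglik(self) -> float:
        if self.prior_only:
            return 0.0
        return self._loglik_update(self._postorder_internal)

    def _loglik_update(self, dirty: np.ndarray) -> float:
        _kernels.update_partials(
            dirty, self.children, self.age, self.rate_mult, self.clock_rate,
            self.tipstate, self.kvec, self.cat_rates, self.partial,
        )
        pat = _kernels.pattern_mixture(self.partial[self.root], self.kvec)
        return _kernels.assemble_loglik(
            pat, self.kvec, self.n_real, self.const_start,
            self.conditioning == "variable",
        )

    def tree_prior(self) -> float:
        return _kernels.bdss_log_density_arrays(
            self.age, self.n_tips, self.origin_age,
            self.birth_rate, self.death_rate, self.sampling_rate,
        )

    def params_view(self) -> ModelParams:
        return ModelParams(
            clock_rate=self.clock_rate, clock_sd=self.clock_sd,
            gamma_shape=self.gamma_shape, birth_rate=self.birth_rate,
            death_rate=self.death_rate, sampling_rate=self.sampling_rate,
            origin_age=self.origin_age,
            branch_rate_mult={
                int(i): float(self.rate_mult[i])
                for i in range(self.age.shape[0]) if i != self.root
            },
        )

    def recompute_all(self) -> None:
        self.hp_terms = hyperprior_terms(self.params_view(), self.priors)
        nonroot = np.ones(self.age.shape[0], dtype=bool)
        nonroot[self.root] = False
        self.log_ratemult_prior = branch_rate_log_prior(
            self.rate_mult[nonroot], self.clock_sd
        )
        widths = self.site_max - self.site_min
        self.log_site_uniform = float(-np.sum(np.log(widths[widths > 0])))
        self.log_tree_prior = self.tree_prior()
        self.loglik = self.full_loglik()

    def log_prior_total(self) -> float:
        return (sum(self.hp_terms.values()) + self.log_ratemult_prior
                + self.log_site_uniform + self.log_tree_prior)

    # ------------------------------------------------------------------
    def ancestors_dirty(self, nodes) -> np.ndarray:
        """Given changed nodes, the internal nodes needing partial updates
        (the changed internals and all their ancestors), in postorder."""
        self._stamp_ctr += 1
        ctr = self._stamp_ctr
        stamp = self._stamp
        parent = self.parent
        children = self.children
        out: list[int] = []
        for nd in nodes:
            if children[nd, 0] >= 0 and stamp[nd] != ctr:
                stamp[nd] = ctr
                out.append(nd)
            p = parent[nd]
            while p >= 0 and stamp[p] != ctr:
                stamp[p] = ctr
                out.append(p)
                p = parent[p]
        out.sort(key=self._pos.__getitem__)
        return np.array(out, dtype=np.int64)

    def to_dated_tree(self) -> DatedTree:
        n = self.age.shape[0]
        parent = {i: int(self.parent[i]) for i in range(n) if self.parent[i] >= 0}
        children = {
            i: tuple(int(c) for c in self.children[i] if c >= 0)
            for i in range(n) if self.children[i, 0] >= 0
        }
        age = {i: float(self.age[i]) for i in range(n)}
        labels = {i: self.tip_labels[i] for i in range(self.n_tips)}
        return DatedTree(parent, children, age, labels, self.root, validate=False)


# ----------------------------------------------------------------------
def initial_site_ages(sites: list[FossilSite], seq: StratSequence) -> dict[str, float]:
    """Bound midpoints, clamped by a topological pass so that every site
    lying below (older side of) another starts at least as old."""
    ages = {s.site_id: (s.min_age + s.max_age) / 2.0 for s in sites}
    by_id = {s.site_id: s for s in sites}
    # process lower sites first, then clamp upper sites downward
    from graphlib import TopologicalSorter

    ts: TopologicalSorter = TopologicalSorter()
    for s in sites:
        ts.add(s.site_id)
    for lower, upper in seq.relations:
        ts.add(upper, lower)
    for sid in ts.static_order():
        lows = seq.below_of(sid) if sid in by_id else []
        for lo_id in lows:
            if lo_id in ages and ages[sid] > ages[lo_id]:
                ages[sid] = ages[lo_id]
        s = by_id[sid]
        if ages[sid] < s.min_age - 1e-12:
            raise ValueError(
                f"cannot initialise site {sid}: ordering forces age below "
                f"its minimum bound {s.min_age}"
            )
        ages[sid] = max(ages[sid], s.min_age)
    return ages


def build_initial_tree(
    tip_ages: dict[str, float], rng: np.random.Generator, join_scale: float = 2.0
) -> DatedTree:
    """Serial-sample-coalescent-style random starting tree: repeatedly join
    two random lineages at an age above both (exponential increments)."""
    labels = sorted(tip_ages)
    nodes = list(range(len(labels)))
    age = {i: float(tip_ages[lab]) for i, lab in enumerate(labels)}
    parent: dict[int, int] = {}
    children: dict[int, tuple[int, ...]] = {}
    active = list(nodes)
    tau = max(age.values())
    nxt = len(labels)
    while len(active) > 1:
        i = int(rng.integers(0, len(active)))
        a = active.pop(i)
        j = int(rng.integers(0, len(active)))
        b = active.pop(j)
        tau = max(tau, age[a], age[b]) + float(rng.exponential(join_scale)) + 1e-6
        age[nxt] = tau
        children[nxt] = (a, b)
        parent[a] = nxt
        parent[b] = nxt
        active.append(nxt)
        nxt += 1
    root = active[0]
    lab_map = {i: lab for i, lab in enumerate(labels)}
    return DatedTree(parent, children, age, lab_map, root)


def _initialise(data: AnalysisData, config, rng: np.random.Generator):
    sites = list(data.sites)
    seq = data.seq or StratSequence()
    if data.tree is not None:
        tree = data.tree
    else:
        ages0 = initial_site_ages(sites, seq)
        tip_ages: dict[str, float] = {}
        for s in sites:
            for t in s.taxa:
                tip_ages[t] = ages0[s.site_id]
        if data.matrix is not None:
            for t in data.matrix.taxa:
                if t not in tip_ages:
                    raise ValueError(
                        f"taxon {t} is in the matrix but has no site or age"
                    )
        sites = [
            FossilSite(s.site_id, s.taxa, s.min_age, s.max_age, ages0[s.site_id])
            for s in sites
        ]
        tree = build_initial_tree(tip_ages, rng)
    params = data.params
    if params is None:
        pri = config.priors()
        params = ModelParams(
            clock_rate=pri.clock_rate_offset + pri.clock_rate_mean,
            clock_sd=0.5,
            gamma_shape=1.0,
            birth_rate=pri.birth_mean_real,
            death_rate=pri.death_mean,
            sampling_rate=pri.sampling_mean,
            origin_age=tree.age[tree.root] + 10.0,
        )
    return tree, sites, seq, params


# ----------------------------------------------------------------------
def _operator_schedule(state: ChainState, config) -> tuple[list, np.ndarray]:
    """(entries, cumulative weights); entry = (kind, payload)."""
    w = dict(config.operator_weights or {})

    def weight(name: str, default: float) -> float:
        return float(w.get(name, default))

    entries: list[tuple[str, object]] = []
    weights: list[float] = []
    n_int = state.internal_nonroot.size
    n_branch = state.age.shape[0] - 1
    per_taxon = weight("site_ages", 1.0)
    for i in range(len(state.site_ids)):
        if state.site_max[i] > state.site_min[i]:
            entries.append(("site", i))
            weights.append(per_taxon * state.site_tips[i].size)
    entries.append(("node_slide", None)); weights.append(weight("node_slide", 0.5 * max(n_int, 1)))
    entries.append(("root", None)); weights.append(weight("root", 2.0))
    entries.append(("origin", None)); weights.append(weight("origin", 2.0))
    entries.append(("narrow", None)); weights.append(weight("narrow", 0.3 * max(n_int, 1)))
    for name, dflt in (("clock_rate", 2.0), ("clock_sd", 2.0),
                       ("gamma_shape", 2.0), ("birth_rate", 1.0),
                       ("death_rate", 1.0), ("sampling_rate", 1.0)):
        entries.append(("param", name)); weights.append(weight(name, dflt))
    entries.append(("rate_mult", None)); weights.append(weight("rate_mult", 0.25 * max(n_branch, 1)))
    keep = [i for i, wt in enumerate(weights) if wt > 0]
    entries = [entries[i] for i in keep]
    cum = np.cumsum([weights[i] for i in keep])
    if cum[-1] <= 0:
        raise ValueError("no operator has positive weight")
    return entries, cum / cum[-1]


def run_chain(config, data: AnalysisData, rng=None) -> MCMCResult:
    """Run one Metropolis-Hastings chain; fully reproducible from the seed.

    Acceptance probability is min(1, exp(dlog-posterior + log-Hastings));
    hard-rejected proposals count as rejections. The trace (and tree log,
    if enabled) is recorded every ``config.log_interval`` generations,
    starting with the initial state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree, sites, seq, params = _initialise(data, config, rng)
    state = ChainState.from_inputs(
        tree, sites, seq, params, data.matrix, config.priors(),
        ncat=config.gamma_ncat, conditioning=config.conditioning,
        prior_only=config.prior_only,
    )
    # refuse a zero-probability start, naming the offending component
    for name, val in state.hp_terms.items():
        if not math.isfinite(val):
            raise ValueError(f"initial state has zero prior probability: {name}")
    for name, val in (("tree prior", state.log_tree_prior),
                      ("branch-rate prior", state.log_ratemult_prior),
                      ("likelihood", state.loglik)):
        if not math.isfinite(val):
            raise ValueError(f"initial state has zero probability: {name}")

    entries, cumw = _operator_schedule(state, config)
    n_ops = len(entries)
    counts = {e[0] if e[0] != "param" else e[1]: [0, 0] for e in entries}

    chain_length = int(config.chain_length)
    log_interval = int(config.log_interval)
    n_rows = chain_length // log_interval + 1
    site_cols = [f"age_{sid}" for sid in state.site_ids]
    columns = (["generation", "posterior", "likelihood", "prior"]
               + list(_PARAM_NAMES)
               + ["origin_age", "root_age", "tree_length"] + site_cols)
    out = np.empty((n_rows, len(columns)))
    trees: list[DatedTree] | None = [] if config.log_trees else None

    age = state.age
    parent = state.parent
    site_age = state.site_age
    site_tips = state.site_tips
    rand = rng.random

    def log_row(row: int, gen: int) -> None:
        nonroot = parent >= 0
        tlen = float(np.sum(age[parent[nonroot]] - age[nonroot]))
        prior = state.log_prior_total()
        vals = [gen, state.loglik + prior, state.loglik, prior]
        vals.extend(getattr(state, p) for p in _PARAM_NAMES)
        vals.extend([state.origin_age, age[state.root], tlen])
        vals.extend(site_age)
        out[row] = vals
        if trees is not None:
            trees.append(state.to_dated_tree())

    log_row(0, 0)
    row = 1
    for gen in range(1, chain_length + 1):
        kind, payload = entries[
            int(np.searchsorted(cumw, rand())) if n_ops > 1 else 0
        ]
        ck = kind if kind != "param" else payload
        counts[ck][0] += 1

        if kind == "site":
            s = payload
            if state.site_below[s] or state.site_above[s]:
                prop = operators.propose_ordered_site_age(state, s, rng)
            else:
                prop = operators.propose_linked_site_age(state, s, rng)
        else:
            prop = operators.standard_proposals(
                state, rng, kind=payload if kind == "param" else kind
            )

        if prop.hard_reject:
            if row <= n_rows - 1 and gen % log_interval == 0:
                log_row(row, gen); row += 1
            continue

        accepted = False
        if prop.kind == "site_age":
            s = prop.target
            a_new = prop.value
            a_old = site_age[s]
            tips = site_tips[s]
            age[tips] = a_new
            site_age[s] = a_new
            new_tp = state.tree_prior()
            delta = new_tp - state.log_tree_prior
            if state.prior_only:
                if delta >= 0 or rand() < math.exp(delta):
                    state.log_tree_prior = new_tp
                    accepted = True
                else:
                    age[tips] = a_old
                    site_age[s] = a_old
            else:
                dirty = state.ancestors_dirty(tips)
                new_ll = state._loglik_update(dirty)
                delta += new_ll - state.loglik
                if delta >= 0 or rand() < math.exp(delta):
                    state.log_tree_prior = new_tp
                    state.loglik = new_ll
                    accepted = True
                else:
                    age[tips] = a_old
                    site_age[s] = a_old
                    state._loglik_update(dirty)

        elif prop.kind == "node_age":
            nd = prop.target
            a_old = age[nd]
            age[nd] = prop.value
            new_tp = state.tree_prior()
            delta = new_tp - state.log_tree_prior + prop.log_hastings
            if state.prior_only:
                if delta >= 0 or rand() < math.exp(delta):
                    state.log_tree_prior = new_tp
                    accepted = True
                else:
                    age[nd] = a_old
            else:
                dirty = state.ancestors_dirty((nd,))
                new_ll = state._loglik_update(dirty)
                delta += new_ll - state.loglik
                if delta >= 0 or rand() < math.exp(delta):
                    state.log_tree_prior = new_tp
                    state.loglik = new_ll
                    accepted = True
                else:
                    age[nd] = a_old
                    state._loglik_update(dirty)

        elif prop.kind == "origin":
            a_old = state.origin_age
            state.origin_age = prop.value
            new_tp = state.tree_prior()
            delta = new_tp - state.log_tree_prior + prop.log_hastings
            if delta >= 0 or rand() < math.exp(delta):
                state.log_tree_prior = new_tp
                accepted = True
            else:
                state.origin_age = a_old

        elif prop.kind == "narrow":
            x, p, u, g = prop.target
            ch = state.children

            def _swap() -> None:
                i_x = 0 if ch[p, 0] == x else 1
                i_u = 0 if ch[g, 0] == u else 1
                ch[p, i_x] = u
                ch[g, i_u] = x
                parent[x] = g
                parent[u] = p
                state.refresh_postorder()

            _swap()
            if state.prior_only:
                accepted = True  # ages unchanged: tree prior invariant
            else:
                dirty = state.ancestors_dirty((p, g))
                new_ll = state._loglik_update(dirty)
                delta = new_ll - state.loglik
                if delta >= 0 or rand() < math.exp(delta):
                    state.loglik = new_ll
                    accepted = True
                else:
                    # swap back (x and u exchanged roles)
                    x, u = u, x
                    _swap()
                    state._loglik_update(dirty)

        elif prop.kind == "param":
            name = prop.target
            old_val = getattr(state, name)
            setattr(state, name, prop.value)
            new_hp = hyperprior_terms(state.params_view(), state.priors)[name]
            delta = new_hp - state.hp_terms[name] + prop.log_hastings
            if not math.isfinite(new_hp):
                setattr(state, name, old_val)
            elif name in ("birth_rate", "death_rate", "sampling_rate"):
                new_tp = state.tree_prior()
                delta += new_tp - state.log_tree_prior
                if delta >= 0 or rand() < math.exp(delta):
                    state.hp_terms[name] = new_hp
                    state.log_tree_prior = new_tp
                    accepted = True
                else:
                    setattr(state, name, old_val)
            elif name == "clock_sd":
                nonroot = parent >= 0
                new_rmp = branch_rate_log_prior(
                    state.rate_mult[nonroot], state.clock_sd
                )
                delta += new_rmp - state.log_ratemult_prior
                if delta >= 0 or rand() < math.exp(delta):
                    state.hp_terms[name] = new_hp
                    state.log_ratemult_prior = new_rmp
                    accepted = True
                else:
                    setattr(state, name, old_val)
            elif name in ("clock_rate", "gamma_shape"):
                old_rates = state.cat_rates
                if name == "gamma_shape" and not state.prior_only:
                    # the rate mixture only feeds the likelihood
                    state.cat_rates = discrete_gamma_rates(
                        state.gamma_shape, state.ncat
                    ).rates
                if state.prior_only:
                    if delta >= 0 or rand() < math.exp(delta):
                        state.hp_terms[name] = new_hp
                        accepted = True
                    else:
                        setattr(state, name, old_val)
                        state.cat_rates = old_rates
                else:
                    dirty = state._postorder_internal
                    new_ll = state._loglik_update(dirty)
                    delta += new_ll - state.loglik
                    if delta >= 0 or rand() < math.exp(delta):
                        state.hp_terms[name] = new_hp
                        state.loglik = new_ll
                        accepted = True
                    else:
                        setattr(state, name, old_val)
                        state.cat_rates = old_rates
                        state._loglik_update(dirty)

        elif prop.kind == "rate_mult":
            nd = prop.target
            old_val = state.rate_mult[nd]
            state.rate_mult[nd] = prop.value
            # lognormal(mean 1) prior delta for this one multiplier
            sd = state.clock_sd
            mulog = -sd * sd / 2.0

            def _lp(v: float) -> float:
                z = (math.log(v) - mulog) / sd
                return -math.log(v * sd) - 0.5 * z * z

            delta = _lp(prop.value) - _lp(old_val) + prop.log_hastings
            if state.prior_only:
                if delta >= 0 or rand() < math.exp(delta):
                    state.log_ratemult_prior += _lp(prop.value) - _lp(old_val)
                    accepted = True
                else:
                    state.rate_mult[nd] = old_val
            else:
                dirty = state.ancestors_dirty((nd,))
                new_ll = state._loglik_update(dirty)
                delta += new_ll - state.loglik
                if delta >= 0 or rand() < math.exp(delta):
                    state.log_ratemult_prior += _lp(prop.value) - _lp(old_val)
                    state.loglik = new_ll
                    accepted = True
                else:
                    state.rate_mult[nd] = old_val
                    state._loglik_update(dirty)
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"unhandled proposal kind {prop.kind}")

        if accepted:
            counts[ck][1] += 1
        if gen % log_interval == 0 and row <= n_rows - 1:
            log_row(row, gen)
            row += 1

    acceptance = {k: (v[0], v[1]) for k, v in counts.items()}
    proposed = sum(v[0] for v in counts.values())
    accepted_total = sum(v[1] for v in counts.values())
    if proposed > 0 and accepted_total == 0:
        warnings.warn("all operators had acceptance rate 0", stacklevel=2)
    trace = Trace(columns, out[:row])
    return MCMCResult(trace, trees, acceptance, list(state.site_ids),
                      final_tree=state.to_dated_tree())


def sample_prior(config, data: AnalysisData, rng=None) -> MCMCResult:
    """Identical machinery with the data likelihood replaced by 1."""
    cfg = config.replace(prior_only=True)
    return run_chain(cfg, data, rng=rng)


def run_analysis(config, data: AnalysisData | None = None, rng=None,
                 base_dir=None) -> MCMCResult:
    """Load inputs (unless given), honour ``link_site_ages``, run the
    chain, and write the trace / tree log when an output prefix is set.

    With ``link_site_ages = False`` every multi-taxon site is split into
    independent per-taxon sites with the same bounds (the conventional
    independent tip-age analysis); stratigraphic relations, which are
    defined between whole sites, are dropped in that mode.
    """
    from . import io as _io
    from .datamodel import independent_sites

    if data is None:
        data = _io.load_analysis(config, base_dir=base_dir)
    if not config.link_site_ages:
        if data.seq:
            warnings.warn(
                "independent tip ages requested: stratigraphic relations "
                "are ignored", stacklevel=2,
            )
        data = AnalysisData(data.matrix, independent_sites(data.sites),
                            StratSequence(), data.tree, data.params)
    result = run_chain(config, data, rng=rng)
    if config.output_prefix:
        from pathlib import Path

        prefix = Path(config.output_prefix)
        if base_dir is not None and not prefix.is_absolute():
            prefix = Path(base_dir) / prefix
        _io.write_trace(result.trace, f"{prefix}.trace.tsv")
        if result.trees is not None:
            _io.write_tree_log(result.trees, f"{prefix}.trees.nex")
    return result
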