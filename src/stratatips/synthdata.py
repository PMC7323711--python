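"""Synthetic data: forward birth-death-sampling tree simulation, Mk
character evolution, fossil-site table construction, and the independent
rejection sampler used as the oracle for the ordering operator's
effective prior.

The default fixture emulates the empirical regime this package targets:
a couple of dozen Early Devonian fossil taxa, two multi-taxon sites whose
true ages fall inside one wide shared uncertainty window (the Lochkovian,
419.2-410.8 Ma), and a morphological matrix of ~100 binary/ternary
characters with some missing data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    MISSING, CharacterMatrix, DatedTree, FossilSite, ModelParams,
    StratSequence, validate_state,
)
from .models import discrete_gamma_rates, mk_transition_prob

LOCHKOVIAN = (410.8, 419.2)  # Ma, the motivating shared uncertainty window


# ----------------------------------------------------------------------
@dataclass
class SimulationRecipe:
    """Parameters of one forward simulation (rates per Ma)."""

    birth_rate: float = 0.45
    death_rate: float = 0.15
    sampling_rate: float = 0.2
    origin_age: float = 428.0
    stop_age: float = 406.0
    rho: float = 0.0  # extant sampling probability at stop_age
    n_tips_target: int = 20
    n_char: int = 100
    k_states: tuple[int, ...] = (2, 2, 2, 2, 3)
    gamma_shape: float = 1.0
    clock_rate: float = 0.02
    ncat: int = 4
    variable_only: bool = True
    missing_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("birth_rate", "death_rate", "sampling_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_char < 1:
            raise ValueError("n_char must be >= 1")
        if self.origin_age <= self.stop_age:
            raise ValueError("origin_age must exceed stop_age")


class _Lin:
    __slots__ = ("age", "children", "sampled")

    def __init__(self):
        self.age = None
        self.children = None
        self.sampled = False


def _simulate_once(recipe: SimulationRecipe, rng) -> DatedTree | None:
    lam, mu, psi = recipe.birth_rate, recipe.death_rate, recipe.sampling_rate
    total_rate = lam + mu + psi
    cap = max(200, 20 * recipe.n_tips_target)
    root = _Lin()
    active = [root]
    t = recipe.origin_age
    while active and t > recipe.stop_age:
        if len(active) > cap:
            return None
        if total_rate <= 0:
            break
        t -= rng.exponential(1.0 / (len(active) * total_rate))
        if t <= recipe.stop_age:
            break
        i = int(rng.integers(0, len(active)))
        active[i], active[-1] = active[-1], active[i]
        lin = active.pop()
        u = rng.random() * total_rate
        lin.age = t
        if u < lam:
            lin.children = (_Lin(), _Lin())
            active.extend(lin.children)
        elif u < lam + mu:
            pass  # extinct, unsampled leaf
        else:
            lin.sampled = True  # psi-sample, removed on sampling
    for lin in active:  # survivors at the truncation age
        lin.age = recipe.stop_age
        lin.sampled = recipe.rho > 0 and rng.random() < recipe.rho

    # prune to sampled lineages, suppressing unifurcations (iterative)
    def prune(node: _Lin) -> _Lin | None:
        stack = [(node, False)]
        result: dict[int, _Lin | None] = {}
        while stack:
            nd, done = stack.pop()
            if nd.children is None:
                result[id(nd)] = nd if nd.sampled else None
                continue
            if not done:
                stack.append((nd, True))
                stack.extend((c, False) for c in nd.children)
                continue
            kept = [result[id(c)] for c in nd.children]
            kept = [k for k in kept if k is not None]
            if len(kept) == 2:
                nd.children = tuple(kept)
                result[id(nd)] = nd
            elif len(kept) == 1:
                result[id(nd)] = kept[0]
            else:
                result[id(nd)] = None
        return result[id(node)]

    pruned = prune(root)
    if pruned is None or pruned.children is None:
        return None
    # convert to DatedTree
    parent: dict[int, int] = {}
    children: dict[int, tuple[int, ...]] = {}
    age: dict[int, float] = {}
    labels: dict[int, str] = {}
    order: list[_Lin] = []
    stack2 = [pruned]
    while stack2:
        nd = stack2.pop()
        order.append(nd)
        if nd.children:
            stack2.extend(nd.children)
    tips = [nd for nd in order if not nd.children]
    internals = [nd for nd in order if nd.children]
    ids = {id(nd): i for i, nd in enumerate(tips)}
    ids.update({id(nd): len(tips) + i for i, nd in enumerate(internals)})
    for nd in order:
        j = ids[id(nd)]
        age[j] = nd.age
        if nd.children:
            children[j] = tuple(ids[id(c)] for c in nd.children)
            for c in nd.children:
                parent[ids[id(c)]] = j
    for i, nd in enumerate(tips):
        labels[ids[id(nd)]] = f"t{i + 1:02d}"
    return DatedTree(parent, children, age, labels, ids[id(pruned)])


def simulate_bdss_tree(
    recipe: SimulationRecipe, rng=None, max_tries: int = 500
) -> DatedTree:
    """Forward birth-death simulation from the origin with Poisson
    psi-sampling (sampled lineages removed become dated fossil tips) and
    optional rho-sampling of survivors at ``stop_age``. Trees with fewer
    than 4 tips, or far outside the tip-count target, are resimulated.
    """
    if rng is None:
        rng = np.random.default_rng(recipe.seed)
    lo = max(4, int(round(0.6 * recipe.n_tips_target)))
    hi = max(lo, int(round(1.8 * recipe.n_tips_target)))
    for _ in range(max_tries):
        tree = _simulate_once(recipe, rng)
        if tree is not None and lo <= tree.n_tips <= hi:
            return tree
    raise RuntimeError(
        f"could not simulate a tree with ~{recipe.n_tips_target} tips in "
        f"{max_tries} tries; adjust the recipe rates"
    )


# ----------------------------------------------------------------------
def simulate_mk_matrix(
    tree: DatedTree,
    recipe: SimulationRecipe,
    rng=None,
    branch_rate_mult: dict[int, float] | None = None,
) -> CharacterMatrix:
    """Evolve discrete characters along the dated tree under Mk.

    Root states are uniform over each character's state space; each
    character gets one of the ``ncat`` discrete-gamma rates uniformly
    (matching the inference model's mixture exactly). With
    ``variable_only`` constant characters are resimulated, emulating the
    ascertainment regime the Mkv correction assumes. Missing data are an
    independent uniform mask.
    """
    if rng is None:
        rng = np.random.default_rng(recipe.seed)
    rates = discrete_gamma_rates(recipe.gamma_shape, recipe.ncat).rates
    mult = branch_rate_mult or {}
    pre = list(reversed(tree.postorder()))
    tips = tree.tips()
    tip_order = {t: i for i, t in enumerate(tips)}
    n_tips = len(tips)
    data = np.empty((n_tips, recipe.n_char), dtype=np.int16)
    kvec = np.empty(recipe.n_char, dtype=np.int8)
    k_choices = np.asarray(recipe.k_states, dtype=np.int8)
    blen = {
        n: (tree.age[tree.parent[n]] - tree.age[n]) * recipe.clock_rate
           * mult.get(n, 1.0)
        for n in tree.nodes if n != tree.root
    }
    for c in range(recipe.n_char):
        k = int(k_choices[rng.integers(0, k_choices.size)])
        kvec[c] = k
        for _ in range(10_000):
            rate = rates[int(rng.integers(0, rates.size))]
            pmat = {n: mk_transition_prob(k, bl * rate) for n, bl in blen.items()}
            state = {tree.root: int(rng.integers(0, k))}
            for n in pre:
                if n == tree.root:
                    continue
                p = pmat[n][state[tree.parent[n]]]
                state[n] = int(rng.choice(k, p=p))
            col = np.array([state[t] for t in tips], dtype=np.int16)
            if not recipe.variable_only or np.unique(col).size > 1:
                break
        else:
            raise RuntimeError("could not simulate a variable character")
        data[:, c] = col
    if recipe.missing_fraction > 0:
        mask = rng.random(data.shape) < recipe.missing_fraction
        # never blank out a whole character
        for c in range(recipe.n_char):
            if mask[:, c].all():
                mask[int(rng.integers(0, n_tips)), c] = False
        data[mask] = MISSING
    # rebuild per-character k from the *declared* spaces so a ternary
    # character that happened to lose state 2 keeps k=3
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return CharacterMatrix(list(tree.taxa()), data, k=kvec)


# ----------------------------------------------------------------------
def rejection_sample_site_ages(
    sites: list[FossilSite],
    seq: StratSequence,
    n: int,
    rng=None,
    min_acceptance: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Oracle for the effective prior under stratigraphic ordering: draw
    each site age independently Uniform(min, max) and keep the joint draw
    iff every (lower, upper) relation satisfies lower >= upper.

    This shares no code with the MCMC operators; a correct chain must
    reproduce these marginals.
    """
    if rng is None:
        rng = np.random.default_rng()
    ids = [s.site_id for s in sites]
    idx = {sid: i for i, sid in enumerate(ids)}
    lo = np.array([s.min_age for s in sites])
    hi = np.array([s.max_age for s in sites])
    rel = np.array(
        [(idx[a], idx[b]) for a, b in seq.relations], dtype=np.int64
    ).reshape(-1, 2)
    out = np.empty((0, len(sites)))
    tried = 0
    while out.shape[0] < n:
        batch = max(4096, n)
        draws = lo + (hi - lo) * rng.random((batch, len(sites)))
        tried += batch
        if rel.shape[0]:
            ok = np.all(draws[:, rel[:, 0]] >= draws[:, rel[:, 1]], axis=1)
            draws = draws[ok]
        out = np.vstack([out, draws])
        if tried >= 100_000 and out.shape[0] / tried < min_acceptance:
            raise RuntimeError(
                "rejection sampler acceptance below 1e-6: incompatible "
                "bounds/ordering"
            )
    out = out[:n]
    return {sid: out[:, i].copy() for i, sid in enumerate(ids)}


# ----------------------------------------------------------------------
@dataclass
class FixtureDataset:
    """A complete synthetic analysis: truth plus on-disk inputs."""

    tree: DatedTree
    matrix: CharacterMatrix
    sites: list[FossilSite]
    seq: StratSequence
    params_true: ModelParams
    multi_sites: tuple[str, str]  # (older site id, younger site id)
    site_ages_true: dict[str, float]
    paths: dict[str, Path] = field(default_factory=dict)


def make_fixture_dataset(
    seed: int,
    out_dir=None,
    n_tips_target: int = 20,
    n_char: int = 100,
    site_size: int = 4,
    ordered: bool = False,
    clock_rate: float = 0.02,
    relaxed_sd: float = 0.1,
) -> FixtureDataset:
    """Deterministic per-seed synthetic scenario: two multi-taxon fossil
    sites whose (linked) true ages fall inside the shared Lochkovian
    window, remaining taxa dated individually with narrow windows.

    With ``ordered`` a stratigraphic relation (older site below younger
    site) is included. Files (NEXUS matrix, TSV site table, config) are
    written when ``out_dir`` is given.
    """
    rng = np.random.default_rng(seed)
    recipe = SimulationRecipe(
        n_tips_target=n_tips_target, n_char=n_char, clock_rate=clock_rate
    )
    lo_b, hi_b = LOCHKOVIAN
    margin = 0.3
    for _ in range(500):
        tree = simulate_bdss_tree(recipe, rng)
        a_old = 412.5 + 4.0 * rng.random()
        delta = 1.5 + (min(4.0, a_old - (lo_b + 0.5)) - 1.5) * rng.random()
        a_young = a_old - delta
        tips = tree.tips()
        cand_old = [t for t in tips
                    if tree.age[tree.parent[t]] > a_old + margin]
        if len(cand_old) < site_size:
            continue
        old_tips = [cand_old[i] for i in
                    rng.choice(len(cand_old), site_size, replace=False)]
        cand_young = [t for t in tips if t not in old_tips
                      and tree.age[tree.parent[t]] > a_young + margin]
        if len(cand_young) < site_size:
            continue
        young_tips = [cand_young[i] for i in
                      rng.choice(len(cand_young), site_size, replace=False)]
        for t in old_tips:
            tree.age[t] = a_old
        for t in young_tips:
            tree.age[t] = a_young
        break
    else:
        raise RuntimeError("could not construct a fixture tree")

    sites = [
        FossilSite("site_lower", tuple(tree.labels[t] for t in old_tips),
                   lo_b, hi_b, a_old),
        FossilSite("site_upper", tuple(tree.labels[t] for t in young_tips),
                   lo_b, hi_b, a_young),
    ]
    placed = set(old_tips) | set(young_tips)
    for t in tree.tips():
        if t not in placed:
            a = tree.age[t]
            w = 0.5 + rng.random()
            sites.append(
                FossilSite(tree.labels[t], (tree.labels[t],),
                           a - w, a + w, a)
            )
    seq = StratSequence([("site_lower", "site_upper")] if ordered else [])

    mult = {
        n: float(rng.lognormal(-relaxed_sd ** 2 / 2.0, relaxed_sd))
        for n in tree.nodes if n != tree.root
    } if relaxed_sd > 0 else {}
    matrix = simulate_mk_matrix(tree, recipe, rng, branch_rate_mult=mult)
    params_true = ModelParams(
        clock_rate=clock_rate, clock_sd=max(relaxed_sd, 1e-3),
        gamma_shape=recipe.gamma_shape, birth_rate=recipe.birth_rate,
        death_rate=recipe.death_rate, sampling_rate=recipe.sampling_rate,
        origin_age=recipe.origin_age, branch_rate_mult=mult,
    )
    problems = validate_state(tree, sites, seq, params_true)
    if problems:  # pragma: no cover - construction guarantees this
        raise RuntimeError("fixture failed validation: "
                           + "; ".join(map(str, problems)))

    fixture = FixtureDataset(
        tree=tree, matrix=matrix, sites=sites, seq=seq,
        params_true=params_true,
        multi_sites=("site_lower", "site_upper"),
        site_ages_true={"site_lower": a_old, "site_upper": a_young},
    )
    if out_dir is not None:
        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": out / "matrix.nex",
            "site_table": out / "sites.tsv",
            "config": out / "config.txt",
        }
        _io.write_nexus_matrix(matrix, paths["matrix"])
        _io.write_site_table(sites, seq, paths["site_table"])
        cfg = _io.AnalysisConfig(
            matrix="matrix.nex", site_table="sites.tsv",
            output_prefix="run", chain_length=200_000, log_interval=100,
            seed=seed,
        )
        _io.write_config(cfg, paths["config"])
        fixture.paths = paths
    return fixture
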