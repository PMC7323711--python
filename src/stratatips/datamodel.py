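"""Core state types for tip-dating analyses.

All ages are in Ma (million years) before present, increasing into the past:
"younger" always means numerically *smaller*. Trees are strictly binary and
rooted; fossil taxa are terminal tips with non-zero ages (no sampled
ancestors / zero-length terminal branches).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel for a missing (``?`` / ``-``) character state.
MISSING: int = -1


@dataclass(frozen=True)
class Violation:
    """One violated invariant, with enough context to locate it."""

    code: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.code}] {self.detail}"


class DatedTree:
    """Rooted, strictly binary tree with an age (Ma) at every node.

    Node ids are small integers. Tips carry unique, non-empty taxon labels.
    The structural invariants (single root, binary internals, strictly
    decreasing ages toward the tips, unique labels) are checked on
    construction unless ``validate=False``.
    """

    __slots__ = ("parent", "children", "age", "labels", "root")

    def __init__(
        self,
        parent: Mapping[int, int],
        children: Mapping[int, tuple[int, ...]],
        age: Mapping[int, float],
        labels: Mapping[int, str],
        root: int,
        validate: bool = True,
    ) -> None:
        self.parent = dict(parent)
        self.children = {n: tuple(c) for n, c in children.items()}
        self.age = {n: float(a) for n, a in age.items()}
        self.labels = dict(labels)
        self.root = root
        if validate:
            problems = self.check()
            if problems:
                raise ValueError(
                    "invalid DatedTree: " + "; ".join(str(p) for p in problems)
                )

    # ------------------------------------------------------------------
    @property
    def nodes(self) -> list[int]:
        return list(self.age)

    def tips(self) -> list[int]:
        return [n for n in self.age if not self.children.get(n)]

    def internals(self) -> list[int]:
        return [n for n in self.age if self.children.get(n)]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def taxa(self) -> list[str]:
        return [self.labels[t] for t in self.tips()]

    def tip_by_label(self) -> dict[str, int]:
        return {self.labels[t]: t for t in self.tips()}

    def postorder(self) -> list[int]:
        """Children-before-parents node order (iterative)."""
        out: list[int] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children.get(n, ()))
        out.reverse()
        return out

    def copy(self) -> "DatedTree":
        return DatedTree(
            self.parent, self.children, self.age, self.labels, self.root,
            validate=False,
        )

    def clades(self) -> set[frozenset[str]]:
        """Tip-label set of every internal node (for topology comparison)."""
        below: dict[int, frozenset[str]] = {}
        out: set[frozenset[str]] = set()
        for n in self.postorder():
            kids = self.children.get(n)
            if not kids:
                below[n] = frozenset([self.labels[n]])
            else:
                below[n] = frozenset().union(*(below[c] for c in kids))
                out.add(below[n])
        return out

    # ------------------------------------------------------------------
    def check(self) -> list[Violation]:
        """Return every violated structural invariant (empty if valid)."""
        v: list[Violation] = []
        nodes = set(self.age)
        if self.root not in nodes:
            return [Violation("tree-root", f"root {self.root} is not a node")]
        for n in nodes:
            if n == self.root:
                if n in self.parent:
                    v.append(Violation("tree-root", "root has a parent"))
                continue
            if n not in self.parent:
                v.append(Violation("tree-parent", f"node {n} has no parent"))
        for n, kids in self.children.items():
            if kids and len(kids) != 2:
                v.append(
                    Violation("tree-binary", f"node {n} has {len(kids)} children")
                )
            for c in kids:
                if self.parent.get(c) != n:
                    v.append(
                        Violation("tree-parent", f"child {c} of {n} disagrees")
                    )
        for n, p in self.parent.items():
            if p in self.age and n in self.age:
                if not self.age[p] > self.age[n]:
                    v.append(
                        Violation(
                            "tree-ages",
                            f"age(parent {p})={self.age[p]} !> age({n})={self.age[n]}",
                        )
                    )
        seen: set[str] = set()
        for t in self.tips():
            lab = self.labels.get(t, "")
            if not lab:
                v.append(Violation("tree-labels", f"tip {t} has empty label"))
            elif lab in seen:
                v.append(Violation("tree-labels", f"duplicate tip label {lab!r}"))
            seen.add(lab)
        # reachability: every node reachable from root exactly once
        if not v:
            reached = set(self.postorder())
            if reached != nodes:
                v.append(
                    Violation(
                        "tree-connectivity",
                        f"{len(nodes - reached)} node(s) unreachable from root",
                    )
                )
        return v


def branch_duration(tree: DatedTree, node: int) -> float:
    """Duration (Ma) of the branch subtending ``node``: age(parent) − age(node)."""
    if node == tree.root:
        raise ValueError("root has no branch")
    return tree.age[tree.parent[node]] - tree.age[node]


def tree_length(tree: DatedTree) -> float:
    """Sum of all branch durations (Ma)."""
    return sum(branch_duration(tree, n) for n in tree.nodes if n != tree.root)


# ----------------------------------------------------------------------
class CharacterMatrix:
    """Taxa x discrete morphological characters.

    ``data`` holds non-negative integer states with :data:`MISSING` for
    unobservable cells. Each character carries ``k`` >= 2, the size of its
    state space; by default this is computed from the observed states only
    (max observed state + 1, floored at 2 — a character seen in a single
    state still needs a two-state space under the Mk family).
    """

    def __init__(
        self,
        taxa: Sequence[str],
        data: np.ndarray,
        k: Sequence[int] | None = None,
    ) -> None:
        self.taxa = list(taxa)
        self.data = np.asarray(data, dtype=np.int16)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be (n_taxa, n_char)")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon label(s): {', '.join(dup)}")
        n_char = self.data.shape[1]
        observed_max = np.full(n_char, -1, dtype=int)
        for c in range(n_char):
            col = self.data[:, c]
            obs = col[col != MISSING]
            if obs.size == 0:
                raise ValueError(f"character {c} has no observed states")
            if obs.min() < 0:
                raise ValueError(f"character {c} has negative states")
            observed_max[c] = int(obs.max())
            if np.unique(obs).size < 2:
                warnings.warn(
                    f"character {c} observed in fewer than 2 states; "
                    "treating as binary (k=2)",
                    stacklevel=2,
                )
        if k is None:
            self.k = np.maximum(observed_max + 1, 2).astype(np.int8)
        else:
            self.k = np.asarray(k, dtype=np.int8)
            if self.k.shape != (n_char,):
                raise ValueError("k must have one entry per character")
            if np.any(self.k < 2):
                raise ValueError("every character needs k >= 2")
            if np.any(observed_max >= self.k):
                bad = int(np.nonzero(observed_max >= self.k)[0][0])
                raise ValueError(f"character {bad} has a state >= its k")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]


# ----------------------------------------------------------------------
@dataclass
class FossilSite:
    """A set of tips sharing one age parameter with uniform bounds (Ma)."""

    site_id: str
    taxa: tuple[str, ...]
    min_age: float
    max_age: float
    age: float

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if not self.taxa:
            raise ValueError(f"site {self.site_id} lists no taxa")
        if not self.min_age <= self.max_age:
            raise ValueError(
                f"site {self.site_id}: min_age {self.min_age} > max_age {self.max_age}"
            )
        if not self.min_age <= self.age <= self.max_age:
            raise ValueError(
                f"site {self.site_id}: age {self.age} outside "
                f"[{self.min_age}, {self.max_age}]"
            )


@dataclass
class StratSequence:
    """Partial order over fossil sites: (lower, upper) = lower lies below.

    A lower (stratigraphically deeper) site must never be strictly younger
    than a site above it; equal sampled ages are allowed.
    """

    relations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.relations = [(str(a), str(b)) for a, b in self.relations]
        self.check_acyclic()

    def check_acyclic(self) -> None:
        ts: TopologicalSorter = TopologicalSorter()
        for lower, upper in self.relations:
            ts.add(upper, lower)
        try:
            ts.prepare()
        except CycleError as err:
            raise ValueError("cyclic stratigraphic sequence") from err

    def site_ids(self) -> set[str]:
        out: set[str] = set()
        for lower, upper in self.relations:
            out.update((lower, upper))
        return out

    def below_of(self, site_id: str) -> list[str]:
        """Sites immediately below (older side of) ``site_id``."""
        return [lo for lo, up in self.relations if up == site_id]

    def above_of(self, site_id: str) -> list[str]:
        """Sites immediately above (younger side of) ``site_id``."""
        return [up for lo, up in self.relations if lo == site_id]

    def __bool__(self) -> bool:
        return bool(self.relations)


# ----------------------------------------------------------------------
@dataclass
class ModelParams:
    """Every free scalar parameter of the model stack.

    ``clock_rate`` is in substitutions/character/Ma; ``branch_rate_mult``
    maps each non-root node to the lognormal rate multiplier of the branch
    above it (uncorrelated relaxed clock).
    """

    clock_rate: float = 0.0046
    clock_sd: float = 0.5
    gamma_shape: float = 1.0
    birth_rate: float = 0.14
    death_rate: float = 0.1
    sampling_rate: float = 0.03
    origin_age: float = 0.0
    branch_rate_mult: dict[int, float] = field(default_factory=dict)

    def check(self, tree: DatedTree | None = None) -> list[Violation]:
        v: list[Violation] = []
        for name in ("clock_rate", "clock_sd", "gamma_shape",
                     "birth_rate", "death_rate", "sampling_rate"):
            if not getattr(self, name) > 0:
                v.append(Violation("params-positive", f"{name} must be > 0"))
        for node, m in self.branch_rate_mult.items():
            if not m > 0:
                v.append(
                    Violation("params-positive",
                              f"branch rate multiplier at node {node} must be > 0")
                )
        if tree is not None and not self.origin_age > tree.age[tree.root]:
            v.append(
                Violation(
                    "params-origin",
                    f"origin_age {self.origin_age} must exceed root age "
                    f"{tree.age[tree.root]}",
                )
            )
        return v


# ----------------------------------------------------------------------
def independent_sites(sites: Iterable[FossilSite]) -> list[FossilSite]:
    """Split every site into per-taxon single-taxon sites (same bounds).

    This is the conventional independent-tip-ages analysis mode; linked
    multi-taxon sites reduce to it when each taxon is its own site.
    """
    out: list[FossilSite] = []
    for s in sites:
        if len(s.taxa) == 1 and s.site_id == s.taxa[0]:
            out.append(s)
            continue
        for taxon in s.taxa:
            out.append(FossilSite(taxon, (taxon,), s.min_age, s.max_age, s.age))
    return out


# ----------------------------------------------------------------------
def validate_state(
    tree: DatedTree,
    sites: Iterable[FossilSite],
    seq: StratSequence | None = None,
    params: ModelParams | None = None,
) -> list[Violation]:
    """Diagnose a full chain state; returns every violation, never raises.

    Beyond the per-type invariants this checks that every site's tips share
    the site's current age and that no stratigraphic relation is inverted
    (a lower site strictly younger than one above it).
    """
    v = list(tree.check())
    sites = list(sites)
    tip_ages = {tree.labels[t]: tree.age[t] for t in tree.tips()}

    by_id: dict[str, FossilSite] = {}
    owner: dict[str, str] = {}
    for s in sites:
        if s.site_id in by_id:
            v.append(Violation("site-duplicate", f"site id {s.site_id} repeated"))
        by_id[s.site_id] = s
        if not s.min_age <= s.age <= s.max_age:
            v.append(
                Violation("site-bounds",
                          f"site {s.site_id} age {s.age} outside bounds")
            )
        for taxon in s.taxa:
            if taxon in owner:
                v.append(
                    Violation("site-membership",
                              f"taxon {taxon} in sites {owner[taxon]} and {s.site_id}")
                )
            owner[taxon] = s.site_id
            if taxon not in tip_ages:
                v.append(
                    Violation("site-membership",
                              f"site {s.site_id} taxon {taxon} is not a tip")
                )
            elif abs(tip_ages[taxon] - s.age) > 1e-9:
                v.append(
                    Violation(
                        "site-age-desync",
                        f"site {s.site_id} age {s.age} but tip {taxon} at "
                        f"{tip_ages[taxon]}",
                    )
                )

    if seq is not None:
        for lower, upper in seq.relations:
            if lower not in by_id or upper not in by_id:
                v.append(
                    Violation("ordering",
                              f"relation ({lower} below {upper}) names an "
                              "unregistered site")
                )
                continue
            if by_id[lower].age < by_id[upper].age - 1e-12:
                v.append(
                    Violation(
                        "ordering",
                        f"site {lower} (below, age {by_id[lower].age}) younger "
                        f"than {upper} (above, age {by_id[upper].age})",
                    )
                )

    if params is not None:
        v.extend(params.check(tree))
    return v
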