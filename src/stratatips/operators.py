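"""MCMC proposals.

The two site operators are the point of this package:

* :func:`propose_linked_site_age` draws one new age uniformly within a
  fossil site's bounds and applies it to *all* tips of the site at once,
  so fossils from one locality can never drift apart in age.
* :func:`propose_ordered_site_age` additionally hard-rejects any draw that
  would strictly invert a stratigraphic relation (a lower site younger
  than a site above it), given the *current* ages of the neighbouring
  sites. The acceptable window therefore moves as the chain runs, which
  induces a non-uniform effective prior on each site's age.

A hard-rejected proposal is counted as a rejection without evaluating the
posterior — equivalent to assigning the proposed state prior probability
zero. Both site moves draw from the full uniform bounds and are symmetric
(log-Hastings 0).

The standard moves (node slides, root/origin offset scales, narrow
exchange, scalar scale moves, branch-rate walk) are conventional plumbing
needed for a functioning chain; scale moves draw the factor f uniformly on
[1/beta, beta] and carry log-Hastings -log f.

Operators take the sampler's flat state (:class:`stratatips.mcmc.ChainState`)
and return a :class:`Proposal`; the driver applies, scores and possibly
reverts it.
"""
from __future__ import annotations

import math


class Proposal:
    """One proposed state change.

    ``kind`` selects the apply/revert recipe in the driver; ``target`` and
    ``value`` carry the change; ``hard_reject`` marks a proposal that is
    rejected outright (state must remain unchanged).
    """

    __slots__ = ("kind", "target", "value", "log_hastings", "hard_reject")

    def __init__(self, kind, target=None, value=None, log_hastings=0.0,
                 hard_reject=False):
        self.kind = kind
        self.target = target
        self.value = value
        self.log_hastings = log_hastings
        self.hard_reject = hard_reject

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Proposal({self.kind!r}, target={self.target!r}, "
                f"value={self.value!r}, logH={self.log_hastings:.3g}, "
                f"hard_reject={self.hard_reject})")


# ----------------------------------------------------------------------
# Novel site-age proposals
# ----------------------------------------------------------------------
def propose_linked_site_age(state, site: int, rng) -> Proposal:
    """Uniform redraw of one site's age, applied to every tip in the site.

    Hard-rejects when any member tip would become as old as (or older
    than) its parent node.
    """
    lo = state.site_min[site]
    hi = state.site_max[site]
    a = lo if lo == hi else lo + (hi - lo) * rng.random()
    for tip in state.site_tips[site]:
        if a >= state.age[state.parent[tip]]:
            return Proposal("site_age", site, a, hard_reject=True)
    return Proposal("site_age", site, a)


def propose_ordered_site_age(state, site: int, rng) -> Proposal:
    """As :func:`propose_linked_site_age`, with stratigraphic rejection.

    A draw is additionally hard-rejected when it is strictly older than a
    site below, or strictly younger than a site above, at those sites'
    current ages. Exact ties are allowed (they violate nothing and have
    measure zero under the continuous draw).
    """
    prop = propose_linked_site_age(state, site, rng)
    if prop.hard_reject:
        return prop
    a = prop.value
    for b in state.site_below[site]:
        if a > state.site_age[b]:
            prop.hard_reject = True
            return prop
    for u in state.site_above[site]:
        if a < state.site_age[u]:
            prop.hard_reject = True
            return prop
    return prop


# ----------------------------------------------------------------------
# Standard proposals
# ----------------------------------------------------------------------
def _scale_factor(rng, beta: float) -> float:
    """f ~ Uniform(1/beta, beta); univariate scale log-Hastings is -log f."""
    return 1.0 / beta + (beta - 1.0 / beta) * rng.random()


def propose_node_slide(state, node: int, rng) -> Proposal:
    """Uniform slide of an internal (non-root) node age between its oldest
    child and its parent; the window does not depend on the node's own
    age, so the move is symmetric."""
    c0, c1 = state.children[node]
    lo = max(state.age[c0], state.age[c1])
    hi = state.age[state.parent[node]]
    a = lo + (hi - lo) * rng.random()
    if a <= lo or a >= hi:  # float degenerate draw
        return Proposal("node_age", node, a, hard_reject=True)
    return Proposal("node_age", node, a)


def propose_root_offset_scale(state, rng, beta: float = 2.0) -> Proposal:
    """Scale the root's offset above its oldest child by f in [1/beta, beta].

    Hard-rejects when the new root age would reach the origin.
    """
    root = state.root
    c0, c1 = state.children[root]
    base = max(state.age[c0], state.age[c1])
    f = _scale_factor(rng, beta)
    a = base + (state.age[root] - base) * f
    if a >= state.origin_age or a <= base:
        return Proposal("node_age", root, a, hard_reject=True)
    return Proposal("node_age", root, a, log_hastings=-math.log(f))


def propose_origin_offset_scale(state, rng, beta: float = 2.0) -> Proposal:
    """Scale the origin's offset above the root by f in [1/beta, beta]."""
    base = state.age[state.root]
    f = _scale_factor(rng, beta)
    a = base + (state.origin_age - base) * f
    if a <= base:
        return Proposal("origin", None, a, hard_reject=True)
    return Proposal("origin", None, a, log_hastings=-math.log(f))


def propose_narrow_exchange(state, rng) -> Proposal:
    """Swap a node with its uncle (the sibling of its parent).

    Picks a uniform node whose parent is not the root; hard-rejects when
    the uncle is as old as the chosen node's parent (the swap would break
    the age ordering). Selection is symmetric, so log-Hastings is 0.
    """
    n_nodes = state.age.shape[0]
    for _ in range(8):
        x = int(rng.integers(0, n_nodes))
        if x == state.root:
            continue
        p = state.parent[x]
        if p == state.root:
            continue
        g = state.parent[p]
        gc0, gc1 = state.children[g]
        u = gc1 if gc0 == p else gc0
        if state.age[u] >= state.age[p]:
            return Proposal("narrow", (x, p, u, g), None, hard_reject=True)
        return Proposal("narrow", (x, p, u, g), None)
    return Proposal("narrow", None, None, hard_reject=True)


def propose_param_scale(state, name: str, rng, beta: float = 1.5) -> Proposal:
    """Multiplicative scale move on one positive scalar parameter."""
    f = _scale_factor(rng, beta)
    return Proposal("param", name, getattr(state, name) * f,
                    log_hastings=-math.log(f))


def propose_bounded_walk(state, name: str, lo: float, hi: float, rng,
                         window: float = 2.0) -> Proposal:
    """Reflected uniform random walk for a parameter with a bounded
    uniform prior (a multiplicative scale move mixes badly near 0 on a
    bounded support). Reflection keeps the move symmetric: log-Hastings 0."""
    x = getattr(state, name) + (2.0 * rng.random() - 1.0) * window
    span = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        else:
            x = 2.0 * hi - x
        if span <= 0:  # pragma: no cover - degenerate bounds
            return Proposal("param", name, lo, hard_reject=True)
    return Proposal("param", name, x)


def propose_rate_mult_scale(state, node: int, rng, beta: float = 1.5) -> Proposal:
    """Multiplicative random walk on one branch-rate multiplier."""
    f = _scale_factor(rng, beta)
    return Proposal("rate_mult", node, state.rate_mult[node] * f,
                    log_hastings=-math.log(f))


_STANDARD_KINDS = (
    "node_slide", "root", "origin", "narrow", "clock_rate", "clock_sd",
    "gamma_shape", "birth_rate", "death_rate", "sampling_rate", "rate_mult",
)


def standard_proposals(state, rng, kind: str | None = None) -> Proposal:
    """Draw one standard proposal (uniformly over kinds unless given)."""
    if kind is None:
        kind = _STANDARD_KINDS[int(rng.integers(0, len(_STANDARD_KINDS)))]
    if kind == "node_slide":
        internals = state.internal_nonroot
        if internals.size == 0:
            return Proposal("node_age", None, None, hard_reject=True)
        node = int(internals[rng.integers(0, internals.size)])
        return propose_node_slide(state, node, rng)
    if kind == "root":
        return propose_root_offset_scale(state, rng)
    if kind == "origin":
        return propose_origin_offset_scale(state, rng)
    if kind == "narrow":
        return propose_narrow_exchange(state, rng)
    if kind == "rate_mult":
        node = int(rng.integers(0, state.age.shape[0]))
        if node == state.root:
            return Proposal("rate_mult", node, None, hard_reject=True)
        return propose_rate_mult_scale(state, node, rng)
    if kind == "gamma_shape":
        return propose_bounded_walk(state, kind, 0.0, state.priors.shape_max,
                                    rng)
    if kind in ("clock_rate", "clock_sd", "birth_rate",
                "death_rate", "sampling_rate"):
        return propose_param_scale(state, kind, rng)
    raise ValueError(f"unknown standard proposal kind {kind!r}")
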