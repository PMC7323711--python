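import numpy as np
import pytest

from stratatips.datamodel import CharacterMatrix, DatedTree, FossilSite, StratSequence

LOCH_LO, LOCH_HI = 410.8, 419.2


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def two_tip_tree():
    """((a, b)) with tip ages 0 and total path length 1.0."""
    return DatedTree(
        parent={0: 2, 1: 2}, children={2: (0, 1)},
        age={0: 0.0, 1: 0.0, 2: 0.5}, labels={0: "a", 1: "b"}, root=2,
    )


@pytest.fixture
def three_tip_tree():
    return DatedTree(
        parent={0: 3, 1: 3, 2: 4, 3: 4}, children={3: (0, 1), 4: (3, 2)},
        age={0: 1.0, 1: 2.0, 2: 3.5, 3: 4.0, 4: 6.0},
        labels={0: "a", 1: "b", 2: "c"}, root=4,
    )


@pytest.fixture
def four_tip_fossil_tree():
    """Four dated fossil tips, parents comfortably older than the
    Lochkovian window so site-age moves are never truncated."""
    return DatedTree(
        parent={0: 4, 1: 4, 2: 5, 3: 6, 4: 5, 5: 6},
        children={4: (0, 1), 5: (4, 2), 6: (5, 3)},
        age={0: 415.0, 1: 415.0, 2: 413.0, 3: 412.0,
             4: 425.0, 5: 430.0, 6: 436.0},
        labels={0: "a", 1: "b", 2: "c", 3: "d"}, root=6,
    )


@pytest.fixture
def lochkovian_pair():
    """Two fossil sites sharing the Lochkovian uncertainty window, the
    first stratigraphically below (older side of) the second."""
    s_lower = FossilSite("lower", ("a", "b"), LOCH_LO, LOCH_HI, 415.0)
    s_upper = FossilSite("upper", ("c",), LOCH_LO, LOCH_HI, 415.0)
    return [s_lower, s_upper], StratSequence([("lower", "upper")])


def random_dated_tree(rng, n_tips, age_lo=0.0, age_hi=5.0):
    """Random binary dated tree built by successive joins (test helper)."""
    ages = {i: float(a) for i, a in
            enumerate(np.sort(rng.uniform(age_lo, age_hi, n_tips)))}
    labels = {i: f"t{i}" for i in range(n_tips)}
    parent, children = {}, {}
    active = list(range(n_tips))
    tau = max(ages.values())
    nxt = n_tips
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[int(i)], active[int(j)]
        active = [x for x in active if x not in (a, b)]
        tau = max(tau, ages[a], ages[b]) + float(rng.exponential(1.0)) + 1e-3
        ages[nxt] = tau
        children[nxt] = (a, b)
        parent[a] = nxt
        parent[b] = nxt
        active.append(nxt)
        nxt += 1
    return DatedTree(parent, children, ages, labels, active[0])


def random_matrix(rng, taxa, n_char, k_max=3, missing_p=0.2):
    ks = rng.integers(2, k_max + 1, n_char)
    data = np.empty((len(taxa), n_char), dtype=np.int16)
    for c in range(n_char):
        data[:, c] = rng.integers(0, ks[c], len(taxa))
        mask = rng.random(len(taxa)) < missing_p
        if mask.all():
            mask[0] = False
        data[mask, c] = -1
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CharacterMatrix(list(taxa), data, k=ks)
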