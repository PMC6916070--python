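"""Shared fixtures: hand-built histories and an independent layout oracle."""

import itertools

import numpy as np
import pytest

from mullerkit import CloneHistory, SimulationParams, simulate_clonal_dynamics


@pytest.fixture
def two_clone_history():
    """A=[10,8,6] with child B=[0,2,4] over times 0,1,2 (size scale)."""
    return CloneHistory(
        clone_ids=["A", "B"],
        parent_of={"A": None, "B": "A"},
        times=[0, 1, 2],
        sizes=[[10, 8, 6], [0, 2, 4]],
    )


@pytest.fixture
def chain_history():
    """A -> B -> C chain over 3 times, with B and C small."""
    return CloneHistory(
        clone_ids=["A", "B", "C"],
        parent_of={"A": None, "B": "A", "C": "B"},
        times=[0, 1, 2],
        sizes=[[10.0, 6.0, 5.0], [0.0, 3.0, 2.5], [0.0, 1.0, 0.5]],
    )


def simulated(seed, **overrides):
    params = SimulationParams(seed=seed, **overrides)
    return simulate_clonal_dynamics(params)


@pytest.fixture
def simulated_history():
    return simulated(42)


# -- independent brute-force layout oracle --------------------------------


def oracle_bands(history, order, root_gap=0.0):
    """Half-split layout via a flat cumulative-sum enumeration.

    Walks the canonical order and emits, per clone, a half-entry of its own
    mass before its children and another after; cumulative sums of that flat
    sequence give every clone's band boundaries.  Entirely independent of
    the recursive placement in mullerkit.layout.
    """
    idx = {c: i for i, c in enumerate(history.clone_ids)}
    children = {c: [d for d in order if history.parent_of.get(d) == c] for c in order}
    entries = []  # (clone, which_half) in flat vertical order

    def walk(c):
        entries.append((c, "lo"))
        for d in children[c]:
            walk(d)
        entries.append((c, "hi"))

    roots = [c for c in order if history.parent_of.get(c) is None]
    bands = {}
    n_t = history.n_times
    base = np.zeros(n_t)
    for r in roots:
        entries = []
        walk(r)
        cursor = base.copy()
        lowers, uppers = {}, {}
        for c, half in entries:
            if half == "lo":
                lowers[c] = cursor.copy()
            cursor = cursor + history.sizes[idx[c]] / 2.0
            if half == "hi":
                uppers[c] = cursor.copy()
        for c in lowers:
            bands[c] = (lowers[c], uppers[c])
        base = cursor + root_gap
    return bands


def enumerate_forests(n):
    """All labeled forests on clones c0..c{n-1} as parent maps."""
    ids = [f"c{i}" for i in range(n)]
    options = [[None] + [p for p in ids if p != c] for c in ids]
    for combo in itertools.product(*options):
        parent = dict(zip(ids, combo))
        # acyclic check by walking each parent chain
        ok = True
        for c in ids:
            seen = set()
            node = c
            while node is not None:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = parent[node]
            if not ok:
                break
        if ok:
            yield ids, parent
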