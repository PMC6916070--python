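"""Synthetic clonal dynamics: a seeded branching-logistic test-data engine.

A single founding clone grows under a discrete logistic map and stochastically
spawns mutant children; each child inherits its parent's fitness scaled by a
log-normal effect.  The generator produces the wedge-shaped clonal sweeps that
Muller plots are designed to display, with unambiguous origin times (every
mutant is seeded with exactly one individual).  It is a test-data engine, not
a faithful tumor-evolution model.

:func:`make_parser_fixtures` re-encodes any frequency-scale history in all
three reconstruction-tool dialects so the parsers can be exercised round-trip
without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dotio
from .core import FREQUENCY, SIZE, CloneHistory, to_long
from .errors import ParameterError
from .layout import subtree_sizes

__all__ = ["SimulationParams", "simulate_clonal_dynamics", "make_parser_fixtures"]

#: intrinsic per-step growth rate of the logistic map (fixed)
GROWTH_RATE = 0.5


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the branching-logistic generator.

    n_steps
        Number of recorded time steps (>= 2).
    carrying_capacity
        Logistic carrying capacity K (individuals).
    mutation_rate
        Per-clone, per-step probability of spawning one mutant child.
    fitness_effect_sd
        Standard deviation of the log-normal fitness effect; each child's
        fitness is parent fitness x exp(Normal(0, sd)).
    initial_size
        Founding clone size at step 0 (individuals).
    seed
        RNG seed; identical seeds give identical histories.
    """

    n_steps: int = 30
    carrying_capacity: float = 1000.0
    mutation_rate: float = 0.05
    fitness_effect_sd: float = 0.2
    initial_size: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ParameterError("n_steps must be >= 2")
        if self.carrying_capacity <= 0:
            raise ParameterError("carrying_capacity must be positive")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ParameterError("mutation_rate must be in [0, 1]")
        if self.fitness_effect_sd < 0:
            raise ParameterError("fitness_effect_sd must be non-negative")
        if self.initial_size <= 0:
            raise ParameterError("initial_size must be positive")


def simulate_clonal_dynamics(params: SimulationParams) -> CloneHistory:
    """Simulate a clone history under branching logistic growth.

    Each step, every clone's size is updated by
    ``n' = n * exp(r * fitness * (1 - N / K))`` with ``r = 0.5`` and ``N`` the
    total population; then every clone of size >= 1 spawns a child with
    probability ``mutation_rate``, seeded with 1 individual and fitness equal
    to the parent's times a log-normal effect.  Sizes are recorded at every
    step; the output carries a per-clone ``fitness`` attribute and always
    passes validation.
    """
    rng = np.random.default_rng(params.seed)
    clone_ids = ["c0"]
    parent_of: dict[str, str | None] = {"c0": None}
    fitness = {"c0": 1.0}
    sizes = [[float(params.initial_size)]]  # per clone, growing trajectories
    current = np.array([float(params.initial_size)])

    for _step in range(1, params.n_steps):
        total = current.sum()
        factor = np.exp(
            GROWTH_RATE
            * np.array([fitness[c] for c in clone_ids])
            * (1.0 - total / params.carrying_capacity)
        )
        current = current * factor

        n_before = len(clone_ids)
        for i in range(n_before):
            if current[i] >= 1.0 and rng.random() < params.mutation_rate:
                child = f"c{len(clone_ids)}"
                clone_ids.append(child)
                parent_of[child] = clone_ids[i]
                fitness[child] = fitness[clone_ids[i]] * float(
                    np.exp(rng.normal(0.0, params.fitness_effect_sd))
                )
                sizes.append([0.0] * (_step))
                current = np.append(current, 1.0)

        for i, c in enumerate(clone_ids):
            sizes[i].append(float(current[i]))

    mat = np.array(sizes)
    return CloneHistory(
        clone_ids=clone_ids,
        parent_of=parent_of,
        times=np.arange(params.n_steps, dtype=float),
        sizes=mat,
        scale=SIZE,
        attributes={"fitness": dict(fitness)},
    )


def make_parser_fixtures(history: CloneHistory, out_dir) -> dict[str, Path]:
    """Write a frequency-scale history in all three parser dialects.

    Produces ``phylowgs_summ.json`` (cumulative prevalences, so the
    parser's prevalence-minus-children conversion reproduces the input),
    ``calder_proportions.csv`` + ``calder_tree.dot`` (per-clone proportions),
    and ``clone_table.csv`` (long format).  All three round-trip to the
    original history within 1e-9.
    """
    if history.scale != FREQUENCY:
        raise ParameterError("fixtures require a frequency-scale history")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # PhyloWGS dialect: prevalence is cumulative over the subtree
    cumulative = subtree_sizes(history)
    children = history.children_map()
    structure = {
        c: children[c] for c in history.clone_ids if children[c]
    }
    doc = {
        "trees": {
            "0": {
                "populations": {
                    c: {"cellular_prevalence": cumulative[i].tolist()}
                    for i, c in enumerate(history.clone_ids)
                },
                "structure": structure,
                "llh": 0.0,
            }
        }
    }
    if history.time_labels is not None:
        doc["sample_names"] = list(history.time_labels)
    paths["phylowgs"] = out_dir / "phylowgs_summ.json"
    paths["phylowgs"].write_text(json.dumps(doc, indent=1))

    # CALDER dialect: per-clone proportions, sample rows x clone columns
    import pandas as pd

    mat = pd.DataFrame(history.sizes.T, columns=history.clone_ids)
    mat.insert(0, "sample", [history.time_label(k) for k in range(history.n_times)])
    paths["calder_matrix"] = out_dir / "calder_proportions.csv"
    mat.to_csv(paths["calder_matrix"], index=False)
    edges = [
        (history.parent_of[c], c)
        for c in history.clone_ids
        if history.parent_of.get(c) is not None
    ]
    paths["calder_tree"] = out_dir / "calder_tree.dot"
    paths["calder_tree"].write_text(dotio.to_dot(edges, nodes=history.clone_ids))

    # generic clone-table dialect
    table = to_long(history).rename(
        columns={"clone_id": "clone", "parent_id": "parent", "time": "sample"}
    )
    paths["clone_table"] = out_dir / "clone_table.csv"
    table.to_csv(paths["clone_table"], index=False)
    return paths
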