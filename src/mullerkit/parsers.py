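"""Converters from subclonal-reconstruction outputs to clone histories.

Three dialects are supported:

* **PhyloWGS summary JSON** -- a map of candidate trees, each with a
  parent->children ``structure`` and per-population ``cellular_prevalence``
  vectors (one entry per sample).  Cellular prevalence is *cumulative* over
  the subtree (the fraction of cells carrying the clone's mutations,
  including all descendants), so a clone's own abundance is its prevalence
  minus its children's prevalences.
* **CALDER** -- a clone-proportion matrix (sample rows x clone columns) plus
  a DOT tree.  CALDER proportions are already per-clone; no subtraction.
* **generic clone table** -- a long CSV with clone/parent/sample/frequency
  columns, the documented exchange dialect for tools (such as ClonEvol)
  whose native outputs are serialized R objects.

Every parsed history is on frequency scale and passes validation.  Gzipped
JSON is accepted transparently.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dotio
from .core import FREQUENCY, CloneHistory, from_long_frame, validate
from .errors import ConsistencyError, FormatError, ValidationError

__all__ = ["ParsedSolution", "parse_phylowgs", "parse_calder", "parse_clone_table"]

#: tolerance for a child's cumulative prevalence exceeding its parent's
PREVALENCE_TOL = 0.01


@dataclass
class ParsedSolution:
    """One reconstruction solution: a clone history plus provenance.

    ``score`` is the tool's solution score when it reports one (e.g. the
    PhyloWGS log-likelihood); ``source`` is ``"phylowgs"``, ``"calder"`` or
    ``"clone_table"``.
    """

    history: CloneHistory
    solution_id: str
    source: str
    score: float | None = None


def _require_valid(history: CloneHistory) -> CloneHistory:
    problems = validate(history)
    if problems:
        raise ValidationError("; ".join(problems))
    return history


def _read_text(source) -> str:
    """Read text from a path (gzip-transparent), file object, or string."""
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    p = Path(str(source))
    try:
        exists = p.exists()
    except OSError:
        exists = False
    if exists:
        raw = p.read_bytes()
        if raw[:2] == b"\x1f\x8b":
            raw = gzip.decompress(raw)
        return raw.decode("utf-8")
    return str(source)


# -- PhyloWGS -------------------------------------------------------------


def parse_phylowgs(
    source,
    selection="best",
    *,
    sample_labels: list[str] | None = None,
    keep_root: bool = True,
) -> list[ParsedSolution]:
    """Parse a PhyloWGS summary JSON into one history per selected tree.

    Parameters
    ----------
    source
        Path, file object, or JSON text (gzip accepted for paths).
    selection
        ``"best"`` (maximum reported likelihood), ``"all"``, or an explicit
        tree index (int or str key).
    sample_labels
        Optional names for the sample axis; defaults to names found in the
        JSON (``sample_names``) or sample indices.
    keep_root
        Keep the normal/root population as a clone (default).  ``False``
        removes it and renormalizes each sample by the remaining total.

    Each population's own abundance is its cellular prevalence minus the sum
    of its children's prevalences; negative values (inconsistent
    reconstructions) are clipped to zero with a warning, and an excess beyond
    ``PREVALENCE_TOL`` additionally raises a consistency warning naming the
    clone and sample.
    """
    text = _read_text(source)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed PhyloWGS JSON: {exc}") from exc
    if "trees" not in doc or not isinstance(doc["trees"], dict) or not doc["trees"]:
        raise FormatError("PhyloWGS JSON has no 'trees' map")
    trees = doc["trees"]
    labels = sample_labels or doc.get("sample_names")

    keys = sorted(trees, key=lambda k: (len(k), k))
    if selection == "all":
        chosen = keys
    elif selection == "best":
        scored = [(k, trees[k].get("llh")) for k in keys]
        if all(s is None for _, s in scored):
            warnings.warn(
                "no likelihoods reported; selection='best' falls back to the "
                "first tree",
                stacklevel=2,
            )
            chosen = keys[:1]
        else:
            chosen = [max((k for k, s in scored if s is not None),
                          key=lambda k: trees[k]["llh"])]
    else:
        key = str(selection)
        if key not in trees:
            raise FormatError(f"tree index {selection!r} not in summary (have {keys})")
        chosen = [key]

    out = []
    for k in chosen:
        out.append(
            ParsedSolution(
                history=_phylowgs_tree_to_history(trees[k], k, labels, keep_root),
                solution_id=str(k),
                source="phylowgs",
                score=trees[k].get("llh"),
            )
        )
    return out


def _phylowgs_tree_to_history(tree: dict, key: str, labels, keep_root: bool) -> CloneHistory:
    pops = tree.get("populations")
    structure = tree.get("structure", {})
    if not isinstance(pops, dict) or not pops:
        raise FormatError(f"tree {key!r} has no 'populations' map")

    clone_ids = sorted(pops, key=lambda c: (len(c), c))
    prev = {}
    n_samples = None
    for c in clone_ids:
        cp = pops[c].get("cellular_prevalence")
        if cp is None:
            raise FormatError(f"population {c!r} lacks 'cellular_prevalence'")
        cp = np.atleast_1d(np.asarray(cp, dtype=float))
        if n_samples is None:
            n_samples = cp.size
        elif cp.size != n_samples:
            raise FormatError(
                f"population {c!r} has {cp.size} samples, expected {n_samples}"
            )
        prev[c] = cp

    parent_of: dict[str, str | None] = {c: None for c in clone_ids}
    for p, kids in structure.items():
        for d in kids:
            d = str(d)
            if d in parent_of:
                parent_of[d] = str(p)

    own = {}
    for c in clone_ids:
        kids = [d for d in clone_ids if parent_of[d] == c]
        o = prev[c] - sum((prev[d] for d in kids), np.zeros(n_samples))
        for s in np.nonzero(o < -PREVALENCE_TOL)[0]:
            warnings.warn(
                f"children of clone {c!r} exceed its prevalence at sample {s} "
                f"by {-o[s]:.3g}",
                stacklevel=3,
            )
        if np.any(o < 0):
            warnings.warn(
                f"negative own abundance for clone {c!r} clipped to 0", stacklevel=3
            )
        own[c] = np.clip(o, 0.0, None)

    sizes = np.vstack([own[c] for c in clone_ids])
    if not keep_root:
        roots = [c for c in clone_ids if parent_of[c] is None]
        keep = [i for i, c in enumerate(clone_ids) if c not in roots]
        for c in clone_ids:
            if parent_of[c] in roots:
                parent_of[c] = None
        clone_ids = [clone_ids[i] for i in keep]
        sizes = sizes[keep]
        totals = sizes.sum(axis=0)
        pos = totals > 0
        sizes[:, pos] = sizes[:, pos] / totals[pos]
        parent_of = {c: parent_of[c] for c in clone_ids}

    if labels is not None and len(labels) != n_samples:
        raise FormatError(
            f"{len(labels)} sample labels for {n_samples} samples"
        )
    return _require_valid(
        CloneHistory(
            clone_ids=clone_ids,
            parent_of=parent_of,
            times=np.arange(n_samples, dtype=float),
            sizes=sizes,
            scale=FREQUENCY,
            time_labels=list(labels) if labels is not None else None,
        )
    )


# -- CALDER ---------------------------------------------------------------


def parse_calder(matrix_source, dot_source, *, delimiter: str | None = None) -> ParsedSolution:
    """Parse a CALDER solution: proportion matrix (samples x clones) + DOT tree.

    The matrix's first column holds sample labels and its header the clone
    labels; entries are per-clone proportions in [0, 1] (not cumulative).
    The DOT edges must form a rooted tree over exactly the matrix's clones.
    """
    from .core import _read_table  # shares the delimiter sniffing

    df = _read_table(matrix_source, delimiter)
    sample_labels = [str(x) for x in df.iloc[:, 0]]
    clone_ids = [str(c) for c in df.columns[1:]]
    mat = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise FormatError("non-numeric entry in proportion matrix")
    if np.any(mat < 0) or np.any(mat > 1):
        raise ConsistencyError("proportion matrix entries must lie in [0, 1]")
    row_sums = mat.sum(axis=1)
    for s in np.nonzero(row_sums > 1 + PREVALENCE_TOL)[0]:
        raise ConsistencyError(
            f"sample {sample_labels[s]!r} clone proportions sum to {row_sums[s]:.4g} > 1"
        )

    dot_nodes, edges = dotio.parse_dot(_read_text(dot_source))
    known = set(clone_ids)
    for n in dot_nodes:
        if n not in known:
            raise ConsistencyError(f"DOT clone {n!r} absent from proportion matrix")
    parent_of: dict[str, str | None] = {c: None for c in clone_ids}
    for p, c in edges:
        if parent_of[c] is not None:
            raise FormatError(f"DOT is not a tree: clone {c!r} has two parents")
        parent_of[c] = p

    history = CloneHistory(
        clone_ids=clone_ids,
        parent_of=parent_of,
        times=np.arange(len(sample_labels), dtype=float),
        sizes=mat.T.copy(),  # clone x sample
        scale=FREQUENCY,
        time_labels=sample_labels,
    )
    problems = validate(history)
    if problems:
        raise FormatError("DOT/matrix do not form a valid history: " + "; ".join(problems))
    return ParsedSolution(history=history, solution_id="calder", source="calder")


# -- generic clone table --------------------------------------------------


def parse_clone_table(
    source,
    *,
    sample_order: list[str] | None = None,
    delimiter: str | None = None,
) -> ParsedSolution:
    """Parse a generic clone-frequency table (clone, parent, sample, frequency).

    Sample order is first appearance unless ``sample_order`` is given.
    Column aliases of the long reader apply, so ``clone_id/parent_id/time``
    headers work too.
    """
    from .core import _read_table

    df = _read_table(source, delimiter)
    renames = {"clone": "clone_id", "parent": "parent_id", "sample": "time"}
    df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
    if "frequency" not in df.columns and "freq" not in df.columns:
        raise FormatError("missing required column 'frequency'")
    history = from_long_frame(df, scale=FREQUENCY, time_order=sample_order)
    return ParsedSolution(history=history, solution_id="clone_table", source="clone_table")
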