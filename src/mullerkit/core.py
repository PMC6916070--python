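"""Clone-history data model: readers/writers, validation, normalization, filtering.

The central type is :class:`CloneHistory`: a clone forest (each clone has at
most one parent), a strictly increasing time axis (numeric, or ordered sample
labels mapped to 0..m-1), and a clone x time matrix of non-negative sizes or
frequencies.  All other modules consume and produce this type.

Two table layouts are supported:

* **long** -- one row per (clone, time) observation with columns
  ``clone_id, parent_id, time, size`` (or ``frequency``) plus optional
  attribute columns; missing (clone, time) pairs are zero-filled;
* **wide** -- one row per clone, one column per time point, with the parent
  mapping either as a ``parent_id`` column or a separate two-column table.

``read_long(to_long(h))`` and ``read_wide(*to_wide(h))`` are identities.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

SIZE = "size"
FREQUENCY = "frequency"

_VALUE_COLUMN_ALIASES = ("value", "size", "freq", "frequency")

__all__ = [
    "CloneHistory",
    "read_long",
    "read_wide",
    "from_long_frame",
    "from_wide_frame",
    "to_long",
    "to_wide",
    "write_long",
    "write_wide",
    "validate",
    "normalize_frequencies",
    "filter_clones",
    "SIZE",
    "FREQUENCY",
]


@dataclass
class CloneHistory:
    """A clone forest with per-clone abundance trajectories.

    Parameters
    ----------
    clone_ids
        Ordered unique clone identifiers (strings); row order of ``sizes``.
    parent_of
        Map ``clone_id -> parent clone_id`` or ``None`` for roots.  The
        relation must be acyclic (a forest).
    times
        Strictly increasing numeric time points, one per column of ``sizes``.
        Categorical sample labels (e.g. xenograft passages ``T, X1, X2``) are
        represented as consecutive integers with the labels kept in
        ``time_labels``.
    sizes
        ``(n_clones, n_times)`` matrix of non-negative abundances.
    scale
        ``"size"`` (absolute counts) or ``"frequency"`` (column sums <= 1).
    attributes
        Optional per-clone annotations: ``name -> {clone_id -> value}``.
    """

    clone_ids: list[str]
    parent_of: dict[str, str | None]
    times: np.ndarray
    sizes: np.ndarray
    scale: str = SIZE
    time_labels: list[str] | None = None
    attributes: dict[str, dict[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clone_ids = [str(c) for c in self.clone_ids]
        self.times = np.asarray(self.times, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.shape != (len(self.clone_ids), self.times.size):
            raise ValidationError(
                f"sizes has shape {self.sizes.shape}, expected "
                f"({len(self.clone_ids)}, {self.times.size})"
            )
        if self.scale not in (SIZE, FREQUENCY):
            raise ParameterError(f"scale must be 'size' or 'frequency', got {self.scale!r}")

    # -- basic structure -------------------------------------------------

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def index(self, clone: str) -> int:
        return self.clone_ids.index(clone)

    def parent(self, clone: str) -> str | None:
        return self.parent_of.get(clone)

    def roots(self) -> list[str]:
        return [c for c in self.clone_ids if self.parent_of.get(c) is None]

    def children_map(self) -> dict[str, list[str]]:
        """Children of every clone, in ``clone_ids`` order."""
        out: dict[str, list[str]] = {c: [] for c in self.clone_ids}
        for c in self.clone_ids:
            p = self.parent_of.get(c)
            if p is not None:
                out[p].append(c)
        return out

    def row(self, clone: str) -> np.ndarray:
        return self.sizes[self.index(clone)]

    def column_sums(self) -> np.ndarray:
        return self.sizes.sum(axis=0)

    def time_label(self, k: int) -> str:
        if self.time_labels is not None:
            return self.time_labels[k]
        t = self.times[k]
        return str(int(t)) if float(t).is_integer() else str(t)

    def copy(self) -> "CloneHistory":
        return replace(
            self,
            clone_ids=list(self.clone_ids),
            parent_of=dict(self.parent_of),
            times=self.times.copy(),
            sizes=self.sizes.copy(),
            time_labels=None if self.time_labels is None else list(self.time_labels),
            attributes={k: dict(v) for k, v in self.attributes.items()},
        )

    def equals(self, other: "CloneHistory", atol: float = 0.0) -> bool:
        return (
            self.clone_ids == other.clone_ids
            and self.parent_of == other.parent_of
            and np.array_equal(self.times, other.times)
            and np.allclose(self.sizes, other.sizes, rtol=0.0, atol=atol)
            and self.scale == other.scale
        )


# -- validation ----------------------------------------------------------


def _find_cycle(parent_of: Mapping[str, str | None], clones: Sequence[str]) -> list[str] | None:
    """Return one parent-pointer cycle as a list of clone ids, or None."""
    clones_set = set(clones)
    state: dict[str, int] = {}  # 1 = in progress, 2 = done
    for start in clones:
        if state.get(start):
            continue
        path: list[str] = []
        node: str | None = start
        while node is not None and node in clones_set and state.get(node) != 2:
            if state.get(node) == 1:
                i = path.index(node)
                return path[i:]
            state[node] = 1
            path.append(node)
            node = parent_of.get(node)
        for n in path:
            state[n] = 2
    return None


def validate(history: CloneHistory) -> list[str]:
    """Check every :class:`CloneHistory` invariant.

    Returns a list of human-readable violation messages (empty iff valid);
    each message names the clone and/or time involved.  Nothing is raised.
    """
    v: list[str] = []
    seen: set[str] = set()
    for c in history.clone_ids:
        if c in seen:
            v.append(f"duplicate clone id {c!r}")
        seen.add(c)
    for c, p in history.parent_of.items():
        if c not in seen:
            v.append(f"parent_of mentions unknown clone {c!r}")
        if p is not None and p not in seen:
            v.append(f"clone {c!r} has unknown parent {p!r}")
    cycle = _find_cycle(history.parent_of, history.clone_ids)
    if cycle is not None:
        v.append("parent cycle: " + " -> ".join(cycle + [cycle[0]]))
    if history.times.size and np.any(np.diff(history.times) <= 0):
        v.append("times are not strictly increasing")
    neg = np.argwhere(history.sizes < 0)
    for i, k in neg:
        v.append(
            f"negative size for clone {history.clone_ids[i]!r} at time "
            f"{history.time_label(int(k))}"
        )
    if history.scale == FREQUENCY:
        sums = history.column_sums()
        for k in np.nonzero(sums > 1 + 1e-9)[0]:
            v.append(
                f"frequency column at time {history.time_label(int(k))} sums to "
                f"{sums[k]:.6g} > 1"
            )
    return v


def _require_valid(history: CloneHistory) -> CloneHistory:
    problems = validate(history)
    if problems:
        raise ValidationError("; ".join(problems))
    return history


# -- long format ---------------------------------------------------------


def _sniff_delimiter(source, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if isinstance(source, (str, Path)) and Path(source).exists():
        first = Path(source).open("r", encoding="utf-8").readline()
    elif hasattr(source, "read"):
        pos = source.tell()
        first = source.readline()
        source.seek(pos)
    else:
        first = str(source).splitlines()[0] if str(source) else ""
    return "\t" if "\t" in first else ","


def _read_table(source, delimiter: str | None) -> pd.DataFrame:
    sep = _sniff_delimiter(source, delimiter)
    if isinstance(source, str) and not Path(source).exists() and "\n" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or str(x).strip() == ""


def _parse_time_axis(
    raw: Sequence, time_order: Sequence[str] | None
) -> tuple[np.ndarray, list[str] | None, dict]:
    """Map raw time values to a numeric axis.

    Numeric values are used directly (sorted); non-numeric values become an
    ordered categorical axis 0..m-1, ordered by ``time_order`` if given,
    otherwise by first appearance.
    """
    as_str = [str(x) for x in raw]
    numeric = pd.to_numeric(pd.Series(as_str), errors="coerce")
    if time_order is None and not numeric.isna().any():
        uniq = np.unique(numeric.to_numpy(dtype=float))
        return uniq, None, {t: i for i, t in enumerate(uniq)}
    if time_order is not None:
        labels = [str(x) for x in time_order]
        unknown = sorted(set(as_str) - set(labels))
        if unknown:
            raise FormatError(f"time values {unknown} not in declared order {labels}")
    else:
        labels = list(dict.fromkeys(as_str))
    lookup = {lab: i for i, lab in enumerate(labels)}
    times = np.arange(len(labels), dtype=float)
    return times, labels, {lab: lookup[lab] for lab in as_str}


def _time_column_index(times, labels, lookup, value):
    key = float(str(value)) if labels is None else str(value)
    if labels is None:
        return int(np.searchsorted(times, key))
    return lookup[key]


def from_long_frame(
    table: pd.DataFrame,
    *,
    clone_col: str = "clone_id",
    parent_col: str = "parent_id",
    time_col: str = "time",
    value_col: str | None = None,
    scale: str | None = None,
    time_order: Sequence[str] | None = None,
) -> CloneHistory:
    """Build a :class:`CloneHistory` from a long-format DataFrame.

    ``value_col=None`` picks the first of ``value``/``size``/``freq``/
    ``frequency`` present; a ``freq``/``frequency`` column implies
    ``scale="frequency"`` unless ``scale`` is given explicitly.  Extra columns
    become per-clone attributes (and must be constant within a clone).
    """
    for col in (clone_col, time_col):
        if col not in table.columns:
            raise FormatError(f"missing required column {col!r}")
    if value_col is None:
        value_col = next((c for c in _VALUE_COLUMN_ALIASES if c in table.columns), None)
        if value_col is None:
            raise FormatError(
                "missing required value column (one of " + ", ".join(_VALUE_COLUMN_ALIASES) + ")"
            )
    elif value_col not in table.columns:
        raise FormatError(f"missing required column {value_col!r}")
    if scale is None:
        scale = FREQUENCY if value_col in ("freq", "frequency") else SIZE
    has_parent = parent_col in table.columns

    clones = [str(c) for c in dict.fromkeys(table[clone_col])]
    values = pd.to_numeric(table[value_col], errors="coerce")
    if values.isna().any():
        bad = table.loc[values.isna(), value_col].iloc[0]
        raise FormatError(f"non-numeric value {bad!r} in column {value_col!r}")

    parent_of: dict[str, str | None] = {}
    for c in clones:
        if not has_parent:
            parent_of[c] = None
            continue
        raw = table.loc[table[clone_col].astype(str) == c, parent_col]
        seen = {None if _is_missing(p) else str(p) for p in raw}
        if len(seen) > 1:
            raise ConsistencyError(
                f"clone {c!r} has conflicting parents {sorted(str(s) for s in seen)}"
            )
        parent_of[c] = seen.pop()

    times, labels, lookup = _parse_time_axis(table[time_col].tolist(), time_order)
    sizes = np.zeros((len(clones), times.size))
    filled = np.zeros_like(sizes, dtype=bool)
    clone_idx = {c: i for i, c in enumerate(clones)}
    for (c, t, val) in zip(table[clone_col], table[time_col], values):
        i = clone_idx[str(c)]
        k = _time_column_index(times, labels, lookup, t)
        if filled[i, k] and sizes[i, k] != val:
            raise ConsistencyError(
                f"duplicate records for clone {c!r} at time {t!r} with differing "
                f"values ({sizes[i, k]:g} vs {val:g})"
            )
        sizes[i, k] = val
        filled[i, k] = True

    attributes: dict[str, dict[str, object]] = {}
    reserved = {clone_col, parent_col, time_col, value_col}
    for col in table.columns:
        if col in reserved:
            continue
        mapping: dict[str, object] = {}
        for c in clones:
            vals = table.loc[table[clone_col].astype(str) == c, col]
            uniq = {str(v) for v in vals if not _is_missing(v)}
            if len(uniq) > 1:
                raise ConsistencyError(
                    f"attribute {col!r} varies within clone {c!r}: {sorted(uniq)}"
                )
            if uniq:
                raw = uniq.pop()
                num = pd.to_numeric(pd.Series([raw]), errors="coerce").iloc[0]
                mapping[c] = float(num) if not pd.isna(num) else raw
        if mapping:
            attributes[col] = mapping

    return _require_valid(
        CloneHistory(
            clone_ids=clones,
            parent_of=parent_of,
            times=times,
            sizes=sizes,
            scale=scale,
            time_labels=labels,
            attributes=attributes,
        )
    )


def read_long(source, *, delimiter: str | None = None, **kwargs) -> CloneHistory:
    """Read a long-format delimited text file (or string/buffer).

    The delimiter is auto-detected (comma vs. tab) unless given.  See
    :func:`from_long_frame` for column handling.
    """
    return from_long_frame(_read_table(source, delimiter), **kwargs)


def to_long(history: CloneHistory) -> pd.DataFrame:
    """Long-format table with one row per (clone, time), zeros included.

    Columns: ``clone_id, parent_id, time, size|frequency`` plus one column
    per attribute.  ``read_long(to_long(h))`` reproduces ``h`` exactly.
    """
    value_col = "frequency" if history.scale == FREQUENCY else "size"
    rows = []
    for i, c in enumerate(history.clone_ids):
        p = history.parent_of.get(c)
        for k in range(history.n_times):
            t = history.time_labels[k] if history.time_labels is not None else history.times[k]
            rows.append([c, "" if p is None else p, t, history.sizes[i, k]])
    df = pd.DataFrame(rows, columns=["clone_id", "parent_id", "time", value_col])
    for name, mapping in history.attributes.items():
        df[name] = [mapping.get(c, "") for c in df["clone_id"]]
    return df


def write_long(history: CloneHistory, path, *, delimiter: str = ",") -> None:
    to_long(history).to_csv(path, sep=delimiter, index=False)


# -- wide format ----------------------------------------------------------


def from_wide_frame(
    size_table: pd.DataFrame,
    parents: pd.DataFrame | Mapping[str, str | None] | None = None,
    *,
    clone_col: str = "clone_id",
    parent_col: str = "parent_id",
    scale: str = SIZE,
    time_order: Sequence[str] | None = None,
) -> CloneHistory:
    """Build a :class:`CloneHistory` from a wide table (one column per time).

    Time columns are every column other than ``clone_col`` (and ``parent_col``
    if embedded).  Numeric headers give the time axis directly; non-numeric
    headers (e.g. passage labels ``T, X1, X2``) are kept as ordered labels in
    column order, mapped to 0..m-1.
    """
    if clone_col not in size_table.columns:
        raise FormatError(f"missing required column {clone_col!r}")
    clones = [str(c) for c in size_table[clone_col]]

    if parents is None and parent_col in size_table.columns:
        parents = dict(zip(clones, size_table[parent_col]))
    if parents is None:
        raise FormatError("no parent mapping: pass `parents` or include a parent_id column")
    if isinstance(parents, pd.DataFrame):
        pc = parents.columns[0] if clone_col not in parents.columns else clone_col
        qc = [c for c in parents.columns if c != pc][0]
        parents = dict(zip(parents[pc].astype(str), parents[qc]))
    parent_of: dict[str, str | None] = {}
    for c in clones:
        if c not in {str(k) for k in parents}:
            raise ValidationError(f"clone {c!r} missing from parent mapping")
        p = {str(k): v for k, v in parents.items()}[c]
        parent_of[c] = None if _is_missing(p) else str(p)

    time_cols = [c for c in size_table.columns if c not in (clone_col, parent_col)]
    if not time_cols:
        raise FormatError("wide table has no time columns")
    times, labels, lookup = _parse_time_axis(time_cols, time_order or None)
    if labels is None:
        order = np.argsort([float(c) for c in time_cols])
        time_cols = [time_cols[i] for i in order]
    else:
        time_cols = sorted(time_cols, key=lambda c: lookup[str(c)])
    sizes = size_table[time_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(sizes).any():
        raise FormatError("non-numeric entry in wide size table")
    return _require_valid(
        CloneHistory(
            clone_ids=clones,
            parent_of=parent_of,
            times=times,
            sizes=sizes,
            scale=scale,
            time_labels=labels,
        )
    )


def read_wide(
    size_source,
    parent_source=None,
    *,
    delimiter: str | None = None,
    **kwargs,
) -> CloneHistory:
    """Read a wide-format size table plus parent mapping from delimited text."""
    size_table = _read_table(size_source, delimiter)
    parents = None if parent_source is None else _read_table(parent_source, delimiter)
    return from_wide_frame(size_table, parents, **kwargs)


def to_wide(history: CloneHistory) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide size table + two-column parent table (round-trips exactly)."""
    headers = (
        history.time_labels
        if history.time_labels is not None
        else [history.time_label(k) for k in range(history.n_times)]
    )
    size_df = pd.DataFrame(history.sizes, columns=headers)
    size_df.insert(0, "clone_id", history.clone_ids)
    parents_df = pd.DataFrame(
        {
            "clone_id": history.clone_ids,
            "parent_id": ["" if history.parent_of.get(c) is None else history.parent_of[c]
                          for c in history.clone_ids],
        }
    )
    return size_df, parents_df


def write_wide(history: CloneHistory, size_path, parents_path, *, delimiter: str = ",") -> None:
    size_df, parents_df = to_wide(history)
    size_df.to_csv(size_path, sep=delimiter, index=False)
    parents_df.to_csv(parents_path, sep=delimiter, index=False)


# -- normalization and filtering ------------------------------------------


def normalize_frequencies(history: CloneHistory) -> CloneHistory:
    """Convert a size-scale history to frequencies (columns sum to 1 or 0).

    Each column with positive total is divided by that total; all-zero
    columns are left at zero.  Re-normalizing a frequency-scale history is a
    precondition error, as is a history with no mass anywhere.
    """
    if history.scale == FREQUENCY:
        raise ParameterError("history is already on frequency scale")
    totals = history.column_sums()
    if not np.any(totals > 0):
        raise DegenerateInputError("all columns are zero; nothing to normalize")
    out = history.copy()
    pos = totals > 0
    out.sizes[:, pos] = out.sizes[:, pos] / totals[pos]
    out.scale = FREQUENCY
    return out


def _frequencies(history: CloneHistory) -> np.ndarray:
    """Per-column frequencies regardless of scale (zero columns stay zero)."""
    if history.scale == FREQUENCY:
        return history.sizes
    totals = history.column_sums()
    out = np.zeros_like(history.sizes)
    pos = totals > 0
    out[:, pos] = history.sizes[:, pos] / totals[pos]
    return out


def filter_clones(
    history: CloneHistory, threshold: float, mode: str = "merge"
) -> CloneHistory:
    """Remove clones whose frequency never reaches ``threshold``.

    A clone is removed iff it is not a root and its maximum frequency over
    the whole time course (computed on the normalized history) is strictly
    below ``threshold``.  Roots are never removed.

    mode="merge" (default)
        The removed clone's sizes are added to its parent at every time and
        its children are re-parented to that parent, so every column total is
        conserved exactly.  Removal proceeds bottom-up, so a chain of
        sub-threshold clones collapses into its nearest surviving ancestor.
    mode="drop"
        The removed clone's mass is discarded; children are re-parented.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    if mode not in ("merge", "drop"):
        raise ParameterError(f"mode must be 'merge' or 'drop', got {mode!r}")
    _require_valid(history)

    freqs = _frequencies(history)
    max_freq = freqs.max(axis=1) if history.n_times else np.zeros(history.n_clones)
    removed = {
        c
        for i, c in enumerate(history.clone_ids)
        if history.parent_of.get(c) is not None and max_freq[i] < threshold
    }

    out = history.copy()
    # bottom-up: children before parents, so chains collapse into survivors
    order = _postorder(out)
    for c in order:
        if c not in removed:
            continue
        p = out.parent_of[c]
        i, j = out.clone_ids.index(c), out.clone_ids.index(p)
        if mode == "merge":
            out.sizes[j] += out.sizes[i]
        for d in out.clone_ids:
            if out.parent_of.get(d) == c:
                out.parent_of[d] = p
        keep = [k for k in range(out.n_clones) if k != i]
        out.sizes = out.sizes[keep]
        out.clone_ids.pop(i)
        del out.parent_of[c]
        for mapping in out.attributes.values():
            mapping.pop(c, None)
    return out


def _postorder(history: CloneHistory) -> list[str]:
    """Children-before-parents ordering of the forest."""
    children = history.children_map()
    out: list[str] = []

    def visit(c: str) -> None:
        for d in children[c]:
            visit(d)
        out.append(c)

    for r in history.roots():
        visit(r)
    return out
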