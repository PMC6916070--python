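"""Minimal Graphviz DOT reading/writing for clone trees.

Covers the digraph subset that clone-tree exchange needs: one ``digraph``
block containing node statements (with optional ``[key="value"]`` attribute
lists) and ``a -> b`` edge statements.  Identifiers may be bare words or
double-quoted strings.  This is deliberately not a full DOT implementation.
"""

from __future__ import annotations

import re

from .errors import FormatError

__all__ = ["to_dot", "parse_dot"]

_BARE_ID = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$|^-?\d+(\.\d+)?$")
_EDGE = re.compile(r'^\s*("(?:[^"\\]|\\.)*"|[\w.\-]+)\s*->\s*("(?:[^"\\]|\\.)*"|[\w.\-]+)')
_NODE = re.compile(r'^\s*("(?:[^"\\]|\\.)*"|[\w.\-]+)\s*(\[[^\]]*\])?\s*;?\s*$')


def _quote(name: str) -> str:
    return name if _BARE_ID.match(name) else '"' + name.replace('"', '\\"') + '"'


def _unquote(token: str) -> str:
    if token.startswith('"') and token.endswith('"'):
        return token[1:-1].replace('\\"', '"')
    return token


def to_dot(
    edges: list[tuple[str, str]],
    nodes: list[str] | None = None,
    node_attrs: dict[str, dict[str, object]] | None = None,
    name: str = "clone_tree",
) -> str:
    """Serialize a directed clone tree to DOT text."""
    lines = [f"digraph {name} {{"]
    seen: list[str] = []
    for n in (nodes or []):
        if n not in seen:
            seen.append(n)
    for a, b in edges:
        for n in (a, b):
            if n not in seen:
                seen.append(n)
    attrs = node_attrs or {}
    for n in seen:
        decorations = {"label": n, **attrs.get(n, {})}
        body = ", ".join(f'{k}="{v}"' for k, v in decorations.items())
        lines.append(f"  {_quote(n)} [{body}];")
    for a, b in edges:
        lines.append(f"  {_quote(a)} -> {_quote(b)};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def parse_dot(text: str) -> tuple[list[str], list[tuple[str, str]]]:
    """Parse DOT text into (node list, directed edge list).

    Accepts the subset written by :func:`to_dot` plus typical tool output
    (comments, ``graph``/``node``/``edge`` default statements are skipped).
    Raises :class:`FormatError` when no digraph block is found.
    """
    text = re.sub(r"//[^\n]*", "", text)
    text = re.sub(r"/\*.*?\*/", "", text, flags=re.S)
    m = re.search(r"digraph\b[^{]*\{(.*)\}", text, flags=re.S)
    if m is None:
        raise FormatError("no digraph block found in DOT input")
    body = m.group(1)
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []

    def note(n: str) -> None:
        if n not in nodes:
            nodes.append(n)

    for stmt in re.split(r"[;\n]", body):
        stmt = stmt.strip()
        if not stmt or stmt.split("[")[0].strip() in ("graph", "node", "edge"):
            continue
        em = _EDGE.match(stmt)
        if em:
            a, b = _unquote(em.group(1)), _unquote(em.group(2))
            note(a)
            note(b)
            edges.append((a, b))
            continue
        nm = _NODE.match(stmt)
        if nm and "=" not in stmt.split("[")[0]:
            note(_unquote(nm.group(1)))
    return nodes, edges
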