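"""Plain-text I/O: edge lists and community ("cover") files.

Edge-list format: one edge per line, two whitespace-separated node labels;
blank lines and ``#``-prefixed comment lines are ignored.  Community-file
format (the convention shared by the common overlapping-NMI scorers): one
community per line, space-separated node labels; unassigned nodes are kept
in a single ``#unassigned:`` sidecar line so covers round-trip exactly.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Union

from .graph import Cover, Graph, from_edge_list

__all__ = ["read_edge_list", "read_cover", "write_cover", "karate_club"]

_UNASSIGNED_PREFIX = "#unassigned:"


class EdgeListFormatError(ValueError):
    """Raised for malformed edge-list lines, with the line number."""


def read_edge_list(path: Union[str, Path]) -> Graph:
    """Parse an edge-list text file into a Graph."""
    pairs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise EdgeListFormatError(
                f"{path}:{lineno}: expected two labels, got {len(tokens)}: {raw!r}")
        pairs.append((tokens[0], tokens[1]))
    return from_edge_list(pairs)


def read_cover(path: Union[str, Path]) -> Cover:
    """Parse a community file; an empty line is an empty community."""
    communities: list[frozenset] = []
    unassigned: frozenset = frozenset()
    for raw in Path(path).read_text().splitlines():
        if raw.startswith(_UNASSIGNED_PREFIX):
            unassigned = frozenset(raw[len(_UNASSIGNED_PREFIX):].split())
            continue
        if raw.startswith("#"):
            continue
        communities.append(frozenset(raw.split()))
    return Cover(tuple(communities), unassigned)


def write_cover(cover: Cover, path: Union[str, Path]) -> None:
    """Write one community per line (labels sorted for determinism), in
    cover (= medoid) order, plus the ``#unassigned:`` sidecar when needed."""
    lines = [" ".join(sorted(map(str, c))) for c in cover.communities]
    if cover.unassigned:
        lines.append(_UNASSIGNED_PREFIX + " "
                     + " ".join(sorted(map(str, cover.unassigned))))
    Path(path).write_text("\n".join(lines) + "\n")


def karate_club() -> tuple[Graph, Cover]:
    """The bundled Zachary karate-club network (34 nodes, 78 edges) with its
    standard two-faction ground truth."""
    data = importlib.resources.files("lpam.data")
    graph = from_edge_list(
        tuple(line.split()) for line in
        (data / "karate.edgelist").read_text().splitlines()
        if line.strip() and not line.startswith("#"))
    communities = [frozenset(line.split()) for line in
                   (data / "karate_factions.cmty").read_text().splitlines()
                   if line.strip() and not line.startswith("#")]
    return graph, Cover(tuple(communities))
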