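"""Reading and writing per-cell mitochondrial graph ("GNET"-style) files.

A segmented cell's mitochondrial skeleton is stored as a weighted undirected
graph: nodes are branch points and end points, edges carry the physical
length (in μm) of the tubule connecting them.  The file dialect adopted here
is: first line = node count; each subsequent line = ``u v length`` with
0-based integer node indices and a decimal edge length in μm, whitespace (or
a configurable delimiter) separated.  Whether upstream tools emit 0- or
1-based indices is not standardized; this dialect is documented so that
others can be added.

Self-loops and parallel edges are legal (skeletonized loops occur) and are
counted as distinct edges throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import GnetParseError, ValidationError

__all__ = [
    "MitoNetwork",
    "NetworkDataset",
    "read_gnet",
    "write_gnet",
    "load_dataset",
]


@dataclass
class MitoNetwork:
    """One cell's skeletonized mitochondrial network.

    Parameters
    ----------
    cell_id : str
        Unique cell identifier within a dataset.
    condition : str
        Experimental condition label used for grouping.
    n_nodes : int
        Number of nodes; node indices in edges must lie in ``[0, n_nodes)``.
    edges : list of (int, int, float)
        Undirected edges ``(u, v, length_um)`` with strictly positive length.
    node_coords : list of (float, float, float), optional
        Per-node spatial coordinates in μm; unused by metrics.
    """

    cell_id: str
    condition: str
    n_nodes: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)
    node_coords: list[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 0:
            raise ValidationError(f"n_nodes must be >= 0, got {self.n_nodes}")
        for i, (u, v, length) in enumerate(self.edges):
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValidationError(
                    f"edge {i} ({u}, {v}) out of range for {self.n_nodes} nodes"
                )
            if not length > 0:
                raise ValidationError(
                    f"edge {i} ({u}, {v}) has non-positive length {length}"
                )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_length(self) -> float:
        """Sum of all edge lengths in μm."""
        return float(sum(length for _, _, length in self.edges))

    def to_networkx(self) -> nx.MultiGraph:
        """Undirected multigraph view; parallel edges and loops preserved."""
        g = nx.MultiGraph()
        g.add_nodes_from(range(self.n_nodes))
        for u, v, length in self.edges:
            g.add_edge(u, v, length=length)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MitoNetwork):
            return NotImplemented
        return (
            self.cell_id == other.cell_id
            and self.condition == other.condition
            and self.n_nodes == other.n_nodes
            and self.edges == other.edges
        )


@dataclass
class NetworkDataset:
    """A multi-cell, multi-condition collection of mitochondrial networks.

    ``filter_log`` records every component removal performed by the artifact
    filters: one dict per removed component with keys ``filter``, ``cell_id``,
    ``n_nodes``, ``n_edges``, ``length`` and (for the repetition filter)
    ``length_key``.
    """

    networks: list[MitoNetwork] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    filter_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.cell_id for n in self.networks]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate cell_ids in dataset: {dupes}")
        known = set(ids)
        for entry in self.filter_log:
            if entry.get("cell_id") not in known:
                raise ValidationError(
                    f"filter_log references unknown cell_id {entry.get('cell_id')!r}"
                )

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    def get(self, cell_id: str) -> MitoNetwork:
        for net in self.networks:
            if net.cell_id == cell_id:
                return net
        raise KeyError(cell_id)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for net in self.networks:
            seen.setdefault(net.condition, None)
        return list(seen)

    def write_filter_log(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.filter_log, indent=1))


def read_gnet(
    path: str | Path,
    cell_id: str | None = None,
    condition: str = "",
    delimiter: str | None = None,
) -> MitoNetwork:
    """Parse one GNET-style graph file into a :class:`MitoNetwork`.

    ``delimiter=None`` splits on any whitespace (tabs or spaces).  Edge order
    in the file is preserved.  Raises :class:`GnetParseError` naming the line
    number on malformed input, and :class:`ValidationError` for out-of-range
    node indices or non-positive lengths.
    """
    path = Path(path)
    if cell_id is None:
        cell_id = path.stem
    lines = path.read_text().splitlines()
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not body:
        raise GnetParseError(f"{path}: empty file")
    header_no, header = body[0]
    try:
        n_nodes = int(header.strip())
    except ValueError:
        raise GnetParseError(
            f"{path}:{header_no}: expected node count, got {header!r}"
        ) from None
    edges: list[tuple[int, int, float]] = []
    for lineno, line in body[1:]:
        parts = line.split(delimiter)
        if len(parts) != 3:
            raise GnetParseError(
                f"{path}:{lineno}: expected 'u v length', got {line!r}"
            )
        try:
            u, v = int(parts[0]), int(parts[1])
            length = float(parts[2])
        except ValueError:
            raise GnetParseError(
                f"{path}:{lineno}: could not parse 'u v length' from {line!r}"
            ) from None
        if not (0 <= u < n_nodes and 0 <= v < n_nodes):
            raise ValidationError(
                f"{path}:{lineno}: node index out of range [0, {n_nodes})"
            )
        if not length > 0:
            raise ValidationError(f"{path}:{lineno}: non-positive length {length}")
        edges.append((u, v, length))
    return MitoNetwork(cell_id=cell_id, condition=condition,
                       n_nodes=n_nodes, edges=edges)


def write_gnet(net: MitoNetwork, path: str | Path, delimiter: str = "\t") -> None:
    """Write a network in the dialect :func:`read_gnet` reads.

    Lengths are written with shortest round-trip precision (``repr``) so the
    decimal-parsed values — and hence the rounded length keys used by the
    repetition filter — are preserved exactly.
    """
    path = Path(path)
    rows = [str(net.n_nodes)]
    for u, v, length in net.edges:
        rows.append(f"{u}{delimiter}{v}{delimiter}{length!r}")
    path.write_text("\n".join(rows) + "\n")


def load_dataset(manifest: str | Path | pd.DataFrame,
                 delimiter: str | None = None) -> NetworkDataset:
    """Assemble a dataset from a manifest of ``file,cell_id,condition`` rows.

    ``manifest`` may be a CSV path or an equivalent DataFrame.  All missing
    files are reported at once; duplicate cell ids are rejected.
    """
    if isinstance(manifest, (str, Path)):
        table = pd.read_csv(manifest)
    else:
        table = manifest
    required = {"file", "cell_id", "condition"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValidationError(f"manifest missing columns: {sorted(missing_cols)}")
    ids = list(table["cell_id"].astype(str))
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate cell_id in manifest: {dupes}")
    missing = [str(f) for f in table["file"] if not Path(f).exists()]
    if missing:
        raise FileNotFoundError(f"manifest files not found: {missing}")
    networks = [
        read_gnet(row.file, cell_id=str(row.cell_id),
                  condition=str(row.condition), delimiter=delimiter)
        for row in table.itertuples()
    ]
    return NetworkDataset(networks=networks,
                          provenance=[str(f) for f in table["file"]])
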