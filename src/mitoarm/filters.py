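"""Artifact-removal filters for segmented mitochondrial network datasets.

Automated segmentation of confocal z-stacks produces two well-characterized
classes of artifactual connected components:

1. *Long two-node components* — spurious straight segments spanning a cropped
   cell, recognizable because a genuine 2-node/1-edge mitochondrion is rarely
   longer than ~15–20 μm; anything over 100 μm is removed.
2. *Repeating components* — bright noise voxels segmented as tiny components
   whose total length repeats (identically, to rounding) many times across a
   dataset, producing a spurious sub-1 μm shoulder on the component-length
   histogram.  Any component whose rounded length accounts for strictly more
   than 0.05% of all components in the dataset is removed.

Both filters are single-pass: frequencies are computed once on the pre-filter
dataset and never recomputed after removals, so each filter is idempotent.
Isolated (degree-0) nodes carry no length and are dropped with a warning
before filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MitoNetwork, NetworkDataset

__all__ = [
    "ComponentSummary",
    "connected_components",
    "drop_isolated_nodes",
    "filter_long_two_node",
    "filter_repeating_components",
    "length_frequency_table",
    "length_histogram",
    "DEFAULT_TWO_NODE_MAX_UM",
    "DEFAULT_REPEAT_FRACTION",
    "DEFAULT_LENGTH_PRECISION",
]

DEFAULT_TWO_NODE_MAX_UM = 100.0   # legitimate 2-node components top out ~15-20 um
DEFAULT_REPEAT_FRACTION = 0.0005  # strict > 0.05% of all components in a dataset
DEFAULT_LENGTH_PRECISION = 4      # decimals of um used as the repetition key


@dataclass(frozen=True)
class ComponentSummary:
    """One connected component of one cell's network."""

    component_id: int
    cell_id: str
    nodes: tuple[int, ...]
    n_edges: int
    length: float
    length_key: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def connected_components(
    net: MitoNetwork, precision: int = DEFAULT_LENGTH_PRECISION
) -> list[ComponentSummary]:
    """Partition a network into connected components.

    Components are ordered by descending summed length, ties broken by the
    lowest member node index.  ``length_key`` is the summed length rounded to
    ``precision`` decimals of μm — the identity used by the repetition filter.
    """
    g = net.to_networkx()
    summaries = []
    for nodes in nx.connected_components(g):
        nodes = tuple(sorted(nodes))
        sub = g.subgraph(nodes)
        length = float(sum(d["length"] for _, _, d in sub.edges(data=True)))
        summaries.append(
            ComponentSummary(
                component_id=-1,
                cell_id=net.cell_id,
                nodes=nodes,
                n_edges=sub.number_of_edges(),
                length=length,
                length_key=round(length, precision),
            )
        )
    summaries.sort(key=lambda c: (-c.length, c.nodes[0]))
    return [
        ComponentSummary(i, c.cell_id, c.nodes, c.n_edges, c.length, c.length_key)
        for i, c in enumerate(summaries)
    ]


def _remove_components(
    net: MitoNetwork, doomed: list[ComponentSummary]
) -> MitoNetwork:
    """Rebuild a network with the given components' nodes and edges deleted.

    Remaining nodes are re-indexed compactly, preserving order."""
    dead_nodes = set()
    for comp in doomed:
        dead_nodes.update(comp.nodes)
    keep = [i for i in range(net.n_nodes) if i not in dead_nodes]
    remap = {old: new for new, old in enumerate(keep)}
    edges = [
        (remap[u], remap[v], length)
        for u, v, length in net.edges
        if u not in dead_nodes and v not in dead_nodes
    ]
    coords = None
    if net.node_coords is not None:
        coords = [net.node_coords[i] for i in keep]
    return MitoNetwork(
        cell_id=net.cell_id,
        condition=net.condition,
        n_nodes=len(keep),
        edges=edges,
        node_coords=coords,
    )


def drop_isolated_nodes(dataset: NetworkDataset) -> NetworkDataset:
    """Remove degree-0 nodes (zero length, no physical meaning) everywhere."""
    networks = []
    n_dropped = 0
    for net in dataset:
        used = set()
        for u, v, _ in net.edges:
            used.update((u, v))
        isolated = [i for i in range(net.n_nodes) if i not in used]
        if isolated:
            n_dropped += len(isolated)
            keep = [i for i in range(net.n_nodes) if i in used]
            remap = {old: new for new, old in enumerate(keep)}
            net = MitoNetwork(
                cell_id=net.cell_id,
                condition=net.condition,
                n_nodes=len(keep),
                edges=[(remap[u], remap[v], l) for u, v, l in net.edges],
                node_coords=(
                    [net.node_coords[i] for i in keep]
                    if net.node_coords is not None else None
                ),
            )
        networks.append(net)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} isolated node(s) before filtering",
            stacklevel=2,
        )
    return NetworkDataset(networks=networks, provenance=list(dataset.provenance),
                          filter_log=list(dataset.filter_log))


def filter_long_two_node(
    dataset: NetworkDataset, max_length: float = DEFAULT_TWO_NODE_MAX_UM
) -> NetworkDataset:
    """Remove 2-node, 1-edge components strictly longer than ``max_length`` μm.

    Only components with exactly two nodes and exactly one edge are eligible;
    a long branched component is never touched.  Removals are appended to the
    dataset's ``filter_log``.
    """
    if max_length < 0:
        raise ValidationError(f"max_length must be >= 0, got {max_length}")
    dataset = drop_isolated_nodes(dataset)
    networks = []
    log = list(dataset.filter_log)
    for net in dataset:
        comps = connected_components(net)
        doomed = [
            c for c in comps
            if c.n_nodes == 2 and c.n_edges == 1 and c.length > max_length
        ]
        for c in doomed:
            log.append({
                "filter": "long_two_node",
                "cell_id": net.cell_id,
                "n_nodes": c.n_nodes,
                "n_edges": c.n_edges,
                "length": c.length,
            })
        networks.append(_remove_components(net, doomed) if doomed else net)
    return NetworkDataset(networks=networks,
                          provenance=list(dataset.provenance), filter_log=log)


def length_frequency_table(
    dataset: NetworkDataset, precision: int = DEFAULT_LENGTH_PRECISION
) -> pd.DataFrame:
    """Occurrence counts of rounded component lengths pooled over all cells.

    Returns a DataFrame with columns ``length_key``, ``count`` and
    ``fraction`` (count / total components), sorted by descending count.
    """
    keys: list[float] = []
    for net in dataset:
        keys.extend(c.length_key for c in connected_components(net, precision))
    if not keys:
        return pd.DataFrame(columns=["length_key", "count", "fraction"])
    counts = pd.Series(keys).value_counts()
    table = counts.rename_axis("length_key").reset_index(name="count")
    table["fraction"] = table["count"] / len(keys)
    return table


def filter_repeating_components(
    dataset: NetworkDataset,
    freq_threshold: float = DEFAULT_REPEAT_FRACTION,
    precision: int = DEFAULT_LENGTH_PRECISION,
) -> NetworkDataset:
    """Remove components whose rounded length repeats too often dataset-wide.

    A frequency table of rounded component lengths is built once over every
    component pooled across all cells; every component whose length-key
    fraction is strictly greater than ``freq_threshold`` is removed from every
    cell.  A key must actually repeat (count >= 2) to qualify: a unique
    length is never an artifact of this class, however small the dataset.
    Frequencies are *not* recomputed after removals (single pass).
    """
    if not 0 <= freq_threshold <= 1:
        raise ValidationError(
            f"freq_threshold must be in [0, 1], got {freq_threshold}")
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    dataset = drop_isolated_nodes(dataset)
    table = length_frequency_table(dataset, precision)
    over = set(table.loc[(table["fraction"] > freq_threshold)
                         & (table["count"] >= 2), "length_key"])
    networks = []
    log = list(dataset.filter_log)
    for net in dataset:
        comps = connected_components(net, precision)
        doomed = [c for c in comps if c.length_key in over]
        for c in doomed:
            log.append({
                "filter": "repeating_component",
                "cell_id": net.cell_id,
                "n_nodes": c.n_nodes,
                "n_edges": c.n_edges,
                "length": c.length,
                "length_key": c.length_key,
            })
        networks.append(_remove_components(net, doomed) if doomed else net)
    return NetworkDataset(networks=networks,
                          provenance=list(dataset.provenance), filter_log=log)


def length_histogram(
    dataset: NetworkDataset, bin_width: float = 0.5
) -> pd.DataFrame:
    """Histogram of pooled component lengths, for the 'shoulder' diagnostic.

    Bins are ``[k*bin_width, (k+1)*bin_width)`` from zero to past the longest
    component.  Comparing the histogram before and after
    :func:`filter_repeating_components` shows whether a sub-1 μm artifact mode
    was removed.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be > 0, got {bin_width}")
    lengths: list[float] = []
    for net in dataset:
        lengths.extend(c.length for c in connected_components(net))
    if not lengths:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    n_bins = int(np.floor(max(lengths) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
    })
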