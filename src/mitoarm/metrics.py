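"""Per-cell morphometrics of mitochondrial networks and group statistics.

The metric suite quantifies the fission/fusion balance of one cell's
mitochondrial network:

* **PHI** — fraction of total mitochondrial length in the largest connected
  component ("largest" by summed length).  1 means a fully fused network.
* **Average edge length** — total length / number of edges (μm).
* **Average degree** — Σₖ k·P(k) over the node degree distribution P(k);
  when only degrees {1, 3, 4} occur (free ends, 3-way and 4-way junctions,
  the degrees a skeletonization produces for trees) this is
  FreeEnds·1 + 3way·3 + 4way·4.
* **Length-normalized counts** — nodes, edges and connected components per μm
  of network, which rise with fragmentation and branching.
* **Connectivity score** — (PHI + avg edge length + avg degree) /
  (nodes/μm + edges/μm + components/μm): pro-fusion factors over pro-fission
  factors.  The score mixes μm- and μm⁻¹-bearing terms, so values are
  comparable only under a fixed unit convention (μm throughout).

Group comparisons use one-way ANOVA with Tukey HSD post hoc tests.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError, ValidationError
from .filters import connected_components
from .io import MitoNetwork, NetworkDataset

__all__ = [
    "CellMetrics",
    "GroupComparison",
    "compute_phi",
    "compute_avg_edge_length",
    "compute_densities",
    "compute_degree_metrics",
    "connectivity_score",
    "compute_cell_metrics",
    "compute_dataset_metrics",
    "compare_groups",
    "correlate_metrics",
]


@dataclass(frozen=True)
class CellMetrics:
    """The full morphometric readout for one cell."""

    cell_id: str
    condition: str
    total_length: float
    phi: float
    avg_edge_length: float
    avg_degree: float
    nodes_per_um: float
    edges_per_um: float
    cc_per_um: float
    free_end_frac: float
    threeway_frac: float
    fourway_frac: float
    connectivity_score: float


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA + Tukey HSD summary for one metric across conditions."""

    metric: str
    group_stats: pd.DataFrame   # condition, n, mean, sd
    omnibus_p: float
    pairwise: pd.DataFrame      # group1, group2, meandiff, p_adj, reject
    degenerate: bool = False    # True when within-group variance was zero


def _node_degrees(net: MitoNetwork) -> np.ndarray:
    """Degree of every node; a self-loop contributes 2 to its node."""
    deg = np.zeros(net.n_nodes, dtype=int)
    for u, v, _ in net.edges:
        deg[u] += 1
        deg[v] += 1
    return deg


def compute_phi(net: MitoNetwork) -> float:
    """Length fraction of the largest (by length) connected component."""
    total = net.total_length
    if total <= 0:
        raise UndefinedMetricError(
            f"{net.cell_id}: PHI undefined for zero total length")
    comps = connected_components(net)
    # denominator from the same per-component sums as the numerator, so a
    # single-component network yields exactly 1.0
    return comps[0].length / sum(c.length for c in comps)


def compute_avg_edge_length(net: MitoNetwork) -> float:
    """Total network length divided by edge count (μm)."""
    if net.n_edges == 0:
        raise UndefinedMetricError(
            f"{net.cell_id}: average edge length undefined with zero edges")
    return net.total_length / net.n_edges


def compute_densities(net: MitoNetwork) -> tuple[float, float, float]:
    """(nodes/μm, edges/μm, components/μm), each normalized by total length."""
    total = net.total_length
    if total <= 0:
        raise UndefinedMetricError(
            f"{net.cell_id}: densities undefined for zero total length")
    n_cc = len(connected_components(net))
    return net.n_nodes / total, net.n_edges / total, n_cc / total


def compute_degree_metrics(
    net: MitoNetwork,
) -> tuple[dict[int, float], float, float, float, float]:
    """Degree distribution and degree-derived summary metrics.

    Returns ``(P, free_end_frac, threeway_frac, fourway_frac, avg_degree)``
    where ``P[k]`` is the proportion of nodes of degree k.  The average degree
    is Σₖ k·P(k) over *all* observed degrees; on graphs whose degrees are a
    subset of {1, 3, 4} this equals the free-end/junction-weighted sum
    exactly.
    """
    if net.n_nodes == 0:
        raise UndefinedMetricError(
            f"{net.cell_id}: degree metrics undefined with zero nodes")
    deg = _node_degrees(net)
    counts = Counter(int(k) for k in deg)
    n = net.n_nodes
    p = {k: c / n for k, c in sorted(counts.items())}
    avg_degree = float(sum(k * pk for k, pk in p.items()))
    return p, p.get(1, 0.0), p.get(3, 0.0), p.get(4, 0.0), avg_degree


def connectivity_score(
    phi: float,
    avg_edge_length: float,
    avg_degree: float,
    nodes_per_um: float,
    edges_per_um: float,
    cc_per_um: float,
) -> float:
    """Pro-fusion factors over pro-fission factors.

    (PHI + average edge length + average degree) divided by the sum of the
    three length-normalized counts.  High values indicate a fused, elongated,
    branched network; low values a fragmented one.
    """
    for name, v in [("phi", phi), ("avg_edge_length", avg_edge_length),
                    ("avg_degree", avg_degree), ("nodes_per_um", nodes_per_um),
                    ("edges_per_um", edges_per_um), ("cc_per_um", cc_per_um)]:
        if not np.isfinite(v):
            raise ValidationError(f"{name} is not finite: {v}")
    denom = nodes_per_um + edges_per_um + cc_per_um
    if denom <= 0:
        raise UndefinedMetricError("connectivity score: zero denominator")
    return (phi + avg_edge_length + avg_degree) / denom


def compute_cell_metrics(net: MitoNetwork) -> CellMetrics:
    """Compute the full metric suite for one cell.

    Raises :class:`UndefinedMetricError` for degenerate cells (no edges or
    zero total length); callers assembling group statistics should exclude
    such cells (see :func:`compute_dataset_metrics`).
    """
    phi = compute_phi(net)
    ael = compute_avg_edge_length(net)
    nd, ed, cd = compute_densities(net)
    _, free_f, three_f, four_f, avg_deg = compute_degree_metrics(net)
    return CellMetrics(
        cell_id=net.cell_id,
        condition=net.condition,
        total_length=net.total_length,
        phi=phi,
        avg_edge_length=ael,
        avg_degree=avg_deg,
        nodes_per_um=nd,
        edges_per_um=ed,
        cc_per_um=cd,
        free_end_frac=free_f,
        threeway_frac=three_f,
        fourway_frac=four_f,
        connectivity_score=connectivity_score(phi, ael, avg_deg, nd, ed, cd),
    )


def compute_dataset_metrics(dataset: NetworkDataset) -> pd.DataFrame:
    """One row of :class:`CellMetrics` per cell.

    Cells left degenerate by filtering (no edges) are excluded with a
    warning: their metrics are undefined and silent zeros would bias group
    statistics.
    """
    rows, skipped = [], []
    for net in dataset:
        try:
            rows.append(asdict(compute_cell_metrics(net)))
        except UndefinedMetricError:
            skipped.append(net.cell_id)
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} degenerate cell(s) with no edges: "
            f"{skipped}", stacklevel=2)
    return pd.DataFrame(rows)


def compare_groups(metrics: pd.DataFrame, metric: str,
                   alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD across conditions for one metric.

    ``metrics`` is the output of :func:`compute_dataset_metrics` (needs the
    ``condition`` column).  When every group has zero internal variance the
    F statistic is undefined; the comparison is flagged ``degenerate`` with
    NaN p-values rather than raising.
    """
    if metric not in metrics.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    groups = {c: g[metric].to_numpy(float)
              for c, g in metrics.groupby("condition", sort=False)}
    if len(groups) < 2:
        raise ValidationError("need at least 2 conditions")
    for cond, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(
                f"condition {cond!r} has {len(vals)} cell(s); need >= 2")
    stats_rows = [
        {"condition": c, "n": len(v), "mean": float(np.mean(v)),
         "sd": float(np.std(v, ddof=1))}
        for c, v in groups.items()
    ]
    group_stats = pd.DataFrame(stats_rows)
    conds = list(groups)
    if all(np.ptp(v) == 0 for v in groups.values()):
        pairwise = pd.DataFrame([
            {"group1": a, "group2": b,
             "meandiff": float(groups[b].mean() - groups[a].mean()),
             "p_adj": float("nan"), "reject": False}
            for i, a in enumerate(conds) for b in conds[i + 1:]
        ])
        return GroupComparison(metric, group_stats, float("nan"),
                               pairwise, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, omnibus_p = stats.f_oneway(*groups.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    tukey = pairwise_tukeyhsd(
        endog=metrics[metric].to_numpy(float),
        groups=metrics["condition"].to_numpy(str),
        alpha=alpha,
    )
    pairwise = pd.DataFrame(
        tukey.summary().data[1:],
        columns=[str(c) for c in tukey.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return GroupComparison(metric, group_stats, float(omnibus_p), pairwise)


def correlate_metrics(x, y, on_means: pd.Series | None = None
                      ) -> tuple[float, float]:
    """Pearson correlation and its square for paired per-cell values.

    If ``on_means`` (a condition label per observation) is given, x and y are
    first collapsed to per-condition means — the convention used when a trend
    is computed over population means rather than single cells.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if on_means is not None:
        df = pd.DataFrame({"x": x, "y": y, "g": np.asarray(on_means)})
        agg = df.groupby("g", sort=False).mean()
        x, y = agg["x"].to_numpy(), agg["y"].to_numpy()
    if len(x) < 3:
        raise ValidationError(f"need >= 3 paired values, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r
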