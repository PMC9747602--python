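"""Seedable synthetic-data generators for every analysis stage.

Real inputs to this package come from microscopy segmentation (per-cell
mitochondrial graphs) and from NMR / fluorescence instruments.  These
generators emit inputs with the same statistical structure, plus a
ground-truth ledger, so the whole pipeline can be exercised and scored
without raw data:

* networks — per cell, a Poisson number of random tree components (degrees
  in {1, 3, 4}) with i.i.d. log-normal edge lengths, plus the two artifact
  classes the filters target: tiny components sharing one exact repeated
  length, and spurious 2-node segments longer than 100 μm;
* quench series — linear Stern–Volmer ratios with Gaussian noise;
* melt curves — two-state logistic 330/350 ratio curves;
* relaxation — single-exponential decays on standard delay grids, with
  duplicated delays for the empirical error check;
* hetNOE — reference/saturated intensity pairs with region-structured true
  ratios;
* shift tables — paired per-residue shift tables whose differences follow a
  region-structured perturbation model (arm-skewed by default).

Module constants record the reference experimental conditions the study
domain works with (quench constants, melting midpoints, NOE region means,
delay grids) so generator defaults match realistic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MitoNetwork, NetworkDataset

__all__ = [
    "NetworkGenParams",
    "generate_networks",
    "generate_quench",
    "generate_melt",
    "generate_relaxation",
    "generate_hetnoe",
    "generate_shift_tables",
    "generate_emission",
    "ACRYLAMIDE_CONCENTRATIONS_M",
    "WT_KSV_PER_M",
    "DELTA_N_KSV_PER_M",
    "WT_TM_C",
    "DELTA_N_TM_C",
    "MELT_SCAN_RANGE_C",
    "R1_DELAYS_MS",
    "R2_DELAYS_MS",
    "HETNOE_ARM_MEANS",
    "HETNOE_ARM_SDS",
    "ARM_RESIDUES",
]

# Reference experimental conditions (construct WT = full-length with the
# N-terminal arm; dN = arm-deleted).
ACRYLAMIDE_CONCENTRATIONS_M = (0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)
WT_KSV_PER_M = 3.50
DELTA_N_KSV_PER_M = 4.68
WT_TM_C = 82.4
DELTA_N_TM_C = 79.6
MELT_SCAN_RANGE_C = (25.0, 95.0)
R1_DELAYS_MS = (20.0, 60.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1200.0)
R2_DELAYS_MS = (17.6, 35.2, 52.8, 88.0, 123.2, 158.4)
# Mean steady-state NOE ratio of arm residues under the three buffer regimes:
# the arm-in structure's buffer (IN), the arm-out structure's buffer (OUT),
# and physiological pH (PHYS).
HETNOE_ARM_MEANS = {"IN": 0.80, "OUT": 0.77, "PHYS": 0.60}
HETNOE_ARM_SDS = {"IN": 0.10, "OUT": 0.09, "PHYS": 0.13}
ARM_RESIDUES = tuple(range(1, 9))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# mitochondrial network generator

@dataclass
class NetworkGenParams:
    """Settings for the per-cell mitochondrial graph generator.

    ``fragmentation`` is a dimensionless dial (1.0 = baseline) emulating
    fission at constant mitochondrial mass: it multiplies the expected
    component count per cell and divides the edge-length scale by the same
    factor, so expected total length per cell is conserved while the network
    splits into more, shorter pieces.  ``condition_effects`` maps each
    condition label to per-condition (fragmentation, branching) multipliers.
    Artifact counts are per cell.
    """

    n_cells_per_condition: int = 30
    condition_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (1.0, 1.0)})
    components_per_cell: float = 25.0        # Poisson mean of true components
    fragmentation: float = 1.0
    branching_prob: float = 0.25             # growing node becomes a junction
    fourway_prob: float = 0.10               # a junction is 4-way, else 3-way
    edge_length_log_mu: float = 1.0          # ln-scale: median edge ~2.7 um
    edge_length_log_sigma: float = 0.6
    max_nodes_per_component: int = 60
    n_repeat_artifacts: int = 0              # tiny repeated-length components
    artifact_length_um: float = 0.5
    n_long_two_node: int = 0                 # spurious long 2-node segments
    long_length_range_um: tuple[float, float] = (100.0, 300.0)

    def validate(self) -> None:
        if not 0 <= self.branching_prob <= 1 or not 0 <= self.fourway_prob <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.edge_length_log_sigma <= 0:
            raise ValidationError("edge_length_log_sigma must be > 0")
        if min(self.n_cells_per_condition, self.n_repeat_artifacts,
               self.n_long_two_node) < 0:
            raise ValidationError("counts must be >= 0")
        if self.components_per_cell < 0 or self.fragmentation < 0:
            raise ValidationError("rates must be >= 0")
        lo, hi = self.long_length_range_um
        if not (hi > lo > 0):
            raise ValidationError("long_length_range_um must be increasing")


def _grow_tree(rng, branching_prob, fourway_prob, edge_mu, edge_sigma,
               max_nodes, node_offset):
    """Grow one random tree component; returns (n_nodes, edges)."""
    n_nodes = 2  # root plus first child: at least one edge
    edges = [(node_offset, node_offset + 1,
              float(rng.lognormal(edge_mu, edge_sigma)))]
    frontier = [node_offset + 1]
    while frontier and n_nodes < max_nodes:
        node = frontier.pop(0)
        if rng.random() < branching_prob:
            n_children = 3 if rng.random() < fourway_prob else 2
            for _ in range(n_children):
                if n_nodes >= max_nodes:
                    break
                child = node_offset + n_nodes
                edges.append((node, child,
                              float(rng.lognormal(edge_mu, edge_sigma))))
                frontier.append(child)
                n_nodes += 1
    return n_nodes, edges


def generate_networks(
    params: NetworkGenParams, seed
) -> tuple[NetworkDataset, pd.DataFrame]:
    """Generate a multi-condition dataset of synthetic cell networks.

    Returns ``(dataset, ledger)`` where the ledger has one row per
    component with columns ``cell_id, condition, kind, length, n_nodes,
    n_edges``; ``kind`` is ``true``, ``repeat_artifact`` or
    ``long_two_node``, sufficient to score filter sensitivity and
    specificity exactly.
    """
    params.validate()
    rng = _rng(seed)
    networks, ledger_rows = [], []
    for condition, (frag_mult, branch_mult) in params.condition_effects.items():
        frag = params.fragmentation * frag_mult
        branch = min(params.branching_prob * branch_mult, 1.0)
        # fission at constant mass: more components, proportionally shorter
        edge_mu = params.edge_length_log_mu - (np.log(frag) if frag > 0
                                               else 0.0)
        for i in range(params.n_cells_per_condition):
            cell_id = f"{condition}_cell{i:03d}"
            edges: list[tuple[int, int, float]] = []
            offset = 0

            def add_component(kind, comp_edges, n_nodes):
                nonlocal offset
                edges.extend(comp_edges)
                length = sum(l for _, _, l in comp_edges)
                ledger_rows.append({
                    "cell_id": cell_id, "condition": condition, "kind": kind,
                    "length": float(length), "n_nodes": n_nodes,
                    "n_edges": len(comp_edges),
                })
                offset += n_nodes

            n_components = rng.poisson(params.components_per_cell * frag)
            for _ in range(n_components):
                n_nodes, comp_edges = _grow_tree(
                    rng, branch, params.fourway_prob,
                    edge_mu, params.edge_length_log_sigma,
                    params.max_nodes_per_component, offset)
                add_component("true", comp_edges, n_nodes)
            for _ in range(params.n_repeat_artifacts):
                add_component(
                    "repeat_artifact",
                    [(offset, offset + 1, params.artifact_length_um)], 2)
            lo, hi = params.long_length_range_um
            for _ in range(params.n_long_two_node):
                length = float(rng.uniform(lo, hi))
                add_component("long_two_node",
                              [(offset, offset + 1, length)], 2)
            networks.append(MitoNetwork(
                cell_id=cell_id, condition=condition,
                n_nodes=offset, edges=edges))
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["cell_id", "condition", "kind", "length",
                 "n_nodes", "n_edges"])
    return NetworkDataset(networks=networks,
                          provenance=["synthetic"]), ledger


# ---------------------------------------------------------------------------
# fluorescence generators

def generate_quench(
    true_ksv: float = WT_KSV_PER_M,
    concentrations_m=ACRYLAMIDE_CONCENTRATIONS_M,
    noise_sd: float = 0.01,
    seed=0,
) -> pd.DataFrame:
    """Linear Stern–Volmer ratios with Gaussian noise.

    F₀/F = 1 + Ksv·[Q] + ε, with the zero-quencher point fixed at exactly 1
    (it defines the ratio).  Columns: ``conc_M, F0_over_F``.
    """
    rng = _rng(seed)
    c = np.asarray(concentrations_m, dtype=float)
    y = 1.0 + true_ksv * c
    noise = rng.normal(0.0, noise_sd, size=len(c)) if noise_sd > 0 else 0.0
    y = y + noise
    y[c == 0] = 1.0
    return pd.DataFrame({"conc_M": c, "F0_over_F": y})


def generate_melt(
    true_tm: float = WT_TM_C,
    width_c: float = 2.0,
    scan_range_c: tuple[float, float] = MELT_SCAN_RANGE_C,
    step_c: float = 0.1,
    baseline: float = 0.8,
    amplitude: float = 0.2,
    baseline_slope: float = 0.0,
    noise_sd: float = 0.0,
    seed=0,
) -> pd.DataFrame:
    """Two-state logistic 330/350 nm ratio melt curve.

    ratio(T) = baseline + amplitude / (1 + exp(−(T − Tm)/width)) + slope·ΔT
    (+ noise).  The derivative of the logistic term is maximal exactly at
    the midpoint Tm.  Columns: ``temp_C, ratio``.
    """
    rng = _rng(seed)
    lo, hi = scan_range_c
    if not lo < true_tm < hi:
        raise ValidationError("true_tm must lie inside the scan range")
    n = int(round((hi - lo) / step_c)) + 1
    t = np.linspace(lo, hi, n)
    ratio = baseline + amplitude / (1 + np.exp(-(t - true_tm) / width_c)) \
        + baseline_slope * (t - lo)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"temp_C": t, "ratio": ratio})


def generate_emission(
    peak_nm: float = 337.0,
    peak_intensity: float = 3e4,
    width_nm: float = 25.0,
    wavelengths_nm=None,
    buffer_level: float = 500.0,
    noise_sd: float = 0.0,
    seed=0,
) -> pd.DataFrame:
    """Gaussian tryptophan emission band plus a flat buffer background.

    Columns: ``wavelength_nm, intensity, buffer`` (intensity includes the
    buffer background, so subtracting ``buffer`` recovers the band).
    """
    rng = _rng(seed)
    wl = (np.arange(300.0, 400.5, 0.5) if wavelengths_nm is None
          else np.asarray(wavelengths_nm, dtype=float))
    band = peak_intensity * np.exp(-0.5 * ((wl - peak_nm) / width_nm) ** 2)
    buffer = np.full_like(wl, buffer_level)
    intensity = band + buffer
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(wl))
    return pd.DataFrame({"wavelength_nm": wl, "intensity": intensity,
                         "buffer": buffer})


# ---------------------------------------------------------------------------
# NMR generators

def generate_relaxation(
    true_rates: dict[int, float],
    delays_ms=R1_DELAYS_MS,
    duplicate_delays_ms=(R1_DELAYS_MS[0], R1_DELAYS_MS[5]),
    amplitude: float = 1e5,
    noise_frac: float = 0.02,
    seed=0,
) -> pd.DataFrame:
    """Single-exponential decays per residue on a relaxation delay grid.

    ``true_rates`` maps residue number to R (s⁻¹).  Delays listed in
    ``duplicate_delays_ms`` are recorded twice, mirroring the duplicate
    time points used for empirical error analysis.  Noise is Gaussian with
    SD = ``noise_frac`` × amplitude.  Columns:
    ``residue, delay_ms, intensity``.
    """
    rng = _rng(seed)
    delays = list(delays_ms) + [d for d in duplicate_delays_ms
                                if d in delays_ms]
    rows = []
    for residue, rate in true_rates.items():
        for d in delays:
            clean = amplitude * np.exp(-rate * d / 1000.0)
            noisy = clean + (rng.normal(0.0, noise_frac * amplitude)
                             if noise_frac > 0 else 0.0)
            rows.append({"residue": residue, "delay_ms": float(d),
                         "intensity": float(noisy)})
    return pd.DataFrame(rows)


def generate_hetnoe(
    regions: pd.DataFrame,
    region_means: dict[str, float] | None = None,
    region_sds: dict[str, float] | None = None,
    ref_intensity: float = 1e6,
    intensity_noise_frac: float = 0.01,
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reference/saturated intensity pairs with region-structured ratios.

    ``regions`` maps residues to region classes (columns
    ``residue, region``).  Each residue's true NOE ratio is drawn from a
    normal distribution with its region's mean and SD (defaults: arm under
    the IN-condition mean 0.80 SD 0.10; other regions 0.80 SD 0.05,
    rigid-backbone behaviour).  Returns ``(ref, noe, truth)`` where truth
    has columns ``residue, region, true_ratio``.
    """
    rng = _rng(seed)
    means = {"arm": HETNOE_ARM_MEANS["IN"], "helix": 0.80,
             "loop": 0.80, "terminus": 0.40}
    sds = {"arm": HETNOE_ARM_SDS["IN"], "helix": 0.05,
           "loop": 0.05, "terminus": 0.15}
    if region_means:
        means.update(region_means)
    if region_sds:
        sds.update(region_sds)
    rows_ref, rows_noe, rows_truth = [], [], []
    for row in regions.itertuples():
        mu, sd = means[row.region], sds[row.region]
        true_ratio = float(rng.normal(mu, sd))
        i_ref = ref_intensity * (1 + rng.normal(0, intensity_noise_frac))
        i_noe = true_ratio * ref_intensity * (
            1 + rng.normal(0, intensity_noise_frac))
        rows_ref.append({"residue": row.residue, "intensity": i_ref})
        rows_noe.append({"residue": row.residue, "intensity": i_noe})
        rows_truth.append({"residue": row.residue, "region": row.region,
                           "true_ratio": true_ratio})
    return (pd.DataFrame(rows_ref), pd.DataFrame(rows_noe),
            pd.DataFrame(rows_truth))


def generate_shift_tables(
    n_residues: int = 125,
    arm_residues=ARM_RESIDUES,
    n_terminus: int = 5,
    perturbation: dict[str, tuple[float, float, float, float]] | None = None,
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired shift tables with region-structured perturbations.

    Table ``a`` holds plausible backbone amide shifts (¹H ~ N(8.3, 0.5) ppm,
    ¹⁵N ~ N(119, 4) ppm); table ``b`` adds per-residue offsets drawn from a
    per-region model ``region -> (mean_H, sd_H, mean_N, sd_N)`` in ppm.  The
    default model is arm-skewed — arm residues shift systematically while
    helix/loop differences are zero-mean noise — mirroring the signature of
    a conformation change localized to the arm.  Regions: the arm residues,
    a ``terminus`` tail of ``n_terminus`` residues, and alternating
    helix/loop blocks of 10 in between.

    Returns ``(a, b, truth)``; truth has the per-residue true offsets.
    """
    rng = _rng(seed)
    model = {
        "arm": (0.10, 0.03, 0.50, 0.15),
        "helix": (0.0, 0.01, 0.0, 0.05),
        "loop": (0.0, 0.01, 0.0, 0.05),
        "terminus": (0.0, 0.02, 0.0, 0.10),
    }
    if perturbation:
        model.update(perturbation)
    arm = set(arm_residues)
    residues = np.arange(1, n_residues + 1)
    regions = []
    for r in residues:
        if r in arm:
            regions.append("arm")
        elif r > n_residues - n_terminus:
            regions.append("terminus")
        else:
            regions.append("helix" if ((r - 1) // 10) % 2 == 0 else "loop")
    amino = list("ACDEFGHIKLMNPQRSTVWY")
    restype = rng.choice(amino, size=n_residues)
    a = pd.DataFrame({
        "residue": residues,
        "restype": restype,
        "region": regions,
        "dH": rng.normal(8.3, 0.5, n_residues),
        "dN": rng.normal(119.0, 4.0, n_residues),
    })
    off_h = np.empty(n_residues)
    off_n = np.empty(n_residues)
    for i, region in enumerate(regions):
        mh, sh, mn, sn = model[region]
        off_h[i] = rng.normal(mh, sh)
        off_n[i] = rng.normal(mn, sn)
    b = a.copy()
    b["dH"] = a["dH"] + off_h
    b["dN"] = a["dN"] + off_n
    truth = pd.DataFrame({"residue": residues, "region": regions,
                          "true_dH_offset": off_h, "true_dN_offset": off_n})
    return a, b, truth
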