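"""Shift perturbations, region KDE, ensemble comparison, hetNOE, relaxation
fits and ensemble atom distances."""

import numpy as np
import pandas as pd
import pytest

from mitoarm.errors import ValidationError
from mitoarm.nmr import (
    chemical_shift_perturbation,
    delta_delta_delta,
    ensemble_atom_distances,
    fit_exponential_rate,
    hetnoe_ratios,
    kde_by_region,
    rule_of_thumb_bandwidth,
)
from mitoarm.simulate import (
    R1_DELAYS_MS,
    generate_hetnoe,
    generate_relaxation,
    generate_shift_tables,
)


def shift_table(residues, dh, dn):
    return pd.DataFrame({"residue": residues, "dH": dh, "dN": dn})


# --------------------------------------------------------------------------
# chemical shift perturbation

def test_csp_zero_on_identical_tables():
    a = shift_table([1, 2, 3], [8.1, 8.2, 8.3], [118.0, 119.0, 120.0])
    res = chemical_shift_perturbation(a, a.copy())
    assert np.allclose(res.per_residue["delta_total"], 0.0)
    assert res.mean == 0.0


def test_csp_default_weighting_formula():
    # dH difference 0.1, dN difference 0.5:
    # sqrt(5*0.01 + 0.25) = sqrt(0.30) = 0.5477...
    a = shift_table([1], [8.0], [119.0])
    b = shift_table([1], [8.1], [119.5])
    res = chemical_shift_perturbation(a, b)
    assert res.per_residue["delta_total"].iloc[0] == pytest.approx(
        np.sqrt(0.30), rel=1e-9)


def test_csp_alternative_weighting_scheme():
    a = shift_table([1], [8.0], [119.0])
    b = shift_table([1], [8.1], [119.5])
    res = chemical_shift_perturbation(a, b, h_weight=25.0)
    assert res.per_residue["delta_total"].iloc[0] == pytest.approx(
        np.sqrt(25 * 0.01 + 0.25))


def test_csp_symmetric_in_inputs():
    rng = np.random.default_rng(8)
    a = shift_table(range(1, 21), rng.normal(8.3, 0.4, 20),
                    rng.normal(119, 3, 20))
    b = shift_table(range(1, 21), rng.normal(8.3, 0.4, 20),
                    rng.normal(119, 3, 20))
    fwd = chemical_shift_perturbation(a, b)
    rev = chemical_shift_perturbation(b, a)
    assert np.allclose(fwd.per_residue["delta_total"],
                       rev.per_residue["delta_total"])


def test_csp_flags_invariant_under_global_offset():
    rng = np.random.default_rng(9)
    a = shift_table(range(1, 31), rng.normal(8.3, 0.4, 30),
                    rng.normal(119, 3, 30))
    b = shift_table(range(1, 31), rng.normal(8.3, 0.4, 30),
                    rng.normal(119, 3, 30))
    base = chemical_shift_perturbation(a, b)
    a2, b2 = a.copy(), b.copy()
    for t in (a2, b2):
        t["dH"] += 0.7
        t["dN"] -= 2.0
    shifted = chemical_shift_perturbation(a2, b2)
    assert (base.per_residue["exceeds_1sd"] ==
            shifted.per_residue["exceeds_1sd"]).all()
    assert (base.per_residue["exceeds_2sd"] ==
            shifted.per_residue["exceeds_2sd"]).all()


def test_csp_flags_recomputable_from_mean_sd():
    a, b, _ = generate_shift_tables(seed=12)
    res = chemical_shift_perturbation(a, b)
    expect_1sd = res.per_residue["delta_total"] > res.mean + res.sd
    expect_2sd = res.per_residue["delta_total"] > res.mean + 2 * res.sd
    assert (res.per_residue["exceeds_1sd"] == expect_1sd).all()
    assert (res.per_residue["exceeds_2sd"] == expect_2sd).all()


def test_csp_residue_offset_matching():
    # construct b numbered 9.. that matches a's 1.. via offset -8
    a = shift_table([9, 10], [8.0, 8.1], [119.0, 120.0])
    b = shift_table([1, 2], [8.0, 8.1], [119.0, 120.0])
    res = chemical_shift_perturbation(a, b, residue_offset=8)
    assert len(res.per_residue) == 2
    assert np.allclose(res.per_residue["delta_total"], 0.0)


def test_csp_no_matching_residues_rejected():
    a = shift_table([1], [8.0], [119.0])
    b = shift_table([2], [8.0], [119.0])
    with pytest.raises(ValidationError):
        chemical_shift_perturbation(a, b)


def test_csp_missing_dimension_excluded_with_warning():
    a = shift_table([1, 2], [8.0, np.nan], [119.0, 120.0])
    b = shift_table([1, 2], [8.0, 8.1], [119.0, 120.0])
    with pytest.warns(UserWarning, match="missing"):
        res = chemical_shift_perturbation(a, b)
    assert list(res.per_residue["residue"]) == [1]


# --------------------------------------------------------------------------
# kernel density

def test_single_point_kernel_closed_form():
    deltas = pd.DataFrame({"value": [0.3], "region": ["arm"]})
    with pytest.warns(UserWarning, match="bandwidth"):
        curve = kde_by_region(deltas, min_bandwidth=0.05)[0]
    h = curve.bandwidth
    assert h == 0.05
    f_at_x0 = np.interp(0.3, curve.grid, curve.density)
    assert f_at_x0 == pytest.approx(1 / (h * np.sqrt(2 * np.pi)), rel=1e-4)


def test_kde_integrates_to_one_per_region():
    a, b, _ = generate_shift_tables(seed=5)
    deltas = pd.DataFrame({"value": (b["dH"] - a["dH"]),
                           "region": a["region"]})
    for curve in kde_by_region(deltas):
        assert curve.integral() == pytest.approx(1.0, abs=0.01)


def test_identical_point_sets_identical_curves():
    vals = [0.1, 0.25, -0.05, 0.4]
    deltas = pd.DataFrame({
        "value": vals * 2,
        "region": ["arm"] * 4 + ["helix"] * 4,
    })
    arm, helix = kde_by_region(deltas)
    assert np.array_equal(arm.grid, helix.grid)
    assert np.array_equal(arm.density, helix.density)


def test_kde_matches_scipy_gaussian_kde_at_same_bandwidth():
    """Independent cross-check of the density formula."""
    from scipy.stats import gaussian_kde
    rng = np.random.default_rng(3)
    x = rng.normal(0.0, 0.2, 40)
    deltas = pd.DataFrame({"value": x, "region": ["loop"] * 40})
    h = 0.1
    curve = kde_by_region(deltas, bandwidth=h)[0]
    ref = gaussian_kde(x, bw_method=h / x.std(ddof=1))(curve.grid)
    assert np.allclose(curve.density, ref, atol=1e-8)


def test_bandwidth_rule_of_thumb_value():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    expected = 0.9 * min(sd, iqr / 1.34) * 100 ** (-0.2)
    assert rule_of_thumb_bandwidth(x) == pytest.approx(expected)


def test_arm_skewed_generator_displaces_arm_curve():
    """Arm-skewed perturbations shift the arm region's density mean away
    from zero while helix/loop stay centered."""
    a, b, _ = generate_shift_tables(seed=7)
    deltas = pd.DataFrame({"value": (b["dN"] - a["dN"]),
                           "region": a["region"]})
    curves = {c.label: c for c in kde_by_region(deltas)}

    def density_mean(c):
        return np.trapezoid(c.grid * c.density, c.grid) / c.integral()

    assert abs(density_mean(curves["arm"])) > \
        3 * abs(density_mean(curves["helix"]))
    assert abs(density_mean(curves["arm"])) > \
        3 * abs(density_mean(curves["loop"]))


# --------------------------------------------------------------------------
# experiment-vs-ensemble comparison

def _snapshots(values_by_residue, n, jitter, rng):
    tables = []
    for _ in range(n):
        tables.append(pd.DataFrame({
            "residue": list(values_by_residue),
            "dH": [v[0] + rng.normal(0, jitter)
                   for v in values_by_residue.values()],
            "dN": [v[1] + rng.normal(0, jitter)
                   for v in values_by_residue.values()],
        }))
    return tables


def test_identical_ensembles_give_zero_everywhere():
    rng = np.random.default_rng(2)
    vals = {1: (8.0, 119.0), 2: (8.5, 121.0)}
    snaps = _snapshots(vals, 3, 0.0, rng)
    exp = shift_table([1, 2], [8.2, 8.6], [119.5, 122.0])
    res = delta_delta_delta(exp, snaps, [t.copy() for t in snaps])
    assert np.allclose(res["ddd_dH"], 0.0)
    assert np.allclose(res["ddd_dN"], 0.0)


def test_experiment_on_in_mean_forces_nonnegative_values():
    rng = np.random.default_rng(4)
    out_snaps = _snapshots({1: (8.4, 120.0)}, 3, 0.0, rng)
    in_snaps = _snapshots({1: (8.0, 118.0)}, 3, 0.0, rng)
    exp = shift_table([1], [8.0], [118.0])  # equals the IN mean
    res = delta_delta_delta(exp, out_snaps, in_snaps)
    assert res["ddd_dH"].iloc[0] == pytest.approx(abs(8.4 - 8.0))
    assert res["ddd_dN"].iloc[0] == pytest.approx(abs(120.0 - 118.0))
    assert (res[["ddd_dH", "ddd_dN"]] >= 0).all().all()


def test_three_snapshot_hand_computation():
    out_snaps = [shift_table([1], [h], [n])
                 for h, n in [(8.1, 120.0), (8.3, 120.6), (8.2, 120.3)]]
    in_snaps = [shift_table([1], [h], [n])
                for h, n in [(7.9, 118.0), (8.0, 118.4), (8.1, 118.6)]]
    exp = shift_table([1], [8.05], [118.5])
    res = delta_delta_delta(exp, out_snaps, in_snaps)
    # hand: mean_out = (8.2, 120.3), mean_in = (8.0, 118.333...)
    # ddd_H = |8.2-8.05| - |8.0-8.05| = 0.15 - 0.05 = 0.10
    # ddd_N = |120.3-118.5| - |118.3333-118.5| = 1.8 - 0.16667 = 1.63333
    assert res["ddd_dH"].iloc[0] == pytest.approx(0.10)
    assert res["ddd_dN"].iloc[0] == pytest.approx(1.8 - 1 / 6, rel=1e-9)


def test_sign_positive_when_out_farther_than_in():
    rng = np.random.default_rng(14)
    for _ in range(20):
        exp_v = rng.normal(8.0, 0.3)
        d_in = abs(rng.normal(0, 0.1))
        d_out = d_in + abs(rng.normal(0.2, 0.05))
        out_snaps = [shift_table([1], [exp_v + d_out], [119.0])]
        in_snaps = [shift_table([1], [exp_v + d_in], [119.0])]
        exp = shift_table([1], [exp_v], [119.0])
        res = delta_delta_delta(exp, out_snaps, in_snaps)
        assert res["ddd_dH"].iloc[0] > 0


def test_residue_in_one_ensemble_only_excluded():
    out_snaps = [shift_table([1, 2], [8.0, 8.1], [119.0, 120.0])]
    in_snaps = [shift_table([1], [8.0], [119.0])]
    exp = shift_table([1, 2], [8.0, 8.1], [119.0, 120.0])
    with pytest.warns(UserWarning, match="excluded"):
        res = delta_delta_delta(exp, out_snaps, in_snaps)
    assert list(res["residue"]) == [1]


# --------------------------------------------------------------------------
# hetNOE

def test_hetnoe_ratio_identity_and_scaling():
    ref = pd.DataFrame({"residue": [1, 2], "intensity": [1e6, 2e6]})
    noe = pd.DataFrame({"residue": [1, 2], "intensity": [1e6, 1.6e6]})
    records, _ = hetnoe_ratios(ref, noe)
    assert records["ratio"].tolist() == pytest.approx([1.0, 0.8])


def test_hetnoe_region_means_exact_on_constant_ratio():
    residues = list(range(3, 9))
    ref = pd.DataFrame({"residue": residues, "intensity": [1e6] * 6})
    noe = pd.DataFrame({"residue": residues, "intensity": [8e5] * 6})
    regions = pd.DataFrame({"residue": residues, "region": ["arm"] * 6})
    _, summary = hetnoe_ratios(ref, noe, regions=regions)
    arm = summary.set_index("region").loc["arm"]
    assert arm["mean"] == pytest.approx(0.8)
    assert arm["sd"] == pytest.approx(0.0)


def test_hetnoe_zero_reference_excluded_with_warning():
    ref = pd.DataFrame({"residue": [1, 2], "intensity": [0.0, 1e6]})
    noe = pd.DataFrame({"residue": [1, 2], "intensity": [1e5, 8e5]})
    with pytest.warns(UserWarning, match="zero reference"):
        records, _ = hetnoe_ratios(ref, noe)
    assert list(records["residue"]) == [2]


def test_hetnoe_uncertainty_propagation():
    ref = pd.DataFrame({"residue": [1], "intensity": [1e6]})
    noe = pd.DataFrame({"residue": [1], "intensity": [8e5]})
    records, _ = hetnoe_ratios(ref, noe, noise_rms=1e4)
    expected = 0.8 * np.sqrt((1e4 / 8e5) ** 2 + (1e4 / 1e6) ** 2)
    assert records["ratio_err"].iloc[0] == pytest.approx(expected)


def test_hetnoe_generator_region_mean_recovered():
    """Noisy synthetic intensities recover the generator's true arm mean
    within 2 standard errors."""
    regions = pd.DataFrame({"residue": range(3, 9), "region": ["arm"] * 6})
    ratios = []
    rng = np.random.default_rng(20)
    for _ in range(60):
        ref, noe, _ = generate_hetnoe(regions, seed=rng)
        records, _ = hetnoe_ratios(ref, noe)
        ratios.extend(records["ratio"])
    ratios = np.asarray(ratios)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 0.80) <= 2 * se + 1e-9


# --------------------------------------------------------------------------
# relaxation fits

def test_noiseless_rate_recovered_to_high_precision():
    df = generate_relaxation({7: 2.0}, delays_ms=R1_DELAYS_MS, noise_frac=0.0)
    fit = fit_exponential_rate(df["delay_ms"], df["intensity"])
    assert fit.converged
    assert fit.rate == pytest.approx(2.0, rel=1e-7)
    assert fit.amplitude == pytest.approx(1e5, rel=1e-7)


def test_constant_intensities_give_zero_rate():
    delays = [20, 60, 100, 200]
    fit = fit_exponential_rate(delays, [5e4] * 4)
    assert fit.rate == pytest.approx(0.0, abs=1e-10)


def test_duplicate_delays_reported_as_empirical_scatter():
    df = generate_relaxation({1: 1.5}, noise_frac=0.01, seed=2)
    fit = fit_exponential_rate(df["delay_ms"], df["intensity"])
    assert np.isfinite(fit.duplicate_rmsd)
    assert fit.duplicate_rmsd >= 0


def test_rate_estimator_bias_below_one_percent_at_two_percent_noise():
    true_rate = 2.0
    rng = np.random.default_rng(31)
    estimates = []
    for _ in range(200):
        df = generate_relaxation({1: true_rate}, noise_frac=0.02, seed=rng)
        fit = fit_exponential_rate(df["delay_ms"], df["intensity"])
        assert fit.converged
        estimates.append(fit.rate)
    bias = abs(np.mean(estimates) - true_rate) / true_rate
    assert bias < 0.01


def test_too_few_distinct_delays_rejected():
    with pytest.raises(ValidationError):
        fit_exponential_rate([10, 10, 20], [3.0, 3.1, 2.0])


# --------------------------------------------------------------------------
# ensemble distances

PDB_2MODEL = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C
ENDMDL
END
"""


def test_three_four_five_triangle_distance(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(PDB_2MODEL)
    res = ensemble_atom_distances(p, [(1, "CA", 2, "CA")])
    assert res["mean"].iloc[0] == pytest.approx(5.0)
    assert res["sd"].iloc[0] == pytest.approx(0.0)
    assert res["n_models"].iloc[0] == 2


def test_single_model_sd_zero(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text("".join(PDB_2MODEL.splitlines(keepends=True)[:4]) + "END\n")
    res = ensemble_atom_distances(p, [(1, "CA", 2, "CA")])
    assert res["sd"].iloc[0] == 0.0
    assert res["n_models"].iloc[0] == 1


def test_multi_model_matches_brute_force_oracle(tmp_path):
    rng = np.random.default_rng(6)
    coords = rng.uniform(-10, 10, size=(5, 2, 3))  # 5 models, 2 atoms
    lines = []
    for m in range(5):
        lines.append(f"MODEL     {m + 1:4d}")
        for a in range(2):
            x, y, z = coords[m, a]
            resname = "ALA" if a == 0 else "GLY"
            lines.append(
                f"ATOM  {a + 1:5d}  CA  {resname} A{a + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
        lines.append("ENDMDL")
    lines.append("END")
    p = tmp_path / "ens.pdb"
    p.write_text("\n".join(lines) + "\n")
    res = ensemble_atom_distances(p, [(1, "CA", 2, "CA")])
    # PDB coordinates carry 3 decimals; the oracle uses the rounded values
    rounded = np.round(coords, 3)
    dists = np.linalg.norm(rounded[:, 0] - rounded[:, 1], axis=1)
    assert res["mean"].iloc[0] == pytest.approx(dists.mean(), rel=1e-6)
    assert res["sd"].iloc[0] == pytest.approx(dists.std(ddof=0), rel=1e-6)


def test_missing_atom_names_model_and_atom(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(PDB_2MODEL)
    with pytest.raises(ValidationError, match="CB"):
        ensemble_atom_distances(p, [(1, "CB", 2, "CA")])
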