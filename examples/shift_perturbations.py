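"""Chemical-shift perturbation analysis between two protein states.

Generates paired per-residue amide shift tables whose differences are
systematically skewed in the N-terminal arm (residues 1-8), computes the
combined 1H/15N perturbation per residue with 1-SD/2-SD flags, and compares
region-wise kernel densities of the raw nitrogen shift differences.
"""

import pandas as pd

from mitoarm.nmr import chemical_shift_perturbation, kde_by_region
from mitoarm.simulate import generate_shift_tables

state_a, state_b, _ = generate_shift_tables(seed=3)

csp = chemical_shift_perturbation(state_a, state_b)
print(f"mean perturbation {csp.mean:.3f} ppm, SD {csp.sd:.3f} ppm")
top = csp.per_residue[csp.per_residue["exceeds_2sd"]]
print(f"{len(top)} residue(s) perturbed beyond 2 SD:")
print(top[["residue", "delta_total"]].round(3).to_string(index=False))

deltas = pd.DataFrame({"value": state_b["dN"] - state_a["dN"],
                       "region": state_a["region"]})
for curve in kde_by_region(deltas):
    mode = curve.grid[curve.density.argmax()]
    print(f"region {curve.label:<8} N={curve.n:<4} bandwidth "
          f"{curve.bandwidth:.3f} ppm, density mode at {mode:+.3f} ppm")

# Helix and loop densities center near zero (random sample-to-sample
# differences); the arm density sits displaced from zero — the signature of
# a genuine conformational difference localized to the arm.  The residues
# flagged beyond 2 SD are overwhelmingly arm residues.
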