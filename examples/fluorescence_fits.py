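"""Stern-Volmer quenching constants and nanoDSF melting temperatures.

Compares a full-length construct (arm shields the tryptophan; Ksv 3.50 M^-1,
Tm 82.4 degC) against an arm-deleted construct (more solvent-exposed and
less stable; Ksv 4.68 M^-1, Tm 79.6 degC) on synthetic data with realistic
noise.
"""

from mitoarm.fluorescence import melting_temperature, stern_volmer_fit
from mitoarm.simulate import (
    DELTA_N_KSV_PER_M, DELTA_N_TM_C, WT_KSV_PER_M, WT_TM_C,
    generate_melt, generate_quench,
)

for name, ksv, tm, seed in [("full-length", WT_KSV_PER_M, WT_TM_C, 1),
                            ("arm-deleted", DELTA_N_KSV_PER_M, DELTA_N_TM_C, 2)]:
    quench = generate_quench(true_ksv=ksv, noise_sd=0.01, seed=seed)
    fit = stern_volmer_fit(quench["conc_M"], quench["F0_over_F"])
    melt = generate_melt(true_tm=tm, noise_sd=0.002, seed=seed)
    mfit = melting_temperature(melt["temp_C"], melt["ratio"])
    print(f"{name}: Ksv = {fit.ksv:.2f} +/- {fit.ksv_err:.2f} M^-1 "
          f"(true {ksv}), Tm = {mfit.tm:.1f} degC (true {tm})")

# The arm-deleted construct quenches more efficiently (higher Ksv: the
# tryptophan is more accessible to acrylamide) and unfolds ~3 degC earlier —
# both consistent with the arm packing against the core in the full-length
# protein.
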