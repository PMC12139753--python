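"""Unit conversions used throughout the package.

Internal coordinates are in nanometres, time in seconds.  Bimolecular rate
constants are configured in uM^-1 s^-1 and converted to nm^3/s for the
particle-level acceptance-probability calibration.
"""

AVOGADRO = 6.02214076e23

# 1 uM^-1 s^-1 = 1e6 L mol^-1 s^-1 = 1e6 * 1e24 nm^3 / AVOGADRO  per second
UM_S_TO_NM3_S = 1e6 * 1e24 / AVOGADRO  # ~1.6605e6 nm^3/s

NM2_PER_UM2 = 1e6
NM_PER_UM = 1e3
NM3_PER_UM3 = 1e9


def um2_s_to_nm2_s(d_um2_s: float) -> float:
    return d_um2_s * NM2_PER_UM2


def rate_uM_to_nm3(k_uM_s: float) -> float:
    return k_uM_s * UM_S_TO_NM3_S


def molecules_per_um3_to_uM(n_per_um3: float) -> float:
    # 1 molecule / um^3 = 1e15 / L; in mol/L divide by Avogadro; in uM * 1e6
    return n_per_um3 * 1e15 / AVOGADRO * 1e6
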