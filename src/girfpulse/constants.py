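"""Physical constants and unit conversions.

Internal computations use SI units throughout (T, T/m, s, rad, m); the
public I/O surface speaks the units customary in pulse design (uT, mT/m,
ms, mm).
"""

#: Gyromagnetic ratio of 1H in rad/s/T.
GAMMA_1H = 267.522187e6

#: gamma-bar = gamma / (2 pi), in Hz/T.
GAMMA_BAR_1H = GAMMA_1H / (2.0 * 3.141592653589793)

UT_PER_T = 1e6
T_PER_UT = 1e-6
MT_M_PER_T_M = 1e3
T_M_PER_MT_M = 1e-3
MS_PER_S = 1e3
MM_PER_M = 1e3
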