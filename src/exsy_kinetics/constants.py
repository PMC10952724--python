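"""Physical constants used throughout the package (SI units)."""

#: Gyromagnetic ratio of 19F, rad s^-1 T^-1.
GAMMA_F19 = 2.5181e8

#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34

#: mu_0 / 4 pi, T^2 J^-1 m^3.
MU0_OVER_4PI = 1.0e-7

#: Default 19F transmitter frequency, Hz (400 MHz-class spectrometer).
DEFAULT_F19_LARMOR_HZ = 376.46e6
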