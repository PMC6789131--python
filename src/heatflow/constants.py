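"""Physical constants and unit conversions.

Package-wide unit system: energies in eV, temperatures in K, times in ps,
lengths in nm, masses in atomic mass units (u).
"""

#: Boltzmann constant, eV/K (CODATA 2018, exact).
K_B = 8.617333262e-5

#: Conversion factor: 1 u nm^2 ps^-2 expressed in eV.
#: 1 u = 1.66053906660e-27 kg; 1 nm^2 ps^-2 = 1e6 m^2 s^-2;
#: divided by the elementary charge 1.602176634e-19 C.
EV_PER_U_NM2_PS2 = 1.0364269574e-2

#: Inverse conversion: 1 eV expressed in u nm^2 ps^-2.
U_NM2_PS2_PER_EV = 1.0 / EV_PER_U_NM2_PS2
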