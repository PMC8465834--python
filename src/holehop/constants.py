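"""Physical constants used across the package (CODATA values, fixed)."""

#: Boltzmann constant in eV/K.
KB_EV_PER_K = 8.617333262e-5

#: Coulomb constant for charges in elementary charge units and distances in
#: Angstrom, giving potentials in volts: V = KE * sum(q_i / r_i).
KE_V_ANG_PER_E = 14.399645

#: Speed of light in cm/s.
C_CM_PER_S = 2.99792458e10

#: Conversion from frequency in THz (= 1/ps) to wavenumber in cm^-1:
#: nu~ [cm^-1] = f [THz] * 1e12 / c [cm/s].
THZ_TO_WAVENUMBER = 1.0e12 / C_CM_PER_S  # = 33.35641...
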