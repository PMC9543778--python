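"""Physical constants and unit helpers.

Internal unit contract: lengths in nm, forces in pN, times in s, temperatures
in K.  Thermal energy kB*T is therefore carried in pN*nm (1 J = 1e21 pN*nm),
which makes kB*T/p directly a force in pN.  Cantilever spring constants are
exposed in N/m (the field's convention); 1 N/m = 1000 pN/nm.
"""

#: Boltzmann constant, J/K (2019 SI exact value).
KB = 1.380649e-23

#: Joule -> pN*nm
J_TO_PN_NM = 1e21

#: N/m -> pN/nm
NM_TO_PN_PER_NM = 1000.0


def kbt_pn_nm(temperature: float) -> float:
    """Thermal energy kB*T in pN*nm at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature * J_TO_PN_NM


def kbt_joule(temperature: float) -> float:
    """Thermal energy kB*T in J at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
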