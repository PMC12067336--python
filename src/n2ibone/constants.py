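"""Physical constants used across the simulation and calibration modules.

Mass attenuation coefficients (µ/ρ, cm² g⁻¹) are log-log interpolations of the
NIST X-ray attenuation tables (Hubbell & Seltzer) at 24 keV, the beam energy
assumed throughout.  They are packaged defaults; every function that consumes
them accepts user overrides.
"""

# µ/ρ at 24 keV, cm² g⁻¹
MASS_ATTENUATION_24KEV: dict[str, float] = {
    "water": 0.573,
    "alumina": 1.376,
    "hydroxyapatite": 2.317,
    "cortical_bone": 2.441,
}

# bulk densities, g cm⁻³
DENSITY_G_CM3: dict[str, float] = {
    "water": 1.000,
    "alumina": 3.95,
    "cortical_bone": 1.92,
}

#: target hydroxyapatite-equivalent density of healthy bovine cortical matrix,
#: mgHA cm⁻³ — the gray level of the default phantom matrix maps to this value
#: through the default mineral calibration.
REFERENCE_MATRIX_DENSITY_MGHA: float = 1226.0

#: recommended cumulative dose before measurable collagen damage in bone, kGy
DOSE_DAMAGE_THRESHOLD_KGY: float = 35.0

#: energy of one photon, J per keV
JOULE_PER_KEV: float = 1.602176634e-16


def linear_attenuation_mm(material: str, density_g_cm3: float | None = None) -> float:
    """Linear attenuation coefficient in mm⁻¹ at 24 keV.

    ``µ = (µ/ρ) · ρ``, divided by 10 to convert cm⁻¹ to mm⁻¹.
    """
    if density_g_cm3 is None:
        density_g_cm3 = DENSITY_G_CM3[material]
    return MASS_ATTENUATION_24KEV[material] * density_g_cm3 / 10.0
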