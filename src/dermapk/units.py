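"""Package-wide unit conventions and conversions.

Every quantity in :mod:`dermapk` uses a single unit system:

==============  ======================
depth           micrometre (um)
area            cm^2
time            hour (h)
drug amount     microgram (ug)
concentration   ug/cm^3
TEWL            g m^-2 h^-1
flux            ug cm^-2 h^-1
==============  ======================

All conversions between these and other common laboratory units live here so
that no module hand-rolls its own factors.
"""

#: centimetres per micrometre
CM_PER_UM = 1.0e-4


def um_to_cm(depth_um: float) -> float:
    """Convert a depth/thickness from micrometres to centimetres."""
    return depth_um * CM_PER_UM


def cm_to_um(depth_cm: float) -> float:
    """Convert a depth/thickness from centimetres to micrometres."""
    return depth_cm / CM_PER_UM


def mg_per_ml_to_ug_per_cm3(conc_mg_ml: float) -> float:
    """Convert a vehicle drug concentration from mg/mL to ug/cm^3.

    1 mg/mL = 1000 ug/cm^3 (1 mL == 1 cm^3).
    """
    return conc_mg_ml * 1000.0


def mass_per_area_to_depth_um(mass_ug_per_cm2: float, density_g_cm3: float) -> float:
    """Thickness of a tissue layer of the given areal mass and density.

    1 ug/cm^2 at a density of 1 g/cm^3 corresponds to 0.01 um of tissue:
    ``depth_um = mass / (density * 100)``.
    """
    if density_g_cm3 <= 0:
        raise ValueError(f"density must be positive, got {density_g_cm3}")
    if mass_ug_per_cm2 < 0:
        raise ValueError(f"areal mass must be non-negative, got {mass_ug_per_cm2}")
    return mass_ug_per_cm2 / (density_g_cm3 * 100.0)
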