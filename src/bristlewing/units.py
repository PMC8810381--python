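"""Internal unit system and SI conversion factors.

All quantities inside the package are carried in a microgram–micrometre–
millisecond (µg–µm–ms) system, chosen so that the numbers describing a
sub-millimetre insect are of order unity:

===================  =======================  ==================
quantity             internal unit            SI equivalent
===================  =======================  ==================
mass                 µg                       1e-9 kg
length               µm                       1e-6 m
time                 ms                       1e-3 s
speed                µm/ms                    1e-3 m/s
acceleration         µm/ms²                   1 m/s²
force                µg·µm/ms²                1e-9 N (1 nN)
torque               µg·µm²/ms²               1e-15 N·m
power                µg·µm²/ms³               1e-12 W (1 pW)
density              µg/µm³                   1e9 kg/m³
kinematic viscosity  µm²/ms                   1e-9 m²/s
===================  =======================  ==================

A handy coincidence of this system is that 1 µm/ms² equals exactly
1 m/s², so the gravitational acceleration keeps its familiar value.
"""

# multiply an internal value by these to obtain SI
NEWTON_PER_FORCE = 1e-9
NEWTON_METRE_PER_TORQUE = 1e-15
WATT_PER_POWER = 1e-12
M_PER_S_PER_SPEED = 1e-3

# multiply an SI value by these to obtain internal units
DENSITY_FROM_KG_M3 = 1e-9        # kg m^-3  -> µg µm^-3
LINEAR_DENSITY_FROM_UG_M = 1e-6  # µg m^-1  -> µg µm^-1
KINEMATIC_VISCOSITY_FROM_M2_S = 1e9  # m^2 s^-1 -> µm^2 ms^-1

#: body-mass-specific power: (internal power per µg) -> W per kg body mass
SPECIFIC_POWER_TO_W_PER_KG = 1e-3

#: standard gravity, µm/ms² (numerically equal to m/s²)
GRAVITY = 9.81

# --- field defaults used across the package (internal units) ---

#: cuticle density 1200 kg/m³
CUTICLE_DENSITY = 1200.0 * DENSITY_FROM_KG_M3
#: seta linear density 0.96 µg/m (secondary outgrowths absorbed into it)
SETA_LINEAR_DENSITY = 0.96 * LINEAR_DENSITY_FROM_UG_M
#: air density 1.197 kg/m³ (25 °C)
AIR_DENSITY = 1.197 * DENSITY_FROM_KG_M3
#: kinematic viscosity of air 1.54e-5 m²/s (25 °C)
AIR_KINEMATIC_VISCOSITY = 1.54e-5 * KINEMATIC_VISCOSITY_FROM_M2_S


def weight_equivalent_ug(force: float, g: float = GRAVITY) -> float:
    """Express an internal force as the mass (µg) it could support against gravity."""
    return force / g
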