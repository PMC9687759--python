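"""Constitutive models for liver microwave ablation.

Static thermal constants per material, sigmoidal temperature-dependent
dielectric properties, the tissue water-content curve and the two
vaporization treatments (effective specific heat / enthalpy spike) used by
the bioheat solvers.

Temperature is in degrees Celsius throughout; everything else is SI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "MaterialConstants",
    "SigmoidDielectric",
    "WaterModel",
    "VaporizationConstants",
    "MATERIALS",
    "DIELECTRICS",
    "material_lookup",
    "relative_permittivity",
    "electrical_conductivity",
    "water_content",
    "water_content_derivative",
    "effective_specific_heat",
    "vaporization_rho_c",
]


@dataclass(frozen=True)
class MaterialConstants:
    """Static thermal constants of one material region.

    density kg/m^3, thermal_conductivity W/(m.degC), specific_heat J/(kg.degC).
    """

    name: str
    density: float
    thermal_conductivity: float
    specific_heat: float

    def __post_init__(self) -> None:
        for field in ("density", "thermal_conductivity", "specific_heat"):
            if not getattr(self, field) > 0.0:
                raise ValueError(f"{self.name}: {field} must be strictly positive")

    @property
    def rho_c(self) -> float:
        """Volumetric heat capacity rho*c in J/(m^3.degC)."""
        return self.density * self.specific_heat


#: Thermal constants. Liver, tumor and blood values are the simulation
#: parameters of the source tables for hepatic MWA; the antenna materials
#: (PTFE dielectric, copper, polyimide catheter) are generic handbook values
#: and only matter outside the thermal domain.
MATERIALS: dict[str, MaterialConstants] = {
    "healthy_liver": MaterialConstants("healthy_liver", 1079.0, 0.52, 3540.0),
    "tumor": MaterialConstants("tumor", 1040.0, 0.57, 3960.0),
    "blood": MaterialConstants("blood", 1060.0, 0.5, 3600.0),
    "antenna_dielectric": MaterialConstants("antenna_dielectric", 2200.0, 0.25, 1050.0),
    "antenna_metal": MaterialConstants("antenna_metal", 8960.0, 400.0, 385.0),
    "catheter": MaterialConstants("catheter", 1420.0, 0.2, 1090.0),
}

#: Arterial blood baseline temperature, degC.
BLOOD_BASELINE_C = 37.0


def material_lookup(name: str) -> MaterialConstants:
    """Return the registered :class:`MaterialConstants` for ``name``.

    Raises ``KeyError`` with the list of known materials for unknown names.
    """
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; registered: {sorted(MATERIALS)}"
        ) from None


# ---------------------------------------------------------------------------
# Temperature-dependent dielectrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidDielectric:
    """Coefficients of the sigmoidal dielectric collapse model.

    Relative permittivity eps_r(T) = s1 * (1 - 1/(1 + exp(s2 - s3*T))) and
    electrical conductivity sigma(T) = r1 * (1 - 1/(1 + exp(r2 - r3*T)));
    both decrease with heating as tissue water is driven off (s3, r3 > 0).
    Units: s1 dimensionless, r1 S/m, s3 and r3 1/degC.
    """

    s1: float
    s2: float
    s3: float
    r1: float
    r2: float
    r3: float

    def __post_init__(self) -> None:
        if not (self.s1 > 0 and self.r1 > 0 and self.s3 > 0 and self.r3 > 0):
            raise ValueError("sigmoid amplitudes and slopes must be positive")


# Healthy-liver sigmoid coefficients at 2.45 GHz are external literature
# defaults (the dielectric-collapse fits used throughout the hepatic-MWA
# modeling literature), not values printed in the source tables. The tumor
# amplitudes are the healthy ones scaled by the reported tumor-vs-healthy
# contrast at body temperature (+24% permittivity, +11% conductivity).
HEALTHY_LIVER_DIELECTRIC = SigmoidDielectric(
    s1=48.391, s2=6.286, s3=0.0764, r1=2.173, r2=5.951, r3=0.0697
)
TUMOR_DIELECTRIC = SigmoidDielectric(
    s1=48.391 * 1.24, s2=6.286, s3=0.0764, r1=2.173 * 1.11, r2=5.951, r3=0.0697
)

DIELECTRICS: dict[str, SigmoidDielectric] = {
    "healthy_liver": HEALTHY_LIVER_DIELECTRIC,
    "tumor": TUMOR_DIELECTRIC,
}

#: Lossless dielectric constants (eps_r, sigma) of the non-tissue regions.
STATIC_DIELECTRICS: dict[str, tuple[float, float]] = {
    "antenna_dielectric": (2.03, 0.0),  # PTFE
    "slot": (2.03, 0.0),  # slots filled with the coax dielectric
    "catheter": (2.6, 0.0),
}


def relative_permittivity(T, coeffs: SigmoidDielectric):
    """Relative permittivity eps_r(T); strictly decreasing in T."""
    T = np.asarray(T, dtype=float)
    # 1 - 1/(1+e^x) = expit(x); overflow-safe for extreme temperatures
    return coeffs.s1 * expit(coeffs.s2 - coeffs.s3 * T)


def electrical_conductivity(T, coeffs: SigmoidDielectric):
    """Electrical conductivity sigma(T) in S/m; strictly decreasing in T."""
    T = np.asarray(T, dtype=float)
    return coeffs.r1 * expit(coeffs.r2 - coeffs.r3 * T)


def tissue_dielectric(region: str, T):
    """(eps_r, sigma) for a region label at temperature T (degC).

    Tissue regions follow the sigmoid collapse model; antenna regions are
    lossless constants. ``T`` may be scalar or array.
    """
    if region in DIELECTRICS:
        c = DIELECTRICS[region]
        return relative_permittivity(T, c), electrical_conductivity(T, c)
    if region in STATIC_DIELECTRICS:
        eps, sig = STATIC_DIELECTRICS[region]
        T = np.asarray(T, dtype=float)
        return np.full_like(T, eps), np.full_like(T, sig)
    raise KeyError(f"no dielectric model for region {region!r}")


# ---------------------------------------------------------------------------
# Water content and effective specific heat
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterModel:
    """Tissue water mass fraction W(T) and the latent-heat constant.

    The curve has three branches: a slow exponential drawdown between 70 and
    100 degC, a steep linear drop across the 100-104 degC vaporization band,
    and an exponential tail above 104 degC. Below 70 degC the water content
    is held at its 70 degC value (~0.778, the steady-state liver fraction).
    ``latent_heat_alpha`` is the latent heat of vaporization in J/kg.
    """

    latent_heat_alpha: float = 2.26e6

    # branch constants (fixed by the published curve)
    W0: float = 0.778
    b1_shift: float = 106.0
    b1_scale: float = 3.42
    b2_intercept: float = 7.053
    b2_slope: float = 0.064096
    b3_shift: float = 80.0
    b3_scale: float = 34.37

    def __post_init__(self) -> None:
        if self.latent_heat_alpha <= 0:
            raise ValueError("latent heat must be positive")


DEFAULT_WATER = WaterModel()


def water_content(T, model: WaterModel = DEFAULT_WATER):
    """Tissue water mass fraction W(T), continuous on the whole real line."""
    T = np.asarray(T, dtype=float)
    m = model
    w70 = m.W0 * (1.0 - np.exp((70.0 - m.b1_shift) / m.b1_scale))
    return np.select(
        [T < 70.0, T < 100.0, T < 104.0],
        [
            w70,
            m.W0 * (1.0 - np.exp((T - m.b1_shift) / m.b1_scale)),
            m.b2_intercept - m.b2_slope * T,
        ],
        default=m.W0 * np.exp(-(T - m.b3_shift) / m.b3_scale),
    )


def water_content_derivative(T, model: WaterModel = DEFAULT_WATER):
    """Branchwise analytic dW/dT, using the left limit at branch joins.

    At 70, 100 and 104 degC the derivative of the branch *below* the join is
    returned, which keeps the effective specific heat finite and makes the
    evaluation deterministic on the closed branch edges.
    """
    T = np.asarray(T, dtype=float)
    m = model
    return np.select(
        [T <= 70.0, T <= 100.0, T <= 104.0],
        [
            0.0,
            -(m.W0 / m.b1_scale) * np.exp((T - m.b1_shift) / m.b1_scale),
            -m.b2_slope + 0.0 * T,
        ],
        default=-(m.W0 / m.b3_scale) * np.exp(-(T - m.b3_shift) / m.b3_scale),
    )


def effective_specific_heat(
    T,
    mat: MaterialConstants,
    model: WaterModel = DEFAULT_WATER,
    mode: str = "mass_fraction",
):
    """Effective specific heat c' = c - alpha * dW/dT, J/(kg.degC).

    Vaporization enters the transient heat equation as extra apparent heat
    capacity wherever water is being driven off (dW/dT < 0), so c' >= c.
    ``mode='mass_fraction'`` is the dimensionally consistent reading with W a
    mass fraction; ``mode='as_printed'`` multiplies the latent term by the
    material density as well (the alternative typeset reading).
    """
    dW = water_content_derivative(T, model)
    if mode == "mass_fraction":
        return mat.specific_heat - model.latent_heat_alpha * dW
    if mode == "as_printed":
        return mat.specific_heat - model.latent_heat_alpha * mat.density * dW
    raise ValueError(f"unknown effective-heat mode {mode!r}")


# ---------------------------------------------------------------------------
# Enthalpy-method vaporization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VaporizationConstants:
    """Constants of the enthalpy-spike vaporization treatment.

    ``h_fg`` is the latent heat of vaporization multiplied by the water
    density at 100 degC (J/m^3). ``C_w_tissue``/``C_w_blood`` are water
    content fractions; ``rho_g``/``c_g`` describe the desiccated (gas-phase)
    tissue. ``delta_T`` is the width of the vaporization band (degC).
    Gas-phase constants are external literature defaults.
    """

    h_fg: float = 2.26e6 * 958.0
    C_w_tissue: float = 0.778
    C_w_blood: float = 0.79
    rho_g: float = 370.0
    c_g: float = 2160.0
    delta_T: float = 1.0

    def __post_init__(self) -> None:
        if min(self.h_fg, self.C_w_tissue, self.C_w_blood, self.rho_g, self.c_g) <= 0:
            raise ValueError("vaporization constants must be positive")
        if self.delta_T <= 0:
            raise ValueError("vaporization band width must be positive")
        liquid = min(m.rho_c for m in (MATERIALS["healthy_liver"], MATERIALS["blood"]))
        if self.rho_g * self.c_g >= liquid:
            raise ValueError("gas-phase rho*c must be below the liquid-phase value")


DEFAULT_VAPORIZATION = VaporizationConstants()


def vaporization_rho_c(
    T,
    phase: str = "tissue",
    consts: VaporizationConstants = DEFAULT_VAPORIZATION,
    liquid_rho_c: float | None = None,
):
    """Volumetric heat capacity (rho*c)(T) of the enthalpy method, J/(m^3.degC).

    Liquid phase below 99 degC, a latent spike h_fg*C_w/delta_T across the
    99-100 degC band, and the gas-phase product above 100 degC. ``phase``
    selects the water-content fraction ('tissue' or 'blood'); the liquid
    product defaults to the Table values of healthy liver / blood but can be
    overridden (e.g. for the tumor region).
    """
    T = np.asarray(T, dtype=float)
    if phase == "tissue":
        cw = consts.C_w_tissue
        liquid = MATERIALS["healthy_liver"].rho_c
    elif phase == "blood":
        cw = consts.C_w_blood
        liquid = MATERIALS["blood"].rho_c
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if liquid_rho_c is not None:
        liquid = liquid_rho_c
    spike = consts.h_fg * cw / consts.delta_T
    return np.select(
        [T <= 99.0, T <= 100.0],
        [liquid, spike],
        default=consts.rho_g * consts.c_g,
    )
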