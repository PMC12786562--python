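"""Closed-form interference-fit mechanics of the prosthesis loop.

A stapes-prosthesis loop crimped (or self-crimped) around the lenticular
process of the incus is idealised as a thin elastic ring shrunk onto a rigid
cylinder with a small radial interference ``dr``.  The average interface
pressure of the *closed* ring follows from the Lame thin-ring solution,

    p = E * dr / (rm * (rm / t + nu)),

with ``rm`` the mean ring radius and ``t`` the radial wall thickness.  A real
loop is split over an opening angle so that it can be slipped over the bone;
covering only an arc ``theta`` (degrees) reduces its effective radial
stiffness, and with it the transmitted pressure, in proportion to the covered
fraction:

    p_loop = p * theta / 360.

Forces and pressures are related through the nominal contact patch
``Ac = w * Lc`` with ``Lc = (theta/360) * 2*pi*ri``.

Units are mm-MPa-N throughout (1 MPa * 1 mm^2 = 1 N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "RingSpec",
    "Material",
    "PressureResult",
    "InvalidGeometryError",
    "TITANIUM",
    "PTFE",
    "CORTICAL_BONE",
    "MATERIALS",
    "closed_ring_pressure",
    "compliance_factor",
    "open_ring_pressure",
    "contact_length",
    "contact_area",
    "pressure_from_force",
    "force_from_pressure",
    "pressure_table",
]

#: Von Mises strength of cortical bone used as the necrosis-risk proxy, MPa.
BONE_VON_MISES_LIMIT = 60.0


class InvalidGeometryError(ValueError):
    """Raised for degenerate or non-physical ring geometry."""


@dataclass(frozen=True)
class RingSpec:
    """Geometry of a (possibly split) prosthesis loop.

    Parameters
    ----------
    inner_diameter, outer_diameter:
        Loop bore and outer diameter, mm.
    band_width_w:
        Axial width of the band, mm.
    coverage_angle_theta:
        Arc of the ring actually wrapped around the incus, degrees in
        (0, 360].  360 is a closed ring; the default 216 corresponds to a
        typical crimping opening and reproduces the published loop pressures.
    interference_dr:
        Radial interference between the free loop bore and the incus, mm.
    """

    inner_diameter: float
    outer_diameter: float
    band_width_w: float
    coverage_angle_theta: float = 216.0
    interference_dr: float = 0.002

    def __post_init__(self) -> None:
        if not self.inner_diameter > 0:
            raise InvalidGeometryError(f"inner_diameter must be > 0, got {self.inner_diameter}")
        if not self.outer_diameter > self.inner_diameter:
            raise InvalidGeometryError(
                f"outer_diameter ({self.outer_diameter}) must exceed "
                f"inner_diameter ({self.inner_diameter})"
            )
        if not self.band_width_w > 0:
            raise InvalidGeometryError(f"band_width_w must be > 0, got {self.band_width_w}")
        if not 0.0 < self.coverage_angle_theta <= 360.0:
            raise InvalidGeometryError(
                f"coverage_angle_theta must lie in (0, 360], got {self.coverage_angle_theta}"
            )
        if self.interference_dr < 0:
            raise InvalidGeometryError(f"interference_dr must be >= 0, got {self.interference_dr}")

    @property
    def thickness(self) -> float:
        """Radial wall thickness t = (OD - ID)/2, mm."""
        return 0.5 * (self.outer_diameter - self.inner_diameter)

    @property
    def mean_radius(self) -> float:
        """Mean ring radius rm = (ID + OD)/4, mm."""
        return 0.25 * (self.inner_diameter + self.outer_diameter)

    @property
    def inner_radius(self) -> float:
        return 0.5 * self.inner_diameter

    def with_coverage(self, theta: float) -> "RingSpec":
        return replace(self, coverage_angle_theta=theta)


@dataclass(frozen=True)
class Material:
    """Linear-elastic isotropic material with optional named strength limits (MPa)."""

    name: str
    youngs_modulus_E: float
    poisson_nu: float
    strength_limits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.youngs_modulus_E > 0:
            raise ValueError(f"youngs_modulus_E must be > 0, got {self.youngs_modulus_E}")
        if not 0.0 <= self.poisson_nu < 0.5:
            raise ValueError(f"poisson_nu must lie in [0, 0.5), got {self.poisson_nu}")


TITANIUM = Material("titanium", youngs_modulus_E=110_000.0, poisson_nu=0.30)
PTFE = Material(
    "ptfe",
    youngs_modulus_E=500.0,
    poisson_nu=0.46,
    strength_limits={"tensile": 25.0, "compressive": 30.0},
)
CORTICAL_BONE = Material(
    "cortical_bone",
    youngs_modulus_E=14_000.0,
    poisson_nu=0.30,
    strength_limits={"von_mises": BONE_VON_MISES_LIMIT},
)

MATERIALS: dict[str, Material] = {m.name: m for m in (TITANIUM, PTFE, CORTICAL_BONE)}


@dataclass(frozen=True)
class PressureResult:
    """Bundle of the closed-form quantities for one loop configuration."""

    closed_ring_pressure_p: float
    compliance_factor_phi: float
    loop_pressure_ploop: float
    contact_length_Lc: float
    contact_area_Ac: float
    force_F: float


def closed_ring_pressure(ring: RingSpec, mat: Material) -> float:
    """Average interface pressure of a fully closed shrink-fit ring, MPa."""
    rm, t = ring.mean_radius, ring.thickness
    if rm <= 0 or t <= 0:
        raise InvalidGeometryError("ring must have positive mean radius and thickness")
    return mat.youngs_modulus_E * ring.interference_dr / (rm * (rm / t + mat.poisson_nu))


def compliance_factor(coverage_angle_theta: float) -> float:
    """Pressure-reduction factor of a split ring covering ``theta`` degrees.

    The radial stiffness of an open thin ring scales with its angular
    coverage, so the transmitted pressure is the closed-ring value times
    theta/360 (identity at 360 deg).
    """
    if not 0.0 < coverage_angle_theta <= 360.0:
        raise InvalidGeometryError(
            f"coverage angle must lie in (0, 360], got {coverage_angle_theta}"
        )
    return coverage_angle_theta / 360.0


def open_ring_pressure(ring: RingSpec, mat: Material) -> float:
    """Average interface pressure of the split loop, MPa."""
    return closed_ring_pressure(ring, mat) * compliance_factor(ring.coverage_angle_theta)


def contact_length(ring: RingSpec) -> float:
    """Arc length of the loop-incus contact line, mm."""
    return compliance_factor(ring.coverage_angle_theta) * 2.0 * math.pi * ring.inner_radius


def contact_area(ring: RingSpec) -> float:
    """Nominal contact patch area Ac = w * Lc, mm^2."""
    return ring.band_width_w * contact_length(ring)


def pressure_from_force(force_F: float, ring: RingSpec) -> float:
    """Average contact pressure (MPa) equivalent to a crimping force (N)."""
    if force_F < 0:
        raise ValueError(f"force must be >= 0, got {force_F}")
    ac = contact_area(ring)
    if ac <= 0:
        raise InvalidGeometryError("contact area is degenerate (zero)")
    return force_F / ac


def force_from_pressure(p: float, ring: RingSpec) -> float:
    """Crimping force (N) equivalent to an average contact pressure (MPa)."""
    if p < 0:
        raise ValueError(f"pressure must be >= 0, got {p}")
    return p * contact_area(ring)


def evaluate(ring: RingSpec, mat: Material) -> PressureResult:
    """All closed-form quantities for one ring/material configuration."""
    p = closed_ring_pressure(ring, mat)
    phi = compliance_factor(ring.coverage_angle_theta)
    ploop = p * phi
    lc = contact_length(ring)
    ac = ring.band_width_w * lc
    return PressureResult(
        closed_ring_pressure_p=p,
        compliance_factor_phi=phi,
        loop_pressure_ploop=ploop,
        contact_length_Lc=lc,
        contact_area_Ac=ac,
        force_F=ploop * ac,
    )


def pressure_table(
    outer_diameters: tuple[float, ...] = (1.2, 1.4, 1.8),
    inner_diameter: float = 0.8,
    band_width_w: float = 0.3,
    coverage_angle_theta: float = 216.0,
    interference_dr: float = 0.002,
    mat: Material = PTFE,
):
    """Loop pressure versus outer diameter for a self-crimping loop.

    Returns a pandas DataFrame with one row per OD, including the closed-ring
    pressure and the split-loop pressure.  The defaults are the published
    PTFE configurations.
    """
    import pandas as pd

    rows = []
    for od in outer_diameters:
        ring = RingSpec(
            inner_diameter=inner_diameter,
            outer_diameter=od,
            band_width_w=band_width_w,
            coverage_angle_theta=coverage_angle_theta,
            interference_dr=interference_dr,
        )
        res = evaluate(ring, mat)
        rows.append(
            {
                "OD_mm": od,
                "closed_ring_pressure_MPa": res.closed_ring_pressure_p,
                "ploop_MPa": res.loop_pressure_ploop,
                "contact_area_mm2": res.contact_area_Ac,
                "equivalent_force_N": res.force_F,
            }
        )
    return pd.DataFrame(rows)
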