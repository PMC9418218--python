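"""Thermophysical property database and nanofluid mixture correlations.

Effective properties of a dilute nanoparticle suspension in blood follow the
classical volume-weighted mixing rules for density and volumetric heat
capacity, and the Hamilton–Crosser correlation for thermal conductivity,

    k_nf = k_b * (k_s + (m-1) k_b - phi (m-1)(k_b - k_s))
               / (k_s + (m-1) k_b + phi (k_b - k_s)),

where ``m = 3/psi`` is the empirical shape factor tied to the particle
sphericity ``psi`` (``m = 3`` for spheres). Non-spherical particles (bricks,
cylinders, platelets, blades) conduct better at equal volume fraction because
their larger surface-to-volume ratio raises ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "MaterialProps",
    "ParticleShape",
    "NanofluidMixture",
    "MATERIALS",
    "SHAPES",
    "get_material",
    "shape_factor",
    "mixture_density",
    "mixture_heat_capacity",
    "hamilton_crosser_k",
    "materials_table",
]


@dataclass(frozen=True)
class MaterialProps:
    """Thermophysical constants of a base fluid or particle species.

    Parameters
    ----------
    name : str
        Species label.
    rho : float
        Density, kg m^-3.
    cp : float
        Specific heat, J kg^-1 K^-1.
    k : float
        Thermal conductivity, W m^-1 K^-1.
    """

    name: str
    rho: float
    cp: float
    k: float

    def __post_init__(self) -> None:
        for field in ("rho", "cp", "k"):
            value = getattr(self, field)
            if not value > 0:
                raise ValueError(
                    f"material {self.name!r}: {field} must be positive, got {value}"
                )

    @property
    def rho_cp(self) -> float:
        """Volumetric heat capacity rho*cp, J m^-3 K^-1."""
        return self.rho * self.cp


@dataclass(frozen=True)
class ParticleShape:
    """Particle geometry for the Hamilton–Crosser conductivity model.

    ``m`` is the empirical shape factor and ``psi`` the sphericity (surface
    area of the volume-equivalent sphere over the particle's surface area);
    the two are tied by ``m = 3/psi``, so a sphere has ``psi = 1, m = 3``.
    """

    name: str
    m: float
    psi: float

    def __post_init__(self) -> None:
        if not self.m >= 3.0:
            raise ValueError(f"shape {self.name!r}: shape factor m must be >= 3")
        if not 0.0 < self.psi <= 1.0:
            raise ValueError(f"shape {self.name!r}: sphericity must lie in (0, 1]")


@dataclass(frozen=True)
class NanofluidMixture:
    """Base fluid loaded with a volume fraction ``phi`` of shaped particles."""

    base: MaterialProps
    particle: MaterialProps
    phi: float
    shape: ParticleShape

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 0.1:
            raise ValueError(
                f"volume fraction phi={self.phi} outside the dilute range [0, 0.1]"
            )

    def with_phi(self, phi: float) -> "NanofluidMixture":
        return replace(self, phi=phi)

    @property
    def rho(self) -> float:
        return mixture_density(self)

    @property
    def rho_cp(self) -> float:
        return mixture_heat_capacity(self)

    @property
    def k(self) -> float:
        return hamilton_crosser_k(self)

    @property
    def heat_capacity_ratio(self) -> float:
        """(rho*cp)_nf / (rho*cp)_base; equals 1 at phi = 0."""
        return self.rho_cp / self.base.rho_cp

    @property
    def conductivity_ratio(self) -> float:
        """k_nf / k_base; equals 1 at phi = 0."""
        return self.k / self.base.k


#: Reference thermophysical properties of blood and common therapeutic
#: nanoparticle species (densities kg/m^3, specific heats J/(kg K),
#: conductivities W/(m K)).
MATERIALS: dict[str, MaterialProps] = {
    "blood": MaterialProps("blood", rho=1050.0, cp=3617.0, k=0.52),
    "gold": MaterialProps("gold", rho=19300.0, cp=129.0, k=318.0),
    "swcnt": MaterialProps("swcnt", rho=2600.0, cp=425.0, k=6600.0),
    "mwcnt": MaterialProps("mwcnt", rho=1600.0, cp=796.0, k=3000.0),
    "fe3o4": MaterialProps("fe3o4", rho=5180.0, cp=670.0, k=9.7),
}

#: Default shape factors, m = 3/psi with standard sphericities. Overridable
#: through the run configuration.
SHAPES: dict[str, ParticleShape] = {
    "sphere": ParticleShape("sphere", m=3.0, psi=1.0),
    "brick": ParticleShape("brick", m=3.7, psi=3.0 / 3.7),
    "cylinder": ParticleShape("cylinder", m=4.9, psi=3.0 / 4.9),
    "platelet": ParticleShape("platelet", m=5.7, psi=3.0 / 5.7),
    "blade": ParticleShape("blade", m=8.6, psi=3.0 / 8.6),
}


def get_material(name: str) -> MaterialProps:
    """Look up a species in the built-in property database."""
    try:
        return MATERIALS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(MATERIALS)}"
        ) from None


def shape_factor(name: str) -> ParticleShape:
    """Return the (m, psi) pair for a named particle shape."""
    try:
        return SHAPES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown shape {name!r}; known: {sorted(SHAPES)}") from None


def mixture_density(mix: NanofluidMixture) -> float:
    """Volume-weighted mixture density (1-phi) rho_b + phi rho_s, kg m^-3."""
    return (1.0 - mix.phi) * mix.base.rho + mix.phi * mix.particle.rho


def mixture_heat_capacity(mix: NanofluidMixture) -> float:
    """Volume-weighted volumetric heat capacity (rho cp)_nf, J m^-3 K^-1."""
    return (1.0 - mix.phi) * mix.base.rho_cp + mix.phi * mix.particle.rho_cp


def hamilton_crosser_k(mix: NanofluidMixture) -> float:
    """Hamilton–Crosser effective conductivity of the suspension, W m^-1 K^-1."""
    kb, ks = mix.base.k, mix.particle.k
    m, phi = mix.shape.m, mix.phi
    denom = ks + (m - 1.0) * kb + phi * (kb - ks)
    if abs(denom) < 1e-300:
        raise ZeroDivisionError(
            "Hamilton–Crosser denominator vanished "
            f"(k_b={kb}, k_s={ks}, m={m}, phi={phi})"
        )
    numer = ks + (m - 1.0) * kb - phi * (m - 1.0) * (kb - ks)
    return kb * numer / denom


def materials_table() -> pd.DataFrame:
    """Property database as a DataFrame (exportable to CSV)."""
    return pd.DataFrame(
        [
            {"name": mat.name, "rho": mat.rho, "cp": mat.cp, "k": mat.k}
            for mat in MATERIALS.values()
        ]
    )
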