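"""Onsager spherical-cavity model of molecular polarizabilities in a dielectric.

A molecule is a polarizable point dipole (intrinsic polarizability α, Å³)
at the centre of a spherical vacuum cavity of radius ``a`` (Å) carved in a
continuum of optical permittivity ε.  The macroscopic Maxwell field E of
the light wave is modified inside the cavity by the cavity-field factor

    f_c(ε) = 3ε / (2ε + 1),

and the dipole the molecule induces is fed back by the reaction-field
factor

    f_RF(ε, a) = 2(ε − 1) / (a³ (2ε + 1)),

self-consistently enhancing the response by F_RF = 1/(1 − f_RF·α).  Three
polarizabilities follow:

* effective        α̃ = f_c · F_RF · α   (induced dipole per Maxwell field),
* energy-effective α̅ = f_c · α̃          (coefficient of −½E² in the energy),
* excess           α̅_B|A = α̅_B − α̅_A · V_B,m/V_A,m  (solute minus the
  solvent it displaces, the quantity a whispering-gallery-mode biosensor
  responds to).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalSolvent",
    "OnsagerSpecies",
    "OnsagerFactors",
    "cavity_field_factor",
    "reaction_field_factor",
    "enhancement",
    "effective_polarizability",
    "energy_effective_polarizability",
    "interaction_energy",
    "excess_onsager",
    "factors",
]


@dataclass(frozen=True)
class OpticalSolvent:
    """Solvent optical description.

    Either ``eps_omega`` (permittivity at the optical frequency) or the
    refractive index must be given; when only ``refractive_index`` is
    present, ε := n² (Maxwell relation).  When both are present they must
    agree to 0.1% relative.
    """

    name: str = ""
    eps_omega: float | None = None
    eps_static: float | None = None
    refractive_index: float | None = None
    molar_volume: float | None = None
    wavelength_label: float | None = None

    def __post_init__(self):
        if self.eps_omega is None and self.refractive_index is None:
            raise ValueError("need eps_omega or refractive_index")
        if self.eps_omega is not None and self.eps_omega < 1:
            raise ValueError("eps_omega must be >= 1")
        if self.refractive_index is not None and self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.molar_volume is not None and self.molar_volume <= 0:
            raise ValueError("molar_volume must be positive")
        if self.eps_omega is not None and self.refractive_index is not None:
            n2 = self.refractive_index**2
            if abs(self.eps_omega - n2) / self.eps_omega > 1e-3:
                raise ValueError(
                    f"eps_omega={self.eps_omega} inconsistent with n²={n2:.5f}"
                )

    @property
    def eps(self) -> float:
        """Optical permittivity; explicit ε wins over n²."""
        if self.eps_omega is not None:
            return self.eps_omega
        return self.refractive_index**2


@dataclass(frozen=True)
class OnsagerSpecies:
    """A molecular species in the Onsager model: α (Å³), cavity radius a (Å),
    and optionally a molar volume (cm³/mol) for excess combinations."""

    alpha0: float
    radius: float
    molar_volume: float | None = None

    def __post_init__(self):
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class OnsagerFactors:
    f_c: float
    f_RF: float
    F_RF: float


def cavity_field_factor(eps: float) -> float:
    """f_c = 3ε/(2ε+1); dimensionless, in [1, 1.5] for ε ≥ 1."""
    if eps < 1:
        raise ValueError(f"eps must be >= 1, got {eps}")
    return 3.0 * eps / (2.0 * eps + 1.0)


def reaction_field_factor(eps: float, a: float) -> float:
    """f_RF = 2(ε−1)/(a³(2ε+1)), Å⁻³."""
    if eps < 1:
        raise ValueError(f"eps must be >= 1, got {eps}")
    if a <= 0:
        raise ValueError(f"cavity radius must be positive, got {a}")
    return 2.0 * (eps - 1.0) / (a**3 * (2.0 * eps + 1.0))


def enhancement(alpha0: float, f_RF: float) -> float:
    """Reaction-field enhancement F_RF = 1/(1 − f_RF·α).

    Diverges as f_RF·α → 1 (polarization catastrophe); that regime is
    rejected.
    """
    x = f_RF * alpha0
    if x >= 1.0:
        raise ValueError(
            f"polarization catastrophe: f_RF*alpha0 = {x:.6g} >= 1"
        )
    return 1.0 / (1.0 - x)


def factors(species: OnsagerSpecies, eps: float) -> OnsagerFactors:
    """All three Onsager factors for one species in medium ε."""
    f_c = cavity_field_factor(eps)
    f_rf = reaction_field_factor(eps, species.radius)
    return OnsagerFactors(f_c=f_c, f_RF=f_rf, F_RF=enhancement(species.alpha0, f_rf))


def effective_polarizability(species: OnsagerSpecies, eps: float) -> float:
    """α̃ = f_c·F_RF·α, Å³."""
    f = factors(species, eps)
    return f.f_c * f.F_RF * species.alpha0


def energy_effective_polarizability(species: OnsagerSpecies, eps: float) -> float:
    """α̅ = f_c²·F_RF·α = f_c·α̃, Å³."""
    f = factors(species, eps)
    return f.f_c**2 * f.F_RF * species.alpha0


def interaction_energy(alpha_bar: float, E) -> float:
    """Induced-dipole interaction energy W = −½ α̅ |E|², in Å³·E² units."""
    if alpha_bar < 0:
        raise ValueError("alpha_bar must be >= 0")
    E = np.asarray(E, dtype=float)
    return -0.5 * alpha_bar * float(np.sum(E * E))


def excess_onsager(species_b: OnsagerSpecies, species_a: OnsagerSpecies, eps: float) -> float:
    """Excess polarizability α̅_B|A = α̅_B − α̅_A·(V_B,m/V_A,m), Å³.

    Each energy-effective polarizability pairs its own species' reaction
    -field enhancement with its own intrinsic polarizability (the direct
    substitution of the energy expression into the excess definition).
    """
    if species_b.molar_volume is None or species_a.molar_volume is None:
        raise ValueError("both species need molar volumes for an excess value")
    ratio = species_b.molar_volume / species_a.molar_volume
    return (
        energy_effective_polarizability(species_b, eps)
        - energy_effective_polarizability(species_a, eps) * ratio
    )
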