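"""Excess polarizabilities and their extraction from refractive-index data.

The excess polarizability of a solute B in solvent A is

    α̅_B|A = α̅_B − α̅_A · V_B,m/V_A,m   (Å³),

the energy-effective polarizability of the solute minus that of the
solvent molecules displaced from the same volume; it is the quantity a
whispering-gallery-mode biosensor shift is proportional to.

Experimental counterparts derive from standard dielectric theory for a
dilute optical medium.  Writing the polarization density of the pure
solvent as P = N α̃ E with N = N_A/V_m molecules per volume and
ε = n² = 1 + 4πNα̃:

    α̃_exp = (n² − 1)·V_m / (4π N_A)                 (pure solvent),
    α̅_exp = f_c · α̃_exp                            (energy-effective),
    α̅_B|A,exp = f_c · (n/2π) · (dn/dm_B) · M/N_A    (solute, from the
        refractive-index increment: 2n·δn = 4π·N_B·α̃_excess).

f_c is the effective cavity-field factor of the solvent cavity (default:
the water vdW-cavity value 1.1536).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

from .constants import (
    AVOGADRO,
    BASIS_SCALE_FACTOR,
    CM3_TO_A3,
    WATER_CAVITY_FACTOR,
)

__all__ = [
    "PolarizabilityRecord",
    "ExcessResult",
    "combine_excess",
    "scale_basis",
    "cavity_factor_from_pair",
    "exp_effective_from_refraction",
    "exp_energy_effective",
    "exp_excess_from_dndc",
]


@dataclass(frozen=True)
class PolarizabilityRecord:
    """Per-molecule polarizabilities (Å³) with provenance.

    ``alpha_tilde``: effective (dipole per Maxwell field);
    ``alpha_bar``: energy-effective; ``alpha_bare``: intrinsic/noneffective.
    """

    molecule: str
    alpha_bar: float
    alpha_tilde: float | None = None
    alpha_bare: float | None = None
    wavelength_label: float | None = None
    provenance: str = "user"

    def __post_init__(self):
        for name in ("alpha_bar", "alpha_tilde", "alpha_bare"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class ExcessResult:
    """An excess-polarizability combination; the defining identity
    ``alpha_excess = alpha_bar_B − alpha_bar_A·volume_ratio`` holds
    exactly by construction."""

    solute: str
    alpha_bar_B: float
    alpha_bar_A: float
    volume_ratio: float
    alpha_excess: float


def combine_excess(
    alpha_bar_B: float,
    alpha_bar_A: float,
    volume_ratio: float,
    solute: str = "",
) -> ExcessResult:
    """α̅_B|A = α̅_B − α̅_A·(V_B,m/V_A,m), Å³.

    ``volume_ratio`` may be 0 (massless-solvent limit) but not negative.
    """
    if alpha_bar_B <= 0 or alpha_bar_A <= 0:
        raise ValueError("energy-effective polarizabilities must be positive")
    if volume_ratio < 0:
        raise ValueError("volume ratio must be >= 0")
    return ExcessResult(
        solute=solute,
        alpha_bar_B=alpha_bar_B,
        alpha_bar_A=alpha_bar_A,
        volume_ratio=volume_ratio,
        alpha_excess=alpha_bar_B - alpha_bar_A * volume_ratio,
    )


def scale_basis(alpha: float, factor: float = BASIS_SCALE_FACTOR) -> float:
    """Apply the diffuse-function basis-set scaling (default 1.1751, the
    mean of the dimer/trimer aug-cc-pvdz / cc-pvdz ratios)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return alpha * factor


def cavity_factor_from_pair(alpha_bar: float, alpha_tilde: float) -> float:
    """Effective cavity-field factor f_c = α̅/α̃ of a vdW cavity."""
    if alpha_tilde == 0:
        raise ValueError("alpha_tilde must be nonzero")
    if alpha_bar <= 0 or alpha_tilde < 0:
        raise ValueError("polarizabilities must be positive")
    return alpha_bar / alpha_tilde


def exp_effective_from_refraction(n: float, molar_volume: float) -> float:
    """Experimental effective polarizability of a pure liquid, Å³.

    α̃ = (n²−1)·(V_m/N_A)/(4π) with V_m in cm³/mol, converted to Å³.
    """
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if molar_volume <= 0:
        raise ValueError("molar volume must be positive")
    per_molecule = molar_volume / AVOGADRO * CM3_TO_A3  # Å³ per molecule
    return (n**2 - 1.0) * per_molecule / (4.0 * math.pi)


def exp_energy_effective(alpha_tilde_exp: float, f_c: float = WATER_CAVITY_FACTOR) -> float:
    """α̅_exp = f_c·α̃_exp, Å³."""
    if alpha_tilde_exp <= 0 or f_c <= 0:
        raise ValueError("inputs must be positive")
    return alpha_tilde_exp * f_c


def exp_excess_from_dndc(
    n: float,
    dndm: float,
    molar_mass: float,
    f_c: float = WATER_CAVITY_FACTOR,
) -> float:
    """Experimental excess polarizability from the refractive-index
    increment, Å³.

    α̅_B|A = f_c·(n/2π)·(dn/dm_B)·(M/N_A) with dn/dm in cm³/g and M in
    g/mol; dn/dm = 0 gives 0.
    """
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if dndm < 0 or molar_mass <= 0 or f_c <= 0:
        raise ValueError("dndm must be >= 0 and mass/f_c positive")
    mass_volume = molar_mass / AVOGADRO * CM3_TO_A3  # cm³·(g/cm³-free) → Å³ scale
    return f_c * (n / (2.0 * math.pi)) * dndm * mass_volume
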