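"""Boundary-element solver for cavity electrostatics in a dielectric.

Two classical problems on a tessellated vacuum cavity embedded in a medium
of optical permittivity ε are solved with a single boundary operator:

* **reaction field** — point charges/dipoles inside the cavity polarize
  the medium; the polarization is represented by apparent charges on the
  surface (the apparent-surface-charge construction of polarizable
  continuum models);
* **cavity (local) field** — a uniform macroscopic Maxwell field E, with
  the boundary condition at the cavity surface, produces an interior
  field E + E_Σ differing from E; for a sphere the interior field is
  (3ε/(2ε+1))·E, the Onsager cavity factor.

Both reduce to the dielectric jump condition ε·∂φ/∂n|out = ∂φ/∂n|in for
the total potential φ = φ_source + φ_σ with a single-layer charge σ on
the surface.  Collocation at tessera centres gives

    [2π(ε+1)/(ε−1) I − K A] σ = ∂φ_source/∂n,

with K the (principal-value) normal-derivative kernel of the single
layer, Kᵢⱼ = −(rᵢ−rⱼ)·nᵢ/|rᵢ−rⱼ|³, and the diagonal fixed by the
closed-surface Gauss sum rule Σⱼ Kᵢⱼ aⱼ = −2π.  The analytic sphere
results (Born charge, Onsager reaction- and cavity-field factors) are the
correctness contract; discretization error shrinks with refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cavity import Cavity, tessellate

__all__ = [
    "BEMSystem",
    "SurfaceCharge",
    "ProbeField",
    "assemble",
    "reaction_charges",
    "reaction_field_factor_vdw",
    "cavity_field_charges",
    "cavity_field_factor_vdw",
    "sphere_system",
]


@dataclass(frozen=True)
class ProbeField:
    """A uniform optical Maxwell field amplitude (arbitrary linear unit)."""

    vector: np.ndarray
    wavelength_label: float | None = None

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (3,):
            raise ValueError("field vector must have 3 components")
        object.__setattr__(self, "vector", v)


@dataclass(frozen=True)
class SurfaceCharge:
    """Per-tessera apparent charges (same arbitrary unit as the source)."""

    values: np.ndarray
    provenance: str = ""

    @property
    def total(self) -> float:
        return float(np.sum(self.values))


class BEMSystem:
    """Assembled collocation system on a fixed tessellation.

    Attributes
    ----------
    centers, normals : (N, 3) arrays
    areas : (N,) array, Ų
    eps : float, external optical permittivity
    S : single-layer potential matrix (Å⁻¹ scale), SPD on well-separated
        tessellations; diagonal Sᵢᵢ = 1.0694·√(4π/aᵢ).
    K : normal-derivative kernel with Gauss-sum-rule diagonal.
    """

    def __init__(self, tesserae, eps: float):
        if len(tesserae) < 12:
            raise ValueError("need at least 12 tesserae")
        if eps < 1:
            raise ValueError("eps must be >= 1")
        self.eps = float(eps)
        self.centers = np.array([t.center for t in tesserae])
        self.normals = np.array([t.normal for t in tesserae])
        self.areas = np.array([t.area for t in tesserae])
        n = len(tesserae)

        diff = self.centers[:, None] - self.centers[None]  # r_i - r_j
        dist = np.linalg.norm(diff, axis=-1)
        off = ~np.eye(n, dtype=bool)
        if np.any(dist[off] < 1e-10):
            raise ValueError("coincident tessera centers")

        with np.errstate(divide="ignore", invalid="ignore"):
            S = np.where(off, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
            K = np.where(
                off,
                -np.einsum("ijk,ik->ij", diff, self.normals)
                / np.where(dist > 0, dist, 1.0) ** 3,
                0.0,
            )
        np.fill_diagonal(S, 1.0694 * np.sqrt(4.0 * np.pi / self.areas))
        # Gauss sum rule: each row of K·diag(a) must sum to -2π on a
        # closed surface; the diagonal absorbs the defect.
        row = K @ self.areas
        np.fill_diagonal(K, (-2.0 * np.pi - row) / self.areas)
        self.S = S
        self.K = K

    @property
    def n_tesserae(self) -> int:
        return len(self.areas)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Charges q (= σ·a) from the jump-condition system; ε=1 gives
        an unpolarizable medium and identically zero charges."""
        if self.eps == 1.0:
            return np.zeros_like(rhs)
        lam = 2.0 * np.pi * (self.eps + 1.0) / (self.eps - 1.0)
        A = lam * np.eye(self.n_tesserae) - self.K * self.areas[None, :]
        sigma = np.linalg.solve(A, rhs)
        return sigma * self.areas

    # -- evaluation of the induced (single-layer) potential and field ----
    def potential(self, charge: SurfaceCharge, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d = np.linalg.norm(pts[:, None] - self.centers[None], axis=-1)
        return (charge.values[None, :] / d).sum(axis=1)

    def field(self, charge: SurfaceCharge, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        diff = pts[:, None] - self.centers[None]
        d = np.linalg.norm(diff, axis=-1)
        return np.einsum("pj,pjk->pk", charge.values[None, :] / d**3, diff)


def assemble(tesserae, eps: float) -> BEMSystem:
    """Build the collocation system for a tessellation in medium ε."""
    return BEMSystem(tesserae, eps)


def _inside(cavity: Cavity, point: np.ndarray) -> bool:
    d = np.linalg.norm(cavity.centers - point[None], axis=1)
    return bool(np.any(d < cavity.radii))


def reaction_charges(system: BEMSystem, sources, cavity: Cavity | None = None) -> SurfaceCharge:
    """Apparent surface charges induced by interior sources.

    ``sources`` is a list of ``("charge", q, position)`` or
    ``("dipole", p_vector, position)`` tuples; positions must lie inside
    the cavity when one is supplied for checking.  For a central charge q
    in a sphere the total apparent charge is −q(ε−1)/ε (Born).
    """
    rhs = np.zeros(system.n_tesserae)
    for kind, val, pos in sources:
        pos = np.asarray(pos, dtype=float)
        if cavity is not None and not _inside(cavity, pos):
            raise ValueError(f"source position {pos} lies outside the cavity")
        d = system.centers - pos[None]
        dist = np.linalg.norm(d, axis=1)
        if kind == "charge":
            # ∂/∂n [q/|r-x|] = -q n·(r-x)/|r-x|³
            rhs += -val * np.einsum("ij,ij->i", system.normals, d) / dist**3
        elif kind == "dipole":
            p = np.asarray(val, dtype=float)
            grad = p[None, :] / dist[:, None] ** 3 - (
                3.0 * (d @ p)[:, None] * d / dist[:, None] ** 5
            )
            rhs += np.einsum("ij,ij->i", system.normals, grad)
        else:
            raise ValueError(f"unknown source kind {kind!r}")
    return SurfaceCharge(values=system.solve(rhs), provenance="reaction")


def reaction_field_factor_vdw(
    system: BEMSystem, position, cavity: Cavity | None = None
) -> np.ndarray:
    """Diagonal reaction-field tensor at ``position``, Å⁻³.

    For each Cartesian direction a unit dipole is placed at the position
    and the self-consistent field of its apparent charges is evaluated
    back at the dipole; a centred dipole in a sphere recovers the Onsager
    factor 2(ε−1)/(a³(2ε+1)).  Use ``.mean()`` for the isotropic part.
    """
    position = np.asarray(position, dtype=float)
    out = np.zeros(3)
    for k in range(3):
        p = np.zeros(3)
        p[k] = 1.0
        q = reaction_charges(system, [("dipole", p, position)], cavity=cavity)
        out[k] = system.field(q, position)[0, k]
    return out


def cavity_field_charges(system: BEMSystem, field: ProbeField) -> SurfaceCharge:
    """Apparent charges realizing the cavity-field boundary condition for
    a uniform Maxwell field (source potential φ(s) = −E·s)."""
    E = field.vector
    if np.allclose(E, 0.0):
        raise ValueError("cavity-field solve needs a nonzero field")
    rhs = -(system.normals @ E)
    return SurfaceCharge(values=system.solve(rhs), provenance="cavity-field")


def cavity_field_factor_vdw(
    cavity: Cavity,
    eps: float,
    field_direction=(0.0, 0.0, 1.0),
    probes: str = "atoms",
    level: int = 3,
    system: BEMSystem | None = None,
) -> float:
    """Classical cavity-field factor of a molecular vdW cavity.

    Mean over interior probe points of the interior-field component along
    the applied direction divided by the Maxwell amplitude.  For a single
    sphere this converges to 3ε/(2ε+1); for molecular cavities it is the
    classical field-average analog of the polarizability-ratio factor and
    is reported as such.

    ``probes="atoms"`` probes sphere centres; ``probes="grid"`` uses a
    rejection-sampled interior grid.
    """
    e = np.asarray(field_direction, dtype=float)
    norm = np.linalg.norm(e)
    if norm == 0:
        raise ValueError("field direction must be nonzero")
    e = e / norm
    if system is None:
        system = assemble(tessellate(cavity, level=level), eps)
    if probes == "atoms":
        pts = cavity.centers.copy()
    elif probes == "grid":
        lo = (cavity.centers - cavity.radii[:, None]).min(axis=0)
        hi = (cavity.centers + cavity.radii[:, None]).max(axis=0)
        rng = np.random.default_rng(0)
        cand = rng.uniform(lo, hi, size=(4000, 3))
        # keep points comfortably inside (≥ 30% of the radius from any surface)
        d = np.linalg.norm(cand[:, None] - cavity.centers[None], axis=-1)
        inside = np.any(d < 0.7 * cavity.radii[None], axis=1)
        pts = cand[inside][:200]
    else:
        raise ValueError(f"unknown probes {probes!r}")
    if len(pts) == 0:
        raise ValueError("no interior probe points")
    if eps == 1.0:
        return 1.0
    charge = cavity_field_charges(system, ProbeField(vector=e))
    e_sigma = system.field(charge, pts)
    total = (e[None, :] + e_sigma) @ e
    return float(np.mean(total))


def sphere_system(radius: float, eps: float, level: int = 3, center=(0.0, 0.0, 0.0)):
    """Convenience: (Cavity, BEMSystem) for a single sphere."""
    cav = Cavity(centers=np.array([center], dtype=float), radii=np.array([radius]))
    return cav, assemble(tessellate(cav, level=level), eps)
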