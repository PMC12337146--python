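"""Molecular geometries: XYZ file I/O and synthetic cluster generation.

Geometries are plain element-symbol + Cartesian-Å records; they exist to
feed van-der-Waals cavity construction and carry no bonding information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MoleculeGeometry", "read_xyz", "write_xyz", "synth_geometry", "water_geometry"]


@dataclass(frozen=True)
class MoleculeGeometry:
    """Atoms as parallel arrays: ``elements`` (symbols) and ``coords`` (n×3, Å)."""

    elements: tuple
    coords: np.ndarray
    label: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("elements and coords length mismatch")
        if coords.shape[0] < 1:
            raise ValueError("geometry needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def read_xyz(path) -> MoleculeGeometry:
    """Read a standard XYZ file (count line, comment line, atom lines).

    Raises ``ValueError`` with the offending line number on malformed
    count or coordinate lines, or if the count line disagrees with the
    number of atom records.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: malformed atom count {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n:
        raise ValueError(
            f"{path}: count line declares {n} atoms but body has {len(body)}"
        )
    elements, coords = [], []
    for k, ln in enumerate(body, start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {k}: expected 'El x y z', got {ln!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ValueError(f"{path}: line {k}: malformed coordinates {ln!r}") from None
        elements.append(parts[0])
        coords.append(xyz)
    return MoleculeGeometry(tuple(elements), np.array(coords), label=comment.strip())


def write_xyz(path, geometry: MoleculeGeometry) -> None:
    """Write a geometry in standard XYZ format (coordinates to 1e-6 Å)."""
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n{geometry.label}\n")
        for el, (x, y, z) in zip(geometry.elements, geometry.coords):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


_SYNTH_ELEMENTS = ("C", "N", "O", "H")


def synth_geometry(n_atoms: int, seed: int = 0, spread: float = 5.0) -> MoleculeGeometry:
    """Seeded pseudo-random atom cluster for cavity/BEM testing.

    Atoms are sampled uniformly in the cube ``[-spread, spread]³`` with
    element symbols cycling over C, N, O, H; ``n_atoms == 1`` places a
    single carbon at the origin.  Identical seeds give identical
    geometries.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    if n_atoms == 1:
        coords = np.zeros((1, 3))
    else:
        coords = rng.uniform(-spread, spread, size=(n_atoms, 3))
    elements = tuple(_SYNTH_ELEMENTS[i % len(_SYNTH_ELEMENTS)] for i in range(n_atoms))
    return MoleculeGeometry(elements, coords, label=f"synthetic n={n_atoms} seed={seed}")


def water_geometry() -> MoleculeGeometry:
    """Gas-phase-like water geometry (O-H 0.9572 Å, H-O-H 104.52°)."""
    r, half = 0.9572, np.deg2rad(104.52 / 2.0)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [r * np.sin(half), 0.0, r * np.cos(half)],
            [-r * np.sin(half), 0.0, r * np.cos(half)],
        ]
    )
    return MoleculeGeometry(("O", "H", "H"), coords, label="water")
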