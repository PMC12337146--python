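"""Van-der-Waals sphere-union cavities and their surface tessellation.

A cavity is the union of atom-centred spheres (scaled vdW radii).  Each
sphere surface is subdivided with an icosphere mesh; per-face spherical
patch areas are exact solid angles, so a single closed sphere tessellates
to 4πr² by construction.  Faces whose representative point falls strictly
inside another sphere are culled (GEPOL-like exposure test without exact
spherical-polygon clipping); the residual area bias at sphere seams
shrinks with refinement level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures import DEFAULT_RADIUS_SCALE, load_radii
from .geometry import MoleculeGeometry

__all__ = [
    "Cavity",
    "Tessera",
    "build_cavity",
    "tessellate",
    "cavity_volume",
    "volume_ratio",
    "icosphere",
]


@dataclass(frozen=True)
class Cavity:
    """Union of spheres: centers (n×3, Å), radii (n, Å), element labels."""

    centers: np.ndarray
    radii: np.ndarray
    elements: tuple = ()
    scale: float = 1.0
    label: str = ""

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if centers.shape[0] < 1 or centers.shape[1] != 3:
            raise ValueError("centers must be (n, 3) with n >= 1")
        if radii.shape[0] != centers.shape[0]:
            raise ValueError("radii/centers length mismatch")
        if np.any(radii <= 0):
            raise ValueError("all sphere radii must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)

    @property
    def n_spheres(self) -> int:
        return len(self.radii)

    def is_connected(self) -> bool:
        """True if the sphere-overlap graph is connected."""
        n = self.n_spheres
        d = np.linalg.norm(self.centers[:, None] - self.centers[None], axis=-1)
        adj = d < (self.radii[:, None] + self.radii[None])
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in np.nonzero(adj[i])[0]:
                if j not in seen:
                    seen.add(int(j))
                    stack.append(int(j))
        return len(seen) == n


@dataclass(frozen=True)
class Tessera:
    """One surface element: center on the parent sphere, outward unit
    normal, spherical patch area (Ų), parent sphere index."""

    center: np.ndarray
    area: float
    normal: np.ndarray
    parent: int


def build_cavity(
    geometry: MoleculeGeometry,
    radii: dict | None = None,
    scale: float = DEFAULT_RADIUS_SCALE,
    label: str = "",
) -> Cavity:
    """One sphere per atom with radius ``base_radius(element) * scale``.

    ``radii`` defaults to the packaged UFF table; unknown elements are
    rejected by name.
    """
    if scale <= 0:
        raise ValueError("scale must be positive (radius must stay > 0)")
    table = load_radii() if radii is None else radii
    missing = sorted({el for el in geometry.elements if el not in table})
    if missing:
        raise KeyError(f"no vdW radius for element(s): {', '.join(missing)}")
    r = np.array([table[el] * scale for el in geometry.elements])
    return Cavity(
        centers=geometry.coords.copy(),
        radii=r,
        elements=tuple(geometry.elements),
        scale=scale,
        label=label or geometry.label,
    )


def icosphere(level: int):
    """Unit icosphere mesh: (vertices, faces) after ``level`` 4-fold
    subdivisions of the icosahedron (20·4^level triangles)."""
    if level < 0:
        raise ValueError("level must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(level):
        cache: dict = {}
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = np.array(vlist[i]) + np.array(vlist[j])
                m /= np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(tuple(m))
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts, faces = vlist, new_faces
    return np.array(verts), np.array(faces, dtype=int)


def _spherical_face_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Solid angles of unit-sphere triangles (van Oosterom–Strackee);
    sums exactly to 4π over a closed mesh."""
    v1, v2, v3 = (verts[faces[:, k]] for k in range(3))
    num = np.abs(np.einsum("ij,ij->i", v1, np.cross(v2, v3)))
    den = (
        1.0
        + np.einsum("ij,ij->i", v1, v2)
        + np.einsum("ij,ij->i", v2, v3)
        + np.einsum("ij,ij->i", v3, v1)
    )
    return 2.0 * np.arctan2(num, den)


def tessellate(cavity: Cavity, level: int = 3) -> list:
    """Exposed surface tesserae of the sphere union.

    Each sphere carries an icosphere mesh; a face survives if its
    representative point (projected face centroid) is not strictly inside
    any other sphere.  Surviving tesserae keep their full spherical patch
    area.
    """
    verts, faces = icosphere(level)
    centroids = verts[faces].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    unit_areas = _spherical_face_areas(verts, faces)

    tesserae = []
    for s in range(cavity.n_spheres):
        c, r = cavity.centers[s], cavity.radii[s]
        pts = c + r * centroids
        keep = np.ones(len(pts), dtype=bool)
        for t in range(cavity.n_spheres):
            if t == s:
                continue
            d = np.linalg.norm(pts - cavity.centers[t], axis=1)
            keep &= d >= cavity.radii[t] - 1e-9
        for k in np.nonzero(keep)[0]:
            tesserae.append(
                Tessera(
                    center=pts[k],
                    area=float(unit_areas[k] * r * r),
                    normal=centroids[k],
                    parent=s,
                )
            )
    return tesserae


def _inside_union(points: np.ndarray, cavity: Cavity) -> np.ndarray:
    d2 = np.sum((points[:, None, :] - cavity.centers[None]) ** 2, axis=-1)
    return np.any(d2 <= cavity.radii[None] ** 2, axis=1)


def cavity_volume(
    cavity: Cavity,
    method: str = "surface",
    level: int = 4,
    n_samples: int = 1_000_000,
    seed: int = 0,
    return_stderr: bool = False,
):
    """Volume of the sphere union, Å³.

    ``method="surface"``: divergence-theorem estimate
    V = (1/3) Σᵢ areaᵢ (centerᵢ − p)·normalᵢ over the tessellation, with
    p the sphere-centroid origin to reduce cancellation.
    ``method="mc"``: seeded hit-or-miss Monte Carlo over the union's
    bounding box (≥ 10⁴ samples required); optionally returns the
    binomial standard error.
    """
    if method == "surface":
        tesserae = tessellate(cavity, level=level)
        origin = cavity.centers.mean(axis=0)
        v = sum(t.area * float(np.dot(t.center - origin, t.normal)) for t in tesserae) / 3.0
        return (v, 0.0) if return_stderr else v
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    if n_samples < 10_000:
        raise ValueError("Monte-Carlo volume needs at least 1e4 samples")
    rng = np.random.default_rng(seed)
    lo = (cavity.centers - cavity.radii[:, None]).min(axis=0)
    hi = (cavity.centers + cavity.radii[:, None]).max(axis=0)
    box = float(np.prod(hi - lo))
    hits = 0
    chunk = 200_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        pts = rng.uniform(lo, hi, size=(m, 3))
        hits += int(np.count_nonzero(_inside_union(pts, cavity)))
        done += m
    p = hits / n_samples
    vol = p * box
    stderr = box * np.sqrt(max(p * (1 - p), 0.0) / n_samples)
    return (vol, stderr) if return_stderr else vol


def volume_ratio(cavity_b: Cavity, cavity_a: Cavity, **kwargs) -> float:
    """V_B/V_A with identical method/settings for both cavities (the
    molar-volume-ratio surrogate used in excess-polarizability work)."""
    vb = cavity_volume(cavity_b, **kwargs)
    va = cavity_volume(cavity_a, **kwargs)
    if isinstance(vb, tuple):
        vb, va = vb[0], va[0]
    return vb / va
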