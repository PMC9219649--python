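"""Shrake–Rupley solvent-accessible surface area.

Per-atom SASA is computed by placing a deterministic golden-spiral point
set on each atom's solvent-expanded sphere (radius ``r + probe``) and
counting the points that fall outside every neighbouring expanded
sphere:

    area_i = (exposed points / n_points) · 4π (r_i + r_probe)²

The module also provides the fully-exposed side-chain reference areas
(computed on extended Gly-X-Gly tripeptides with the same engine) that
normalise the exposed-fraction terms of the spatial-aggregation-
propensity score.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from aggroscan import peptides
from aggroscan.structio import Structure

__all__ = [
    "SasaResult",
    "sphere_points",
    "shrake_rupley",
    "reference_sidechain_saa",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_POINTS",
]

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class SasaResult:
    """Per-atom solvent-accessible areas (Å²) with quadrature metadata."""

    per_atom_area: np.ndarray
    probe_radius: float
    n_sphere_points: int

    def __post_init__(self) -> None:
        area = np.asarray(self.per_atom_area, dtype=float)
        if np.any(area < 0):
            raise ValueError("areas must be non-negative")
        object.__setattr__(self, "per_atom_area", area)

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())


@lru_cache(maxsize=8)
def sphere_points(n_points: int) -> np.ndarray:
    """Deterministic golden-spiral unit vectors on the sphere.

    Points are laid out at uniform z spacing with azimuths advanced by the
    golden angle, giving near-uniform coverage without randomness.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n_points)
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def shrake_rupley(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Per-atom Shrake–Rupley SASA of a structure.

    Deterministic for fixed ``n_points``: a test point on atom *i*'s
    expanded sphere counts as exposed iff it lies outside every other
    atom's solvent-expanded sphere.
    """
    if len(structure) == 0:
        raise ValueError("cannot compute SASA of an empty structure")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    if n_points < 12:
        raise ValueError("n_points must be >= 12")

    coords = structure.coords
    expanded = structure.vdw_radii + probe_radius
    n = len(structure)
    unit = sphere_points(n_points)

    # neighbour lists from the pair distance matrix (test-scale systems)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    cutoff = expanded[:, None] + expanded[None, :]
    neighbour_mask = (dist < cutoff) & ~np.eye(n, dtype=bool)

    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in np.flatnonzero(neighbour_mask[i]):
            d = pts[exposed] - coords[j]
            # boundary counts as buried (a co-located twin occludes fully);
            # the relative tolerance absorbs roundoff on the sphere surface
            buried = np.einsum("ij,ij->i", d, d) <= expanded[j] ** 2 * (1 + 1e-10)
            idx = np.flatnonzero(exposed)
            exposed[idx[buried]] = False
            if not exposed.any():
                break
        areas[i] = exposed.sum() / n_points * 4.0 * np.pi * expanded[i] ** 2
    return SasaResult(per_atom_area=areas, probe_radius=probe_radius, n_sphere_points=n_points)


@lru_cache(maxsize=256)
def _reference_saa_cached(residue_name: str, probe_radius: float, n_points: int) -> float:
    structure = peptides.build_peptide(["GLY", residue_name, "GLY"], "extended")
    result = shrake_rupley(structure, probe_radius=probe_radius, n_points=n_points)
    central_sidechain = [
        i
        for i, atom in enumerate(structure)
        if atom.residue_seq == 2 and peptides.is_sidechain_atom(atom.name)
    ]
    return float(result.per_atom_area[central_sidechain].sum())


def reference_sidechain_saa(
    residue_name: str,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Side-chain SAA (Å²) of residue X fully exposed in extended Gly-X-Gly.

    Computed once per (residue, probe, quadrature) with the same engine as
    :func:`shrake_rupley` and cached.  Glycine has an empty side chain
    under the backbone-(N, CA, C, O, H*) convention, hence 0.
    """
    key = residue_name.strip().upper()
    if key not in peptides.SIDECHAIN_ATOMS:
        raise ValueError(
            f"unknown residue {residue_name!r}; supported: "
            f"{', '.join(peptides.CANONICAL_RESIDUES)}"
        )
    if key == "GLY":
        return 0.0
    return _reference_saa_cached(key, float(probe_radius), int(n_points))
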