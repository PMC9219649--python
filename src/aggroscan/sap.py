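"""Spatial Aggregation Propensity (SAP) scoring.

The SAP score of atom *i* at radius *R* sums, over every residue having
at least one atom within *R* of atom *i*, the solvent-exposed fraction of
that residue's side chain (restricted to side-chain atoms within *R*)
weighted by the residue's hydrophobicity:

    SAP_i = Σ_res [ SAA(side-chain atoms of res within R of i)
                    / SAA(side chain of res fully exposed) ] · H(res)

Positive scores mark exposed hydrophobic patches; trajectory scores are
the arithmetic mean of per-frame scores.  Hydrophobicities use the Black
& Mould scale normalised to [0, 1] and shifted so glycine is 0, which
makes hydrophilic residues negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from aggroscan import peptides
from aggroscan.sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE_RADIUS,
    SasaResult,
    reference_sidechain_saa,
    shrake_rupley,
)
from aggroscan.structio import Structure, Trajectory

__all__ = [
    "HydrophobicityScale",
    "SapProfile",
    "atom_sap_frame",
    "frame_sap",
    "trajectory_sap",
    "extract_hotspots",
    "DEFAULT_RADIUS",
    "DEFAULT_HOTSPOT_THRESHOLD",
]

DEFAULT_RADIUS = 10.0  # Å
DEFAULT_HOTSPOT_THRESHOLD = 0.15

# Black & Mould (1991) hydrophobicities, published normalised to [0, 1].
_BLACK_MOULD_NORMALISED: dict[str, float] = {
    "ALA": 0.616, "ARG": 0.000, "ASN": 0.236, "ASP": 0.028, "CYS": 0.680,
    "GLN": 0.251, "GLU": 0.043, "GLY": 0.501, "HIS": 0.165, "ILE": 0.943,
    "LEU": 0.943, "LYS": 0.283, "MET": 0.738, "PHE": 1.000, "PRO": 0.711,
    "SER": 0.359, "THR": 0.450, "TRP": 0.878, "TYR": 0.880, "VAL": 0.825,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Residue hydrophobicities with glycine pinned to zero."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(peptides.CANONICAL_RESIDUES) - set(self.values)
        if missing:
            raise ValueError(f"scale missing residues: {sorted(missing)}")
        if abs(self.values["GLY"]) > 1e-12:
            raise ValueError("scale must assign glycine hydrophobicity 0")
        if any(abs(v) > 1.0 for v in self.values.values()):
            raise ValueError("scale values must lie in [-1, 1]")

    def __getitem__(self, residue_name: str) -> float:
        return self.values[residue_name.strip().upper()]

    def __contains__(self, residue_name: str) -> bool:
        return residue_name.strip().upper() in self.values

    @classmethod
    def black_mould(cls) -> "HydrophobicityScale":
        """The Black & Mould scale shifted so that glycine = 0."""
        gly = _BLACK_MOULD_NORMALISED["GLY"]
        return cls({k: v - gly for k, v in _BLACK_MOULD_NORMALISED.items()})


@dataclass
class SapProfile:
    """Per-atom and residue-averaged SAP scores for one structure/ensemble."""

    structure: Structure
    radius: float
    per_atom_sap: np.ndarray
    per_residue_sap: dict[tuple, float]
    residue_names: dict[tuple, str] = field(default_factory=dict)
    n_frames_averaged: int = 1

    def __post_init__(self) -> None:
        self.per_atom_sap = np.asarray(self.per_atom_sap, dtype=float)
        if self.per_atom_sap.shape != (len(self.structure),):
            raise ValueError("one SAP score per atom required")
        if not np.all(np.isfinite(self.per_atom_sap)):
            raise ValueError("SAP scores must be finite")


def _scored_residues(structure: Structure, scale: HydrophobicityScale) -> dict:
    """Residue key -> (name, member indices, side-chain indices) for
    canonical residues; non-canonical residues are skipped with a warning."""
    out = {}
    skipped = set()
    for key, members in structure.residues().items():
        name = structure.residue_name(key)
        if name not in scale:
            skipped.add(name)
            continue
        side = [i for i in members if peptides.is_sidechain_atom(structure.atoms[i].name)]
        out[key] = (name, members, side)
    if skipped:
        warnings.warn(
            f"ignoring non-canonical residues in SAP sums: {sorted(skipped)}",
            stacklevel=3,
        )
    return out


def atom_sap_frame(
    structure: Structure,
    sasa_result: SasaResult,
    atom_i: int,
    radius: float = DEFAULT_RADIUS,
    scale: HydrophobicityScale | None = None,
) -> float:
    """Single-frame SAP score of one atom.

    A residue enters the sum iff at least one of its atoms lies within
    ``radius`` of atom *i*; its numerator counts side-chain atoms whose
    centres lie within ``radius``.  Residues with zero reference area
    (glycine) contribute 0.
    """
    if not 0 <= atom_i < len(structure):
        raise IndexError(f"atom index {atom_i} out of range for {len(structure)} atoms")
    if radius <= 0:
        raise ValueError("radius must be positive")
    scale = scale or HydrophobicityScale.black_mould()
    coords = structure.coords
    dist = np.linalg.norm(coords - coords[atom_i], axis=1)
    score = 0.0
    for key, (name, members, side) in _scored_residues(structure, scale).items():
        if not np.any(dist[members] <= radius):
            continue
        ref = reference_sidechain_saa(
            name, sasa_result.probe_radius, sasa_result.n_sphere_points
        )
        if ref == 0.0:
            continue
        near_side = [j for j in side if dist[j] <= radius]
        if not near_side:
            continue
        saa = float(sasa_result.per_atom_area[near_side].sum())
        frac = saa / ref
        if frac > 1.0 + 1e-9:
            warnings.warn(
                f"exposed fraction {frac:.3f} > 1 for residue {name} {key}; "
                "conformer exceeds the fully-exposed reference",
                stacklevel=2,
            )
        score += frac * scale[name]
    return score


def frame_sap(
    structure: Structure,
    radius: float = DEFAULT_RADIUS,
    scale: HydrophobicityScale | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
    residue_average: str = "all",
) -> SapProfile:
    """Single-structure SAP profile: per-atom scores and residue averages.

    SASA is computed once and reused for every atom.  Hydrogens are
    excluded by default (``include_hydrogens=True`` keeps them).
    ``residue_average`` is ``"all"`` (mean over every residue atom) or
    ``"sidechain"`` (mean over side-chain atoms only).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    if residue_average not in ("all", "sidechain"):
        raise ValueError("residue_average must be 'all' or 'sidechain'")
    if not include_hydrogens:
        heavy = [i for i, a in enumerate(structure) if a.element.upper() != "H"]
        if len(heavy) < len(structure):
            structure = structure.subset(heavy)
    scale = scale or HydrophobicityScale.black_mould()
    sasa_result = shrake_rupley(structure, probe_radius=probe_radius, n_points=n_points)

    coords = structure.coords
    residues = _scored_residues(structure, scale)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))

    per_atom = np.zeros(len(structure))
    for key, (name, members, side) in residues.items():
        ref = reference_sidechain_saa(name, probe_radius, n_points)
        hydro = scale[name]
        if ref == 0.0 or not side:
            continue
        # contribution of this residue to every atom i at once
        within = dist[:, members] <= radius  # residue triggers for atom i
        triggered = within.any(axis=1)
        side_within = dist[:, side] <= radius
        saa_sum = side_within @ sasa_result.per_atom_area[side]
        per_atom += np.where(triggered, saa_sum / ref * hydro, 0.0)

    per_residue: dict[tuple, float] = {}
    residue_names: dict[tuple, str] = {}
    for key, members in structure.residues().items():
        name = structure.residue_name(key)
        if residue_average == "sidechain":
            pool = [i for i in members if peptides.is_sidechain_atom(structure.atoms[i].name)]
            pool = pool or members
        else:
            pool = members
        per_residue[key] = float(per_atom[pool].mean())
        residue_names[key] = name
    return SapProfile(
        structure=structure,
        radius=radius,
        per_atom_sap=per_atom,
        per_residue_sap=per_residue,
        residue_names=residue_names,
        n_frames_averaged=1,
    )


def trajectory_sap(
    trajectory: Trajectory,
    radius: float = DEFAULT_RADIUS,
    scale: HydrophobicityScale | None = None,
    stride: int = 1,
    **frame_kwargs,
) -> SapProfile:
    """Trajectory-averaged SAP: arithmetic mean of per-frame profiles."""
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    indices = range(0, trajectory.n_frames, stride)
    profiles = [
        frame_sap(trajectory.frame_structure(f), radius=radius, scale=scale, **frame_kwargs)
        for f in indices
    ]
    n = len(profiles)
    per_atom = np.mean([p.per_atom_sap for p in profiles], axis=0)
    keys = profiles[0].per_residue_sap.keys()
    per_residue = {k: float(np.mean([p.per_residue_sap[k] for p in profiles])) for k in keys}
    return SapProfile(
        structure=profiles[0].structure,
        radius=radius,
        per_atom_sap=per_atom,
        per_residue_sap=per_residue,
        residue_names=profiles[0].residue_names,
        n_frames_averaged=n,
    )


def extract_hotspots(
    profile: SapProfile, threshold: float = DEFAULT_HOTSPOT_THRESHOLD
) -> list[tuple[str, int, str, float]]:
    """Residues whose average SAP exceeds ``threshold``.

    Returns (chain_id, residue_seq, residue_name, sap) tuples sorted by
    descending SAP, ties broken by (chain, residue number).
    """
    rows = [
        (key[0], key[1], profile.residue_names.get(key, "UNK"), value)
        for key, value in profile.per_residue_sap.items()
        if value > threshold
    ]
    rows.sort(key=lambda r: (-r[3], r[0], r[1]))
    return rows
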