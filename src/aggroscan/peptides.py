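"""Idealised peptide geometry templates.

Provides the toy-peptide builder shared by the synthetic-data generators
and the fully-exposed Gly-X-Gly reference fixtures used to normalise SAP
scores.  Residues are built from an idealised extended backbone (N, CA,
C, O) with heavy side-chain pseudo-atoms laid out in a solvent-pointing
zig-zag; this is deliberately not a rotamer library — it exists to give
the SASA/SAP machinery structures with known exposure, correct atom
names, masses and radii.
"""

from __future__ import annotations

import numpy as np

from aggroscan.structio import (
    Atom,
    Structure,
    element_mass,
    element_vdw_radius,
    guess_element,
)

__all__ = [
    "CANONICAL_RESIDUES",
    "SIDECHAIN_ATOMS",
    "BACKBONE_ATOM_NAMES",
    "is_sidechain_atom",
    "build_peptide",
]

# Heavy side-chain atoms per canonical residue (PDB naming).
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

CANONICAL_RESIDUES: tuple[str, ...] = tuple(sorted(SIDECHAIN_ATOMS))

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Backbone heavy atoms and their hydrogens; everything else is side chain.
BACKBONE_ATOM_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HN",
     "HA", "HA1", "HA2", "HA3", "1H", "2H", "3H"}
)


def is_sidechain_atom(atom_name: str) -> bool:
    return atom_name.strip().upper() not in BACKBONE_ATOM_NAMES


_CA_SPACING = 3.8  # Å between consecutive Cα in the extended form


def _residue_atom_positions(resname: str, base_x: float) -> list[tuple[str, np.ndarray]]:
    """Backbone + side-chain pseudo-atom positions for one residue."""
    positions = [
        ("N", np.array([base_x - 1.23, 0.30, 0.0])),
        ("CA", np.array([base_x, 0.0, 0.0])),
        ("C", np.array([base_x + 1.26, 0.30, 0.0])),
        ("O", np.array([base_x + 1.26, 1.53, 0.0])),
    ]
    for k, name in enumerate(SIDECHAIN_ATOMS[resname]):
        # zig-zag rising away from the backbone plane (+z, −y)
        pos = np.array([base_x + 0.5 * (k % 2), -0.9, 1.3 * (k + 1)])
        positions.append((name, pos))
    return positions


def build_peptide(sequence: str | list[str], conformation: str = "extended") -> Structure:
    """Build an idealised peptide Structure from a sequence.

    ``sequence`` accepts one-letter codes (``"GAG"``) or a list of
    three-letter codes.  ``conformation`` is ``"extended"`` (residues at
    3.8 Å Cα spacing, side chains pointing into solvent, no side-chain
    burial beyond nearest-neighbour effects) or ``"compact"`` (the same
    topology isotropically contracted about its centroid, burying
    surface).
    """
    if isinstance(sequence, str):
        try:
            resnames = [ONE_TO_THREE[ch.upper()] for ch in sequence]
        except KeyError as exc:
            raise ValueError(f"unknown residue code {exc.args[0]!r}") from exc
    else:
        resnames = [r.upper() for r in sequence]
    for r in resnames:
        if r not in SIDECHAIN_ATOMS:
            raise ValueError(
                f"unknown residue {r!r}; supported: {', '.join(CANONICAL_RESIDUES)}"
            )
    if conformation not in ("extended", "compact"):
        raise ValueError("conformation must be 'extended' or 'compact'")

    atoms: list[Atom] = []
    serial = 1
    for i, resname in enumerate(resnames):
        for name, pos in _residue_atom_positions(resname, base_x=i * _CA_SPACING):
            element = guess_element(name)
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name=resname,
                    residue_seq=i + 1,
                    chain_id="A",
                    coords=pos,
                    mass=element_mass(element),
                    vdw_radius=element_vdw_radius(element),
                )
            )
            serial += 1
    structure = Structure(atoms)
    if conformation == "compact":
        coords = structure.coords
        centroid = coords.mean(axis=0)
        structure = structure.with_coords(centroid + 0.65 * (coords - centroid))
    return structure
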