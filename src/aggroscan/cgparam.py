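"""Bottom-up coarse-grained (MARTINI-style) parametrisation.

Maps an atomistic trajectory onto beads (mass-weighted centres of mass),
measures bonded coordinates (bonds in nm, angles/dihedrals in degrees),
locates equilibrium values as the most prominent histogram peak, derives
harmonic force constants by Boltzmann inversion of the peak width
(k = k_B·T / σ²), builds an ElNeDyn-style elastic network over backbone
beads, and emits GROMACS ``.itp`` topology text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from aggroscan.structio import Trajectory

__all__ = [
    "Bead",
    "MappingScheme",
    "BeadTrajectory",
    "BondedTerm",
    "ElasticBond",
    "CgTopology",
    "read_mapping",
    "map_to_beads",
    "measure_bonded_series",
    "histogram_peak",
    "fit_harmonic",
    "elastic_network",
    "emit_itp",
    "KB_KJ_PER_MOL_K",
    "ELNEDYN_CUTOFF_NM",
    "ELNEDYN_FORCE_CONSTANT",
]

logger = logging.getLogger(__name__)

KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ mol⁻¹ K⁻¹
ELNEDYN_CUTOFF_NM = 0.9
ELNEDYN_FORCE_CONSTANT = 500.0  # kJ mol⁻¹ nm⁻²


@dataclass(frozen=True)
class Bead:
    """One CG bead: MARTINI type (ordinary or S-class), charge, members."""

    name: str
    martini_type: str
    members: tuple[str, ...]
    charge: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"bead {self.name!r} has no member atoms")


@dataclass(frozen=True)
class MappingScheme:
    """Bead definitions for one molecule; every mapped atom in exactly one bead."""

    molecule_name: str
    beads: tuple[Bead, ...]

    def __post_init__(self) -> None:
        if not self.beads:
            raise ValueError("mapping needs at least one bead")
        seen: dict[str, str] = {}
        for bead in self.beads:
            for atom in bead.members:
                if atom in seen:
                    raise ValueError(
                        f"atom {atom!r} mapped to both {seen[atom]!r} and {bead.name!r}"
                    )
                seen[atom] = bead.name


def read_mapping(path) -> MappingScheme:
    """Read the declarative mapping format.

    First non-comment line: molecule name.  Then one bead per line:
    ``bead_name martini_type charge member_atom [member_atom ...]``.
    """
    beads = []
    molecule = None
    with open(path) as handle:
        for raw in handle:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if molecule is None:
                molecule = line.split()[0]
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"mapping line needs >= 4 fields: {raw!r}")
            beads.append(
                Bead(
                    name=fields[0],
                    martini_type=fields[1],
                    charge=float(fields[2]),
                    members=tuple(fields[3:]),
                )
            )
    if molecule is None:
        raise ValueError(f"{path}: empty mapping file")
    return MappingScheme(molecule_name=molecule, beads=tuple(beads))


@dataclass
class BeadTrajectory:
    """Bead coordinates per frame in nm, with names/types/charges/masses."""

    names: list[str]
    types: list[str]
    charges: np.ndarray
    masses: np.ndarray
    coords: np.ndarray  # (n_frames, n_beads, 3), nm

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_beads(self) -> int:
        return int(self.coords.shape[1])


_A_TO_NM = 0.1


def map_to_beads(trajectory: Trajectory, mapping: MappingScheme) -> BeadTrajectory:
    """Map an atomistic trajectory (Å) to CG beads (nm).

    Each bead coordinate is the mass-weighted centre of mass of its member
    atoms; bead mass is the sum of member masses.
    """
    names = [atom.name for atom in trajectory.topology]
    if len(set(names)) != len(names):
        raise ValueError(
            "atom names in the topology are not unique; name-based bead "
            "mapping needs a single small molecule with distinct atom names"
        )
    name_to_index = {name: i for i, name in enumerate(names)}
    member_idx: list[np.ndarray] = []
    for bead in mapping.beads:
        missing = [a for a in bead.members if a not in name_to_index]
        if missing:
            raise ValueError(f"bead {bead.name!r}: atoms not in topology: {missing}")
        member_idx.append(np.array([name_to_index[a] for a in bead.members]))

    atom_masses = trajectory.topology.masses
    bead_masses = np.array([atom_masses[idx].sum() for idx in member_idx])
    n_frames = trajectory.n_frames
    coords = np.empty((n_frames, len(mapping.beads), 3))
    for b, idx in enumerate(member_idx):
        w = atom_masses[idx] / atom_masses[idx].sum()
        coords[:, b, :] = np.einsum("fij,i->fj", trajectory.frames[:, idx, :], w)
    return BeadTrajectory(
        names=[b.name for b in mapping.beads],
        types=[b.martini_type for b in mapping.beads],
        charges=np.array([b.charge for b in mapping.beads]),
        masses=bead_masses,
        coords=coords * _A_TO_NM,
    )


@dataclass(frozen=True)
class BondedTerm:
    """A bonded interaction: bond (2 beads), angle (3) or dihedral (4).

    Equilibrium values are nm for bonds and degrees for angles/dihedrals;
    force constants kJ mol⁻¹ nm⁻² and kJ mol⁻¹ rad⁻² respectively.
    ``constraint`` terms (rigid ring edges) carry a length but no force
    constant.
    """

    kind: str
    indices: tuple[int, ...]
    equilibrium: float = float("nan")
    force_constant: float = float("nan")

    _ARITY = {"bond": 2, "constraint": 2, "angle": 3, "dihedral": 4}

    def __post_init__(self) -> None:
        if self.kind not in self._ARITY:
            raise ValueError(f"unknown bonded kind {self.kind!r}")
        n = self._ARITY[self.kind]
        if len(self.indices) != n or len(set(self.indices)) != n:
            raise ValueError(f"{self.kind} needs {n} distinct bead indices")
        eq = self.equilibrium
        if np.isfinite(eq):
            if self.kind in ("bond", "constraint") and eq <= 0:
                raise ValueError("equilibrium bond length must be positive")
            if self.kind == "angle" and not 0 < eq <= 180:
                raise ValueError("equilibrium angle must lie in (0, 180]")
            if self.kind == "dihedral" and not -180 < eq <= 180:
                raise ValueError("equilibrium dihedral must lie in (-180, 180]")


def measure_bonded_series(bead_trajectory: BeadTrajectory, term: BondedTerm) -> np.ndarray:
    """Per-frame value of one bonded coordinate (nm or degrees).

    Degenerate geometry (a zero-length bond inside an angle or dihedral)
    is flagged with a warning and yields NaN for the affected frames.
    """
    idx = term.indices
    if max(idx) >= bead_trajectory.n_beads:
        raise IndexError(f"bead index {max(idx)} out of range")
    x = bead_trajectory.coords
    if term.kind in ("bond", "constraint"):
        return np.linalg.norm(x[:, idx[1]] - x[:, idx[0]], axis=1)
    if term.kind == "angle":
        u = x[:, idx[0]] - x[:, idx[1]]
        v = x[:, idx[2]] - x[:, idx[1]]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        bad = (nu == 0) | (nv == 0)
        if bad.any():
            warnings.warn(f"degenerate angle geometry in {bad.sum()} frame(s)")
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    # dihedral: signed torsion about the b2 axis, IUPAC convention
    b1 = x[:, idx[1]] - x[:, idx[0]]
    b2 = x[:, idx[2]] - x[:, idx[1]]
    b3 = x[:, idx[3]] - x[:, idx[2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2, axis=1)
    bad = (np.linalg.norm(n1, axis=1) == 0) | (np.linalg.norm(n2, axis=1) == 0)
    if bad.any():
        warnings.warn(f"degenerate dihedral geometry in {bad.sum()} frame(s)")
    with np.errstate(invalid="ignore", divide="ignore"):
        xcomp = np.einsum("ij,ij->i", n1, n2)
        ycomp = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / norm_b2[:, None])
        ang = np.degrees(np.arctan2(ycomp, xcomp))
    # map -180 exactly to +180 so the range is (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    ang = np.where(bad, np.nan, ang)
    return ang


def _histogram(series: np.ndarray, n_bins: int | None):
    if n_bins is None:
        # Freedman–Diaconis with a floor of 30 bins
        q75, q25 = np.percentile(series, [75, 25])
        iqr = q75 - q25
        if iqr > 0:
            width = 2 * iqr / len(series) ** (1 / 3)
            n_bins = max(30, int(np.ceil((series.max() - series.min()) / width)))
        else:
            n_bins = 30
    counts, edges = np.histogram(series, bins=n_bins)
    return counts, edges


def histogram_peak(series: Sequence[float], n_bins: int | None = None) -> float:
    """Equilibrium value as the most prominent histogram peak.

    The highest-count bin wins (ties break toward the smaller value, with
    a log message); the returned value is refined to the mean of the
    samples inside that bin.  A constant series returns the constant.
    """
    series = np.asarray(series, dtype=float)
    series = series[np.isfinite(series)]
    if series.size == 0:
        raise ValueError("empty series")
    if series.max() == series.min():
        return float(series[0])
    counts, edges = _histogram(series, n_bins)
    peak_bin = int(np.argmax(counts))
    if np.count_nonzero(counts == counts[peak_bin]) > 1:
        logger.info("histogram peak tie; choosing the smaller-valued mode")
    lo, hi = edges[peak_bin], edges[peak_bin + 1]
    in_bin = (series >= lo) & (series <= hi if peak_bin == len(counts) - 1 else series < hi)
    return float(series[in_bin].mean())


# variance retained by a normal distribution truncated at ±3σ; the ±3σ
# window around the peak removes this fraction of the variance, so the
# fitted width is corrected by it to keep the inversion unbiased
_TRUNC3_VARIANCE_FACTOR = 0.973337

def fit_harmonic(
    series: Sequence[float],
    temperature_K: float = 300.0,
    kind: str = "bond",
    n_bins: int | None = None,
) -> float:
    """Harmonic force constant by Boltzmann inversion of the mode width.

    The width of the prominent mode is estimated from samples within ±3σ
    of the histogram peak (initial σ from the robust MAD about the peak,
    one re-estimation pass — this confines the fit to the prominent
    mode's basin for multimodal data) and inverted as k = k_B·T/σ².
    Angles and dihedrals are converted to radians first, giving
    kJ mol⁻¹ rad⁻²; bonds give kJ mol⁻¹ nm⁻².
    """
    series = np.asarray(series, dtype=float)
    series = series[np.isfinite(series)]
    if series.size < 2 or series.var() == 0:
        raise ValueError("rigid coordinate (zero variance); constrain instead")
    peak = histogram_peak(series, n_bins)
    sigma_mad = 1.4826 * np.median(np.abs(series - peak))
    if sigma_mad == 0:
        raise ValueError("rigid coordinate (zero variance); constrain instead")
    selected = series[np.abs(series - peak) <= 3 * sigma_mad]
    sigma1 = selected.std()
    refined = series[np.abs(series - peak) <= 3 * sigma1]
    if refined.size < 2:
        refined = selected
    sigma2 = refined.var() / _TRUNC3_VARIANCE_FACTOR
    sigma = np.sqrt(sigma2)
    if kind in ("angle", "dihedral"):
        sigma = np.radians(sigma)
    return float(KB_KJ_PER_MOL_K * temperature_K / sigma**2)


@dataclass(frozen=True)
class ElasticBond:
    i: int
    j: int
    length: float  # nm
    force_constant: float  # kJ mol⁻¹ nm⁻²


def elastic_network(
    coords_nm: np.ndarray,
    backbone_indices: Sequence[int] | None = None,
    cutoff: float = ELNEDYN_CUTOFF_NM,
    force_constant: float = ELNEDYN_FORCE_CONSTANT,
    bonded_pairs: set[tuple[int, int]] | None = None,
) -> list[ElasticBond]:
    """ElNeDyn-style elastic network over backbone beads.

    One harmonic bond per backbone-bead pair closer than ``cutoff`` (nm),
    with the observed distance as equilibrium and a uniform force
    constant; pairs already covered by bonded terms are excluded.
    Defaults are 0.9 nm and 500 kJ mol⁻¹ nm⁻².
    """
    coords = np.asarray(coords_nm, dtype=float)
    idx = np.arange(len(coords)) if backbone_indices is None else np.asarray(backbone_indices)
    exclude = {tuple(sorted(p)) for p in (bonded_pairs or set())}
    bonds = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = int(idx[a]), int(idx[b])
            if (i, j) in exclude:
                continue
            d = float(np.linalg.norm(coords[j] - coords[i]))
            if d <= cutoff:
                bonds.append(ElasticBond(i=i, j=j, length=d, force_constant=force_constant))
    return bonds


@dataclass
class CgTopology:
    """A complete CG molecule: mapping, bonded terms, elastic network, masses."""

    mapping: MappingScheme
    bonded_terms: list[BondedTerm] = field(default_factory=list)
    elastic_bonds: list[ElasticBond] = field(default_factory=list)
    masses: np.ndarray | None = None

    def validate(self) -> None:
        n = len(self.mapping.beads)
        seen: set[tuple] = set()
        for term in self.bonded_terms:
            if max(term.indices) >= n:
                raise ValueError(f"{term.kind} indices {term.indices} out of range")
            key = (term.kind, term.indices)
            if key in seen:
                raise ValueError(f"duplicate {term.kind} over beads {term.indices}")
            seen.add(key)
            if not np.isfinite(term.equilibrium):
                raise ValueError(f"{term.kind} {term.indices}: equilibrium not set")


def emit_itp(topology: CgTopology, molecule_name: str | None = None) -> str:
    """Render a CG topology as GROMACS ``.itp`` text.

    Sections appear in canonical order ([moleculetype], [atoms], then
    [bonds]/[constraints]/[angles]/[dihedrals] as populated); bonds in nm,
    angles and dihedrals in degrees; bead indices are 1-based.
    """
    topology.validate()
    name = molecule_name or topology.mapping.molecule_name
    masses = (
        topology.masses
        if topology.masses is not None
        else np.full(len(topology.mapping.beads), 72.0)  # ordinary MARTINI bead
    )
    lines = [
        "[ moleculetype ]",
        "; name  nrexcl",
        f"{name}  1",
        "",
        "[ atoms ]",
        "; nr  type  resnr  residue  atom  cgnr  charge  mass",
    ]
    for i, bead in enumerate(topology.mapping.beads, start=1):
        lines.append(
            f"{i:>4d}  {bead.martini_type:<5s}  1  {name:<8s}  "
            f"{bead.name:<5s}  {i:>4d}  {bead.charge:8.3f}  {masses[i - 1]:8.3f}"
        )
    by_kind: dict[str, list[BondedTerm]] = {}
    for term in topology.bonded_terms:
        by_kind.setdefault(term.kind, []).append(term)

    def idx1(t: BondedTerm) -> str:
        return "  ".join(f"{i + 1:>4d}" for i in t.indices)

    if by_kind.get("bond") or topology.elastic_bonds:
        lines += ["", "[ bonds ]", ";  i    j  funct  length  force_constant"]
        for t in by_kind.get("bond", []):
            lines.append(f"{idx1(t)}  1  {t.equilibrium:8.4f}  {t.force_constant:10.1f}")
        for eb in topology.elastic_bonds:
            lines.append(
                f"{eb.i + 1:>4d}  {eb.j + 1:>4d}  1  {eb.length:8.4f}  "
                f"{eb.force_constant:10.1f}  ; elastic"
            )
    if by_kind.get("constraint"):
        lines += ["", "[ constraints ]", ";  i    j  funct  length"]
        for t in by_kind["constraint"]:
            lines.append(f"{idx1(t)}  1  {t.equilibrium:8.4f}")
    if by_kind.get("angle"):
        lines += ["", "[ angles ]", ";  i    j    k  funct  angle  force_constant"]
        for t in by_kind["angle"]:
            lines.append(f"{idx1(t)}  2  {t.equilibrium:8.2f}  {t.force_constant:10.1f}")
    if by_kind.get("dihedral"):
        lines += ["", "[ dihedrals ]", ";  i    j    k    l  funct  angle  force_constant"]
        for t in by_kind["dihedral"]:
            lines.append(f"{idx1(t)}  1  {t.equilibrium:8.2f}  {t.force_constant:10.1f}  1")
    return "\n".join(lines) + "\n"
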