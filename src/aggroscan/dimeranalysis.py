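"""Replicate-ensemble analysis of two-molecule CG trajectories.

Given many short replicate simulations of two protein fragments (plus
optional excipient molecules), this module computes:

* minimum inter-molecular bead distances (minimum-image when a box is
  present);
* contact occurrence maps — for every frame of every replicate, each
  cross-molecule bead pair within a cutoff increments its count, with a
  residue-level roll-up;
* excipient residence — per-residue occupancy of excipient centres of
  mass near the protein;
* inter-molecular nonbonded energy as the MARTINI-style sum of 12-6
  Lennard-Jones and screened Coulomb terms, each potential-shifted to
  zero at the cutoff (default 1.8 nm);
* ensemble plateau energies — the mean across replicates over the final
  quarter of the time grid, with an exponential-approach fit
  E(t) = E∞(1 − e^(−t/τ)) as a cross-check.

All coordinates are nm and energies kJ/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BeadFrame",
    "NonbondedTable",
    "OccurrenceMap",
    "EnergySeries",
    "PlateauResult",
    "min_interbead_distance",
    "contact_occurrence_map",
    "excipient_residence",
    "pair_interaction_energy",
    "ensemble_plateau",
    "DEFAULT_CONTACT_CUTOFF_NM",
    "DEFAULT_NONBONDED_CUTOFF_NM",
    "MARTINI_RELATIVE_DIELECTRIC",
    "COULOMB_CONSTANT",
]

DEFAULT_CONTACT_CUTOFF_NM = 0.6
DEFAULT_NONBONDED_CUTOFF_NM = 1.8
MARTINI_RELATIVE_DIELECTRIC = 15.0
COULOMB_CONSTANT = 138.935458  # kJ mol⁻¹ nm e⁻²


@dataclass
class BeadFrame:
    """One CG frame: coordinates (nm) plus per-bead identity.

    ``mol_labels`` names the molecule each bead belongs to (e.g. "FvA",
    "FvB", "EXC1"); ``residue_labels`` identifies the residue of each
    protein bead (any hashable; None for non-protein beads).
    """

    coords: np.ndarray
    types: list[str]
    mol_labels: list[str]
    charges: np.ndarray | None = None
    residue_labels: list | None = None
    masses: np.ndarray | None = None
    box: np.ndarray | None = None  # orthorhombic box lengths, nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be a finite (n, 3) array")
        if len(self.mol_labels) != n or len(self.types) != n:
            raise ValueError("one type and one molecule label per bead required")
        if self.charges is None:
            self.charges = np.zeros(n)
        else:
            self.charges = np.asarray(self.charges, dtype=float)
        if self.masses is None:
            self.masses = np.ones(n)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def indices_of(self, label: str) -> np.ndarray:
        idx = np.array([i for i, m in enumerate(self.mol_labels) if m == label], dtype=int)
        if idx.size == 0:
            raise ValueError(f"molecule label {label!r} not present in frame")
        return idx


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """(len(a), len(b)) distance matrix, minimum-image when box is given."""
    disp = a[:, None, :] - b[None, :, :]
    if box is not None:
        disp -= box * np.round(disp / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", disp, disp))


def min_interbead_distance(frame: BeadFrame, label_a: str, label_b: str) -> float:
    """Minimum distance (nm) over all cross-molecule bead pairs."""
    ia, ib = frame.indices_of(label_a), frame.indices_of(label_b)
    return float(_pair_distances(frame.coords[ia], frame.coords[ib], frame.box).min())


@dataclass
class OccurrenceMap:
    """Cross-molecule bead-pair contact counts summed over an ensemble."""

    counts: np.ndarray  # (n_beads_a, n_beads_b)
    label_a: str
    label_b: str
    cutoff: float
    n_replicates: int
    n_frames_total: int
    residue_labels_a: list | None = None
    residue_labels_b: list | None = None

    def residue_rollup(self) -> dict[tuple, int]:
        """Contact counts aggregated to (residue_a, residue_b) pairs."""
        if self.residue_labels_a is None or self.residue_labels_b is None:
            raise ValueError("no residue labels available for roll-up")
        rollup: dict[tuple, int] = {}
        for i, ra in enumerate(self.residue_labels_a):
            for j, rb in enumerate(self.residue_labels_b):
                c = int(self.counts[i, j])
                if c:
                    key = (ra, rb)
                    rollup[key] = rollup.get(key, 0) + c
        return rollup

    def transpose(self) -> "OccurrenceMap":
        return OccurrenceMap(
            counts=self.counts.T.copy(),
            label_a=self.label_b,
            label_b=self.label_a,
            cutoff=self.cutoff,
            n_replicates=self.n_replicates,
            n_frames_total=self.n_frames_total,
            residue_labels_a=self.residue_labels_b,
            residue_labels_b=self.residue_labels_a,
        )


def contact_occurrence_map(
    replicate_trajectories: Sequence[Sequence[BeadFrame]],
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    label_a: str = "A",
    label_b: str = "B",
) -> OccurrenceMap:
    """Bead-pair contact counts across a replicate ensemble.

    Every frame of every replicate contributes: each cross-molecule bead
    pair with distance ≤ cutoff increments its count.  Counts are
    additive over replicate subsets.
    """
    if len(replicate_trajectories) == 0:
        raise ValueError("need at least one replicate")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    first = replicate_trajectories[0][0]
    ia, ib = first.indices_of(label_a), first.indices_of(label_b)
    ref_labels = list(first.mol_labels)
    counts = np.zeros((ia.size, ib.size), dtype=int)
    n_frames = 0
    for r, replicate in enumerate(replicate_trajectories):
        for frame in replicate:
            if list(frame.mol_labels) != ref_labels:
                raise ValueError(f"replicate {r}: inconsistent bead labelling")
            d = _pair_distances(frame.coords[ia], frame.coords[ib], frame.box)
            counts += d <= cutoff
            n_frames += 1
    res_a = res_b = None
    if first.residue_labels is not None:
        res_a = [first.residue_labels[i] for i in ia]
        res_b = [first.residue_labels[i] for i in ib]
    return OccurrenceMap(
        counts=counts,
        label_a=label_a,
        label_b=label_b,
        cutoff=cutoff,
        n_replicates=len(replicate_trajectories),
        n_frames_total=n_frames,
        residue_labels_a=res_a,
        residue_labels_b=res_b,
    )


def excipient_residence(
    replicate_trajectories: Sequence[Sequence[BeadFrame]],
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    protein_labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Per-residue occupancy of excipient centres of mass near the protein.

    For every frame and excipient molecule the excipient COM is computed;
    every protein residue with at least one bead within ``cutoff`` of that
    COM is incremented.  The result maps residue label → occupancy
    fraction over all frames × replicates × excipients.
    """
    if len(replicate_trajectories) == 0:
        raise ValueError("need at least one replicate")
    first = replicate_trajectories[0][0]
    protein_idx = np.concatenate([first.indices_of(l) for l in protein_labels])
    if first.residue_labels is None:
        raise ValueError("protein beads need residue labels for residence analysis")
    exc_labels = sorted(
        {m for m in first.mol_labels if m not in protein_labels}
    )
    if not exc_labels:
        raise ValueError("no excipient molecules present")
    residues = sorted({first.residue_labels[i] for i in protein_idx}, key=str)
    hits = {r: 0 for r in residues}
    n_events = 0
    for replicate in replicate_trajectories:
        for frame in replicate:
            pcoords = frame.coords[protein_idx]
            for label in exc_labels:
                idx = frame.indices_of(label)
                m = frame.masses[idx]
                com = (frame.coords[idx] * m[:, None]).sum(axis=0) / m.sum()
                d = _pair_distances(pcoords, com[None, :], frame.box)[:, 0]
                near = {
                    frame.residue_labels[protein_idx[k]]
                    for k in np.flatnonzero(d <= cutoff)
                }
                for r in near:
                    hits[r] += 1
                n_events += 1
    return {r: hits[r] / n_events for r in residues}


@dataclass(frozen=True)
class NonbondedTable:
    """Symmetric (typeA, typeB) → LJ (ε kJ/mol, σ nm) with Coulomb settings."""

    pairs: dict
    relative_dielectric: float = MARTINI_RELATIVE_DIELECTRIC
    cutoff: float = DEFAULT_NONBONDED_CUTOFF_NM

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.relative_dielectric <= 0:
            raise ValueError("cutoff and relative dielectric must be positive")
        canonical = {}
        for (a, b), (eps, sigma) in self.pairs.items():
            if eps < 0 or sigma <= 0:
                raise ValueError(f"invalid LJ parameters for pair ({a}, {b})")
            canonical[tuple(sorted((a, b)))] = (float(eps), float(sigma))
        object.__setattr__(self, "pairs", canonical)

    def lookup(self, type_a: str, type_b: str) -> tuple[float, float]:
        key = tuple(sorted((type_a, type_b)))
        if key not in self.pairs:
            raise KeyError(f"no nonbonded parameters for type pair {key}")
        return self.pairs[key]

    @classmethod
    def from_file(cls, path, relative_dielectric=MARTINI_RELATIVE_DIELECTRIC,
                  cutoff=DEFAULT_NONBONDED_CUTOFF_NM) -> "NonbondedTable":
        """Read whitespace-separated rows: typeA typeB epsilon sigma."""
        pairs = {}
        with open(path) as handle:
            for raw in handle:
                line = raw.split("#")[0].strip()
                if not line:
                    continue
                a, b, eps, sigma = line.split()[:4]
                pairs[(a, b)] = (float(eps), float(sigma))
        return cls(pairs=pairs, relative_dielectric=relative_dielectric, cutoff=cutoff)


def _lj(r, eps, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def pair_interaction_energy(
    frame: BeadFrame,
    table: NonbondedTable,
    label_a: str = "A",
    label_b: str = "B",
) -> float:
    """Inter-molecular nonbonded energy (kJ/mol), potential-shifted.

    Sums 12-6 Lennard-Jones and screened Coulomb terms over cross-label
    pairs with r ≤ cutoff; each term is shifted by its value at the
    cutoff, so pairs beyond the cutoff contribute exactly zero.
    """
    ia, ib = frame.indices_of(label_a), frame.indices_of(label_b)
    d = _pair_distances(frame.coords[ia], frame.coords[ib], frame.box)
    rc = table.cutoff
    energy = 0.0
    qa, qb = frame.charges[ia], frame.charges[ib]
    for ai in range(ia.size):
        for bi in range(ib.size):
            r = d[ai, bi]
            if r > rc:
                continue
            eps, sigma = table.lookup(frame.types[ia[ai]], frame.types[ib[bi]])
            energy += _lj(r, eps, sigma) - _lj(rc, eps, sigma)
            qq = qa[ai] * qb[bi]
            if qq != 0.0:
                k = COULOMB_CONSTANT / table.relative_dielectric
                energy += k * qq * (1.0 / r - 1.0 / rc)
    return float(energy)


@dataclass
class EnergySeries:
    """Per-replicate interaction-energy time series on a shared grid."""

    times: np.ndarray  # ns, shape (n_points,)
    energies: np.ndarray  # kJ/mol, shape (n_replicates, n_points)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.atleast_2d(np.asarray(self.energies, dtype=float))
        if self.energies.shape[1] != self.times.size:
            raise ValueError("all replicates must share the time grid")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")

    @property
    def mean_curve(self) -> np.ndarray:
        return self.energies.mean(axis=0)


@dataclass
class PlateauResult:
    """Plateau interaction energy with the cross-check estimator."""

    plateau: float  # primary: final-quartile mean of the ensemble mean
    tail_mean: float
    exponential_e_inf: float | None
    exponential_tau_ns: float | None
    estimators_agree: bool


def ensemble_plateau(
    series: EnergySeries, tail_fraction: float = 0.25
) -> PlateauResult:
    """Plateau of the across-replicate mean energy curve.

    The primary estimator is the mean of the ensemble-mean curve over the
    final ``tail_fraction`` of time points.  An exponential-approach fit
    E(t) = E∞(1 − e^(−t/τ)) is computed as a cross-check; when the two
    differ by more than 5 % both are reported and a warning is issued.
    """
    n = series.times.size
    if n < 8:
        raise ValueError("need at least 8 time points for a plateau estimate")
    if series.energies.shape[0] < 1:
        raise ValueError("need at least one replicate")
    mean_curve = series.mean_curve
    n_tail = max(1, int(np.ceil(tail_fraction * n)))
    tail_mean = float(mean_curve[-n_tail:].mean())

    e_inf = tau = None
    agree = True
    try:
        t = series.times - series.times[0]
        scale = max(abs(tail_mean), 1e-12)
        popt, _ = curve_fit(
            lambda tt, e, ta: e * (1.0 - np.exp(-tt / ta)),
            t,
            mean_curve,
            p0=(tail_mean if tail_mean != 0 else -scale, max(t[-1] / 4.0, 1e-6)),
            maxfev=10000,
        )
        e_inf, tau = float(popt[0]), float(popt[1])
        if abs(e_inf - tail_mean) > 0.05 * max(abs(tail_mean), 1e-12):
            agree = False
            warnings.warn(
                f"plateau estimators disagree by >5%: tail mean {tail_mean:.4g}, "
                f"exponential fit {e_inf:.4g}"
            )
    except RuntimeError:
        e_inf = tau = None
    return PlateauResult(
        plateau=tail_mean,
        tail_mean=tail_mean,
        exponential_e_inf=e_inf,
        exponential_tau_ns=tau,
        estimators_agree=agree,
    )
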