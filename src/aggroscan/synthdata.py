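"""Deterministic, seeded synthetic fixtures.

Every generator is a pure function of its arguments (same seed ⇒
bit-identical output) and emulates one study condition used elsewhere in
the package:

* toy peptides with known geometry and exposure (SASA/SAP tests);
* DAFT-style two-body starting configurations — two copies of a molecule
  under independent uniform random rotations with centres of mass at an
  exact separation (default 3 nm, 1024 orientations);
* Boltzmann ensembles of a harmonic coordinate (bonded-parameter
  recovery);
* dimerisation trajectories with planted contacts and known ground-truth
  occurrence counts;
* noiseless/noisy linear D(c) series for kD fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from aggroscan import peptides
from aggroscan.cgparam import KB_KJ_PER_MOL_K
from aggroscan.dimeranalysis import BeadFrame
from aggroscan.dlskd import DlsSeries
from aggroscan.structio import Structure

__all__ = [
    "FixtureSpec",
    "make_toy_peptide",
    "random_rotation_matrix",
    "make_daft_pairs",
    "sample_harmonic_ensemble",
    "make_contact_trajectory",
    "make_dls_series",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Seed plus size/noise parameters identifying one synthetic fixture."""

    seed: int
    params: tuple = ()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_toy_peptide(sequence, conformation: str = "extended") -> Structure:
    """Idealised peptide structure (see :func:`aggroscan.peptides.build_peptide`)."""
    return peptides.build_peptide(sequence, conformation)


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a normalised 4-D Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_daft_pairs(
    molecule_coords_nm: np.ndarray,
    n_orientations: int = 1024,
    separation: float = 3.0,
    seed: int = 0,
    types: list[str] | None = None,
    charges: np.ndarray | None = None,
    masses: np.ndarray | None = None,
    residue_labels: list | None = None,
) -> list[BeadFrame]:
    """Two-rigid-body starting configurations at a fixed COM separation.

    Each configuration holds two copies of the molecule, each under an
    independent uniform random rotation, with centres of mass exactly
    ``separation`` nm apart along x.  Defaults follow the replicate-
    ensemble protocol: 3 nm separation, 1024 orientations.
    """
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    if separation <= 0:
        raise ValueError("separation must be positive")
    coords = np.asarray(molecule_coords_nm, dtype=float)
    n = coords.shape[0]
    if masses is None:
        masses = np.ones(n)
    masses = np.asarray(masses, dtype=float)
    types = types or ["P1"] * n
    charges = np.zeros(n) if charges is None else np.asarray(charges, dtype=float)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    centred = coords - com

    rng = np.random.default_rng(seed)
    frames: list[BeadFrame] = []
    offset = np.array([separation, 0.0, 0.0])
    for _ in range(n_orientations):
        ra = random_rotation_matrix(rng)
        rb = random_rotation_matrix(rng)
        a = centred @ ra.T
        b = centred @ rb.T
        # re-centre so each copy's COM is exact despite rounding
        a -= (a * masses[:, None]).sum(axis=0) / masses.sum()
        b -= (b * masses[:, None]).sum(axis=0) / masses.sum()
        frames.append(
            BeadFrame(
                coords=np.vstack([a, b + offset]),
                types=types * 2,
                mol_labels=["A"] * n + ["B"] * n,
                charges=np.concatenate([charges, charges]),
                masses=np.concatenate([masses, masses]),
                residue_labels=(
                    None
                    if residue_labels is None
                    else [("A", r) for r in residue_labels]
                    + [("B", r) for r in residue_labels]
                ),
            )
        )
    return frames


def sample_harmonic_ensemble(
    k: float,
    temperature_K: float = 300.0,
    n: int = 100_000,
    seed: int = 0,
    mean: float = 0.0,
) -> np.ndarray:
    """I.i.d. draws from the Boltzmann distribution of a harmonic coordinate.

    For potential U(x) = ½k(x−mean)² at temperature T the equilibrium
    distribution is Gaussian with σ = √(k_B·T/k); units follow k (nm for
    kJ mol⁻¹ nm⁻², degrees require converting k accordingly).
    """
    if k <= 0 or temperature_K <= 0 or n < 1:
        raise ValueError("k > 0, T > 0 and n >= 1 required")
    sigma = np.sqrt(KB_KJ_PER_MOL_K * temperature_K / k)
    return np.random.default_rng(seed).normal(mean, sigma, size=n)


def make_contact_trajectory(
    planted_contacts: list[tuple[int, int, tuple[int, int] | None]],
    n_frames: int,
    n_replicates: int = 1,
    seed: int = 0,
    n_beads_a: int = 5,
    n_beads_b: int = 5,
) -> tuple[list[list[BeadFrame]], np.ndarray]:
    """Dimerisation replicates with planted contacts and known truth.

    ``planted_contacts`` lists (bead_i_of_A, bead_j_of_B, frame_span)
    with ``frame_span = (start, stop)`` (stop exclusive) or ``None`` for
    all frames.  In an active frame, molecule B (a rigid 2 nm-spaced
    linear cloud) is translated so bead j sits 0.45 nm from bead i of A;
    every other cross pair stays beyond 1 nm.  Returns the replicate
    list and the ground-truth (n_beads_a, n_beads_b) occurrence counts.
    Overlapping spans for different pairs are geometrically infeasible
    and raise an error.
    """
    contacts = []
    for (i, j, span) in planted_contacts:
        if not (0 <= i < n_beads_a and 0 <= j < n_beads_b):
            raise ValueError(f"planted contact ({i}, {j}) references invalid beads")
        start, stop = span if span is not None else (0, n_frames)
        if not 0 <= start < stop <= n_frames:
            raise ValueError(f"invalid frame span {span}")
        contacts.append((i, j, start, stop))
    # at most one planted pair may be active per frame
    active_per_frame: dict[int, tuple[int, int]] = {}
    for (i, j, start, stop) in contacts:
        for f in range(start, stop):
            if f in active_per_frame and active_per_frame[f] != (i, j):
                raise ValueError(
                    f"frame {f}: contacts {active_per_frame[f]} and {(i, j)} "
                    "cannot both be planted (infeasible geometry)"
                )
            active_per_frame[f] = (i, j)

    a_coords = np.column_stack(
        [2.0 * np.arange(n_beads_a), np.zeros(n_beads_a), np.zeros(n_beads_a)]
    )
    b_template = np.column_stack(
        [np.zeros(n_beads_b), 2.0 * np.arange(n_beads_b), np.zeros(n_beads_b)]
    )
    rng = np.random.default_rng(seed)
    truth = np.zeros((n_beads_a, n_beads_b), dtype=int)
    types = ["P1"] * (n_beads_a + n_beads_b)
    mol_labels = ["A"] * n_beads_a + ["B"] * n_beads_b
    residue_labels = [f"A{i + 1}" for i in range(n_beads_a)] + [
        f"B{j + 1}" for j in range(n_beads_b)
    ]
    replicates: list[list[BeadFrame]] = []
    for _ in range(n_replicates):
        frames: list[BeadFrame] = []
        for f in range(n_frames):
            jitter = rng.uniform(-0.02, 0.02, size=3)
            if f in active_per_frame:
                i, j = active_per_frame[f]
                anchor = a_coords[i] + np.array([0.0, 0.45, 0.0]) + jitter
                b = b_template - b_template[j] + anchor
                truth[i, j] += 1
            else:
                b = b_template + np.array([0.0, 10.0, 0.0]) + jitter
            frames.append(
                BeadFrame(
                    coords=np.vstack([a_coords, b]),
                    types=list(types),
                    mol_labels=list(mol_labels),
                    residue_labels=list(residue_labels),
                )
            )
        replicates.append(frames)
    return replicates, truth


def make_dls_series(
    d0: float,
    kd: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DlsSeries:
    """Linear D(c) = D0(1 + kD·c) series with optional Gaussian noise.

    ``concentrations`` are mg/mL and ``kd`` is mL/g, so c enters the
    linear law in g/mL.
    """
    if d0 <= 0:
        raise ValueError("D0 must be positive")
    c = np.asarray(concentrations, dtype=float)
    d = d0 * (1.0 + kd * c * 1e-3)
    if noise_sd > 0:
        d = d + np.random.default_rng(seed).normal(0.0, noise_sd, size=c.shape)
    return DlsSeries(concentrations=c, diffusion_coefficients=d)
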