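# Methods

This note documents the models and numerical choices behind each
module, the parameters that matter, what the synthetic generators do
and do not emulate, and the known limitations.

## Units and data model

Internal canonical units are Å for atomistic coordinates, Da for
masses, kJ/mol for energies and ns for time. GRO files (nm) are
converted on I/O; the coarse-grained world (`cgparam`,
`dimeranalysis`) works in nm throughout, matching the force-field
convention. Van der Waals radii come from an embedded Bondi-style
element table (C 1.70, N 1.55, O 1.52, S 1.80 Å, …); unknown elements
fall back to 1.70 Å with a warning. On PDB read, only altloc blank or
'A' is kept, and duplicate (chain, resseq, icode, name) identities
after altloc resolution are rejected rather than silently merged.

## Solvent-accessible surface area

`sasa.shrake_rupley` places a golden-spiral point set (default 960
points — deterministic, no RNG) on each atom's solvent-expanded sphere
(r + probe, probe default 1.4 Å for water) and counts points lying
outside every neighbouring expanded sphere. The burial test treats the
boundary as buried with a 1e-10 relative slack, which makes a
co-located identical twin occlude its partner completely instead of
leaving a roundoff-dependent half-surface. Accuracy is validated three
independent ways in the tests: the analytic isolated sphere (≤1 %),
the two-sphere spherical-cap closed form (≤2 %), and a randomised
Monte-Carlo surface integrator plus biotite's implementation on random
clusters (≤2 % of the expanded-sphere area). Doubling the quadrature
changes areas by well under 1 %.

The algorithm is O(n²) in atoms per frame with vectorised inner loops;
this is ample for the Fv-fragment-scale structures (≈10³ heavy atoms)
and test fixtures the package targets. A cell-list neighbour search
would be the first optimisation if whole-mAb trajectories were needed.

## Spatial aggregation propensity

The per-atom score at radius R sums, over residues having ≥1 atom
within R of the central atom, the exposed side-chain fraction times
residue hydrophobicity. Choices the score definition leaves open, and
how this implementation fixes them:

- **Hydrophobicity scale**: Black & Mould values in their published
  0–1 normalisation, shifted by glycine's value (0.501) so glycine is
  exactly 0. Hydrophilic residues (Arg, Asp, Glu…) become negative,
  which is what makes negative SAP patches meaningful.
- **Fully-exposed reference**: side-chain SAA of residue X computed
  once, with the same engine and quadrature, on an embedded extended
  Gly-X-Gly tripeptide (idealised geometry, φ=ψ effectively extended)
  and cached per (residue, probe, n_points). Glycine's side chain is
  empty under the backbone = {N, CA, C, O, OXT + their hydrogens}
  convention, so its reference is 0 and it contributes nothing —
  consistent with its zero hydrophobicity.
- **Membership test**: a side-chain atom counts toward the numerator
  iff its centre lies within R of the central atom (centre-distance
  criterion).
- **Exposed fractions are not clipped**: a conformer more exposed than
  the reference can push a fraction above 1; this is logged, not
  truncated.
- **Hydrogens** are excluded by default (`include_hydrogens=True`
  restores them); the residue average is over all residue atoms by
  default with a `sidechain` switch.
- **Defaults**: R = 10 Å, hotspot threshold 0.15, trajectory stride 1.
  Trajectory scores are the arithmetic mean of per-frame scores; a
  single-frame trajectory is bitwise identical to the frame
  computation.

## Coarse-grained parametrisation

Bead coordinates are mass-weighted centres of mass of their member
atoms (geometric centres would ignore the heavy-atom asymmetry of
mapped groups); whole-molecule mass and COM are conserved exactly.
Atom-name-based mapping presumes a single small molecule with unique
atom names and refuses duplicates.

Equilibrium bonded values are taken from the most prominent histogram
peak (Freedman–Diaconis bin width with a floor of 30 bins; ties break
toward the smaller value, logged), refined to the mean of the samples
in the winning bin. Force constants come from Boltzmann inversion of
the mode width, k = k_B·T/σ², the standard bottom-up identity for a
harmonic coordinate in equilibrium. σ is estimated robustly: an
initial width from the MAD about the peak confines the sample to the
prominent mode's basin, one re-estimation pass at ±3σ follows, and the
retained variance is divided by 0.9733 (the variance fraction a normal
distribution keeps inside ±3σ) so the truncation does not bias k
upward. Angles and dihedrals are converted to radians before
inversion. Recovery on seeded Boltzmann ensembles is within 5 % (in
practice <1 %) for k ∈ {100, 500, 1250, 5000} kJ mol⁻¹ nm⁻² at
n = 10⁵, and the taller mode of a 0.7/0.3 bimodal mixture wins in
100/100 seeded trials.

The elastic network adds one harmonic bond per backbone-bead pair
within the cutoff (defaults 0.9 nm and 500 kJ mol⁻¹ nm⁻²), equilibrium
at the observed distance, excluding pairs already covered by bonded
terms. Ring edges may be emitted as constraints instead of stiff
bonds; stiff bonds are the default. The `.itp` emitter writes
[moleculetype], [atoms], [bonds] (including elastic bonds, tagged),
[constraints], [angles], [dihedrals] in that order, validates index
ranges and duplicate terms, and refuses topologies with unset
equilibria. Choosing MARTINI chemical bead types is expert judgement
and out of scope.

## Dimer-ensemble analysis

All analyses treat replicates as exchangeable and unweighted.
Minimum-image distances are used whenever an orthorhombic box is
attached to a frame; otherwise free space.

- **Contacts**: every cross-molecule bead pair with distance ≤ cutoff
  increments its count, per frame, per replicate. The cutoff default
  is 0.6 nm — a conventional CG bead-contact distance, since the
  analysis protocol itself does not pin one — and is echoed into all
  output metadata. Counts are additive over replicate subsets and
  transpose exactly under label swap. A residue-level roll-up
  preserves totals.
- **Excipient residence** tracks each excipient molecule by its
  centre of mass per frame; every protein residue with a bead within
  the cutoff of that COM is credited, and occupancies are fractions of
  frames × replicates × excipients.
- **Pair energy** is the MARTINI-style sum of 12-6 Lennard-Jones and
  screened Coulomb terms (relative dielectric 15, the standard MARTINI
  water screening) over cross-molecule pairs within the 1.8 nm cutoff,
  each term potential-shifted to zero at the cutoff, so the energy is
  exactly 0 for separated molecules. Bonded and intra-molecular terms
  are deliberately excluded — the quantity of interest is
  inter-molecular binding.
- **Plateau**: the primary estimator is the mean of the
  across-replicate mean-energy curve over the final 25 % of time
  points — robust and assumption-light. An exponential-approach fit
  E(t) = E∞(1 − e^(−t/τ)) is always attempted as a cross-check; when
  the two disagree by more than 5 % both are reported and a warning is
  issued. On the synthetic model (E∞ = −300 kJ/mol, τ = 50 ns, 512 ns
  grid, 64 noisy replicates) the tail mean recovers E∞ within 2 %, and
  its error shrinks as replicates grow.

## kD fitting

D(c) = D0(1 + kD·c) is fitted by unweighted ordinary least squares of
D on c. Concentrations are accepted in mg/mL (the instrument
convention) and converted to g/mL inside the fit so that the slope is
kD·D0 in cm²·mL·s⁻¹·g⁻¹ and kD = slope/intercept lands directly in
mL/g — this is the convention under which a slope of −4.05×10⁻⁶ with
D0 = 4.48×10⁻⁷ cm²/s gives kD ≈ −9.0 mL/g. Replicate spread, when
provided, informs the reported standard errors but does not reweight
the fit. A warning fires when the concentration range extends well
outside the 1–10 mg/mL regime where the linearisation is trusted.
Noiseless generated data are recovered to 1e-10 relative; scaling all
D by a constant scales D0 and leaves kD unchanged.

## Synthetic data

Generators are pure functions of (seed, parameters):

- **Toy peptides** use an idealised extended backbone (3.8 Å Cα
  spacing) with heavy side-chain pseudo-atoms in a solvent-pointing
  zig-zag — correct names, masses and radii, but not a rotamer
  library. They exist to give SASA/SAP known exposure; they say
  nothing about real conformational ensembles. The "compact" form is
  an isotropic contraction (factor 0.65) used to test burial
  monotonicity.
- **DAFT-style pairs** place two copies of a molecule under
  independent uniform random rotations (normalised 4-D Gaussian
  quaternions, provably uniform on the rotation group) with COMs
  exactly at the requested separation (re-centred after rotation, so
  exact to ~1e-15). Defaults: 3 nm, 1024 orientations.
- **Harmonic ensembles** draw i.i.d. from the Gaussian of width
  √(k_B·T/k) — the exact Boltzmann distribution, with none of the
  autocorrelation a real trajectory would carry, so recovery tests
  probe the estimator, not sampling convergence.
- **Planted-contact trajectories** hold one designated cross-molecule
  bead pair at 0.45 nm for designated frame spans while every other
  cross pair stays beyond 1 nm; ground-truth counts are emitted with
  the frames. At most one pair may be planted per frame — two
  simultaneous contacts at distinct sites are geometrically infeasible
  for rigid translation and are refused.
- **D(c) series** evaluate the linear law exactly, with optional
  Gaussian noise.

Passing tests on these fixtures demonstrates correctness of the
estimators and bookkeeping, not force-field realism: no solvent, no
excipient chemistry, no protein flexibility.

## Problem sizes

The test suite and the acceptance script run the statistical checks at
n = 10⁵ samples per harmonic ensemble, 20 random clusters for the
Monte-Carlo SASA oracle, 50 random frames for the energy oracle,
64 replicates × 128 time points for plateau recovery and
1024 DAFT orientations — sizes at which the quoted tolerances are
comfortably resolved while the whole suite completes in seconds.

## Known limitations

- No binary trajectory formats (XTC/DCD) and no mmCIF; the Trajectory
  contract would admit them.
- SASA is quadrature-based, not analytic; 960 points resolve ~0.1 Å²
  features at protein-atom radii.
- The SAP reference conformer is a fixed idealised Gly-X-Gly; other
  reference conventions would rescale exposed fractions slightly.
- Docking/virtual screening, running MD/CGMD engines, and instrument
  acquisition are out of scope: the package consumes structures,
  frame sequences and tabulated D(c) values.
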