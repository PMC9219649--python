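# aggroscan

A toolkit for the computational side of excipient discovery against
antibody self-association. Therapeutic antibodies with hydrophobic
CDR loops tend to self-associate; aggregation raises viscosity and
immunogenicity risk but the offending residues often cannot be mutated
away because they bind the antigen. One mitigation strategy is to find
a small-molecule excipient that parks on the aggregation-prone patch
and acts as an interaction breaker. `aggroscan` implements the four
analysis stages such a campaign needs:

1. **Aggregation-prone patch detection** — per-atom Spatial
   Aggregation Propensity (SAP) at radius *R*:

   `SAP_i = ⟨ Σ_res [SAA(side-chain atoms of res within R of atom i) /
   SAA(side chain of res fully exposed)] · H(res) ⟩_frames`

   where SAA is the Shrake–Rupley solvent-accessible area, the sum
   runs over residues with at least one atom within *R* of atom *i*,
   and H is the Black & Mould hydrophobicity scale shifted so
   glycine = 0. Residues averaging above a threshold (default 0.15 at
   R = 10 Å) are reported as hotspots.
2. **Bottom-up coarse-grained parametrisation** of a candidate
   excipient: map an atomistic trajectory onto MARTINI-style beads
   (mass-weighted COM), take the most prominent histogram peak of each
   bond/angle/dihedral as its equilibrium value, Boltzmann-invert the
   peak width into a force constant (k = k_B·T/σ²), add an
   ElNeDyn-style elastic network (0.9 nm cutoff,
   500 kJ mol⁻¹ nm⁻²), and emit a GROMACS `.itp`.
3. **Replicate-ensemble dimer analysis** for DAFT-style simulation
   sets (two fragments at a 3 nm COM separation, 1024 random mutual
   orientations): cross-molecule bead-contact occurrence maps,
   excipient residence per residue, shifted LJ+Coulomb inter-molecular
   energies (1.8 nm cutoff, MARTINI dielectric 15) and the plateau of
   the ensemble-mean energy.
4. **kD fitting** from dynamic-light-scattering concentration series:
   `D(c) = D0(1 + kD·c)`; negative kD means net attractive
   protein–protein interactions.

Every stage has a deterministic synthetic-fixture generator
(`aggroscan.synthdata`) so the full pipeline can be exercised without
simulation engines or instrument data.

## Worked example

Score a toy peptide, extract hotspots, and fit kD from a synthetic
DLS series:

```python
import numpy as np
from aggroscan import sap, synthdata, dlskd

pep = synthdata.make_toy_peptide("GALWG", "extended")
profile = sap.frame_sap(pep, radius=10.0)
for chain, resseq, name, score in sap.extract_hotspots(profile, 0.15):
    print(f"{chain} {resseq:3d} {name}  SAP={score:.3f}")

series = synthdata.make_dls_series(4.48e-7, -9.03, np.arange(1.0, 11.0))
fit = dlskd.fit_kd(series)
print(f"D0={fit.d0:.3g} cm2/s  kD={fit.kd:.2f} mL/g")
```

prints

```
A   4 TRP  SAP=0.602
A   3 LEU  SAP=0.588
A   2 ALA  SAP=0.471
A   5 GLY  SAP=0.408
A   1 GLY  SAP=0.346
```

— the tryptophan and leucine side chains dominate the exposed
hydrophobic surface (the flanking glycines score positive only because
they sit within 10 Å of those side chains) — and

```
D0=4.48e-07 cm2/s  kD=-9.03 mL/g
```

recovering the generator's parameters exactly from the noiseless
line. The same operations are available from the shell:

```sh
aggroscan sap --pdb fv.pdb --radius 10 --threshold 0.15 --out sap.tsv
aggroscan kd  --tsv dls.tsv --out kd.json
aggroscan --help   # sasa, cgmap, cgparam, itp, contacts, residence, ...
```

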