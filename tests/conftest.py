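import numpy as np
import pytest

from aggroscan.structio import Atom, Structure


def make_atom(serial, coords, name="C", element="C", resname="UNK", resseq=1,
              chain="A", radius=1.7, mass=12.011):
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_seq=resseq, chain_id=chain, coords=np.asarray(coords, dtype=float),
        mass=mass, vdw_radius=radius,
    )


@pytest.fixture
def single_carbon():
    return Structure([make_atom(1, [0.0, 0.0, 0.0])])


def random_cluster(rng, n_atoms, spread=4.0, radius_range=(1.2, 1.9)):
    """A random atom cluster with mixed radii for SASA oracle tests."""
    atoms = []
    for i in range(n_atoms):
        atoms.append(
            make_atom(
                i + 1,
                rng.uniform(-spread, spread, 3),
                name=f"C{i}",
                resseq=i + 1,
                radius=rng.uniform(*radius_range),
            )
        )
    return Structure(atoms)
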