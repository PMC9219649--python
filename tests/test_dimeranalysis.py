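import numpy as np
import pytest

from aggroscan import dimeranalysis, synthdata
from aggroscan.dimeranalysis import (
    BeadFrame,
    EnergySeries,
    NonbondedTable,
    contact_occurrence_map,
    ensemble_plateau,
    excipient_residence,
    min_interbead_distance,
    pair_interaction_energy,
)


def random_dimer_frame(rng, n_a=20, n_b=20, box=None, charged=False, spread=3.0):
    # resample until no unphysical overlap (< 0.3 nm) so LJ stays in a
    # range where float64 absolute comparisons at 1e-9 are meaningful
    while True:
        coords = np.vstack(
            [rng.uniform(0, spread, (n_a, 3)), rng.uniform(0, spread, (n_b, 3))]
        )
        d = np.linalg.norm(coords[:n_a, None, :] - coords[None, n_a:, :], axis=-1)
        if d.min() >= 0.3:
            break
    charges = rng.choice([-1.0, 0.0, 1.0], n_a + n_b) if charged else None
    return BeadFrame(
        coords=coords,
        types=["P1"] * n_a + ["SC3"] * n_b,
        mol_labels=["A"] * n_a + ["B"] * n_b,
        charges=charges,
        residue_labels=[f"A{i}" for i in range(n_a)] + [f"B{j}" for j in range(n_b)],
        box=box,
    )


TABLE = NonbondedTable(
    pairs={
        ("P1", "P1"): (4.5, 0.47),
        ("P1", "SC3"): (3.5, 0.43),
        ("SC3", "SC3"): (2.5, 0.43),
    }
)


class TestMinInterbeadDistance:
    def test_daft_single_bead_pair_is_exact_separation(self):
        frames = synthdata.make_daft_pairs(np.zeros((1, 3)), n_orientations=4, seed=0)
        for frame in frames:
            assert min_interbead_distance(frame, "A", "B") == pytest.approx(3.0, abs=1e-12)

    def test_colocated_beads_zero(self):
        frame = BeadFrame(
            coords=np.zeros((2, 3)), types=["P1"] * 2, mol_labels=["A", "B"]
        )
        assert min_interbead_distance(frame, "A", "B") == 0.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(21)
        frame = random_dimer_frame(rng, 50, 50)
        expected = min(
            np.linalg.norm(frame.coords[i] - frame.coords[j])
            for i in range(50)
            for j in range(50, 100)
        )
        assert min_interbead_distance(frame, "A", "B") == pytest.approx(expected, abs=1e-12)

    def test_minimum_image_with_box(self):
        frame = BeadFrame(
            coords=np.array([[0.1, 0.0, 0.0], [9.9, 0.0, 0.0]]),
            types=["P1"] * 2,
            mol_labels=["A", "B"],
            box=np.array([10.0, 10.0, 10.0]),
        )
        assert min_interbead_distance(frame, "A", "B") == pytest.approx(0.2, abs=1e-12)

    def test_missing_label_rejected(self):
        frame = BeadFrame(coords=np.zeros((1, 3)), types=["P1"], mol_labels=["A"])
        with pytest.raises(ValueError, match="'B'"):
            min_interbead_distance(frame, "A", "B")


class TestContactOccurrenceMap:
    def test_no_contacts_all_zero(self):
        replicates, _ = synthdata.make_contact_trajectory([], n_frames=5, n_replicates=2)
        occ = contact_occurrence_map(replicates, cutoff=0.6)
        assert occ.counts.sum() == 0

    def test_persistent_pair_counts_every_frame(self):
        replicates, truth = synthdata.make_contact_trajectory(
            [(1, 2, None)], n_frames=7, n_replicates=1
        )
        occ = contact_occurrence_map(replicates, cutoff=0.6)
        assert occ.counts[1, 2] == 7
        assert occ.counts.sum() == 7
        np.testing.assert_array_equal(occ.counts, truth)

    def test_matches_brute_force_recount(self):
        replicates, _ = synthdata.make_contact_trajectory(
            [(0, 0, (0, 4)), (3, 4, (4, 9))], n_frames=9, n_replicates=3, seed=5
        )
        occ = contact_occurrence_map(replicates, cutoff=0.6)
        recount = np.zeros_like(occ.counts)
        for frames in replicates:
            for frame in frames:
                a = frame.coords[:5]
                b = frame.coords[5:]
                for i in range(5):
                    for j in range(5):
                        if np.linalg.norm(a[i] - b[j]) <= 0.6:
                            recount[i, j] += 1
        np.testing.assert_array_equal(occ.counts, recount)

    def test_label_swap_transposes_map(self):
        replicates, _ = synthdata.make_contact_trajectory(
            [(2, 1, (0, 5))], n_frames=8, n_replicates=2, seed=3
        )
        forward = contact_occurrence_map(replicates, 0.6, label_a="A", label_b="B")
        backward = contact_occurrence_map(replicates, 0.6, label_a="B", label_b="A")
        np.testing.assert_array_equal(forward.counts, backward.counts.T)
        assert forward.counts.sum() == backward.counts.sum()

    def test_counts_additive_over_replicate_subsets(self):
        replicates, _ = synthdata.make_contact_trajectory(
            [(1, 1, (0, 6))], n_frames=6, n_replicates=4, seed=9
        )
        whole = contact_occurrence_map(replicates, 0.6)
        first = contact_occurrence_map(replicates[:2], 0.6)
        second = contact_occurrence_map(replicates[2:], 0.6)
        np.testing.assert_array_equal(whole.counts, first.counts + second.counts)

    def test_residue_rollup_conserves_counts(self):
        replicates, _ = synthdata.make_contact_trajectory(
            [(1, 2, None)], n_frames=5, n_replicates=1
        )
        occ = contact_occurrence_map(replicates, 0.6)
        assert sum(occ.residue_rollup().values()) == occ.counts.sum()

    def test_inconsistent_labelling_rejected(self):
        replicates, _ = synthdata.make_contact_trajectory([], n_frames=2, n_replicates=2)
        replicates[1][0].mol_labels[0] = "C"
        replicates[1][0].mol_labels[5] = "A"
        with pytest.raises(ValueError, match="replicate 1"):
            contact_occurrence_map(replicates, 0.6)


class TestExcipientResidence:
    def _frame_with_excipient(self, offset):
        coords = np.array(
            [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [5.0, 0.0, 0.0], list(offset)]
        )
        return BeadFrame(
            coords=coords,
            types=["P1"] * 4,
            mol_labels=["A", "A", "B", "EXC1"],
            residue_labels=["res1", "res5", "resB", None],
        )

    def test_pinned_excipient_full_occupancy(self):
        frames = [self._frame_with_excipient([2.0, 0.4, 0.0])] * 6
        occupancy = excipient_residence([frames], cutoff=0.6)
        assert occupancy["res5"] == 1.0
        assert occupancy["res1"] == 0.0
        assert occupancy["resB"] == 0.0

    def test_distant_excipient_all_zero(self):
        frames = [self._frame_with_excipient([50.0, 50.0, 50.0])] * 4
        occupancy = excipient_residence([frames], cutoff=0.6)
        assert set(occupancy.values()) == {0.0}

    def test_diffusing_excipient_matches_brute_force(self):
        rng = np.random.default_rng(30)
        frames = [self._frame_with_excipient(rng.uniform(0, 4, 3)) for _ in range(40)]
        occupancy = excipient_residence([frames], cutoff=0.8)
        expected = {"res1": 0, "res5": 0, "resB": 0}
        for frame in frames:
            com = frame.coords[3]
            for idx, res in [(0, "res1"), (1, "res5"), (2, "resB")]:
                if np.linalg.norm(frame.coords[idx] - com) <= 0.8:
                    expected[res] += 1
        for res, count in expected.items():
            assert occupancy[res] == pytest.approx(count / 40)

    def test_excipient_com_used_not_beads(self):
        # two excipient beads straddle the residue: COM lands near it
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, -1.0, 0.0]])
        frame = BeadFrame(
            coords=coords,
            types=["P1"] * 3,
            mol_labels=["A", "EXC1", "EXC1"],
            residue_labels=["res1", None, None],
            masses=np.array([72.0, 36.0, 36.0]),
        )
        dummy_b = BeadFrame(
            coords=np.vstack([coords, [[9.0, 9.0, 9.0]]]),
            types=["P1"] * 4,
            mol_labels=["A", "EXC1", "EXC1", "B"],
            residue_labels=["res1", None, None, "resB"],
            masses=np.array([72.0, 36.0, 36.0, 72.0]),
        )
        occupancy = excipient_residence([[dummy_b]], cutoff=0.5)
        assert occupancy["res1"] == 1.0

    def test_no_excipients_rejected(self):
        frame = BeadFrame(
            coords=np.zeros((2, 3)), types=["P1"] * 2, mol_labels=["A", "B"],
            residue_labels=["r1", "r2"],
        )
        with pytest.raises(ValueError, match="excipient"):
            excipient_residence([[frame]])


def brute_force_energy(frame, table, label_a="A", label_b="B"):
    ia = [i for i, m in enumerate(frame.mol_labels) if m == label_a]
    ib = [i for i, m in enumerate(frame.mol_labels) if m == label_b]
    rc = table.cutoff
    total = 0.0
    for i in ia:
        for j in ib:
            r = np.linalg.norm(frame.coords[i] - frame.coords[j])
            if r > rc:
                continue
            eps, sigma = table.lookup(frame.types[i], frame.types[j])

            def lj(rr):
                return 4 * eps * ((sigma / rr) ** 12 - (sigma / rr) ** 6)

            total += lj(r) - lj(rc)
            qq = frame.charges[i] * frame.charges[j]
            if qq:
                k = dimeranalysis.COULOMB_CONSTANT / table.relative_dielectric
                total += k * qq * (1 / r - 1 / rc)
    return total


class TestPairInteractionEnergy:
    def test_beyond_cutoff_exactly_zero(self):
        frame = BeadFrame(
            coords=np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
            types=["P1", "P1"],
            mol_labels=["A", "B"],
            charges=np.array([1.0, -1.0]),
        )
        assert pair_interaction_energy(frame, TABLE) == 0.0

    def test_neutral_pair_at_sigma_equals_minus_lj_at_cutoff(self):
        eps, sigma = TABLE.lookup("P1", "P1")
        frame = BeadFrame(
            coords=np.array([[0.0, 0.0, 0.0], [sigma, 0.0, 0.0]]),
            types=["P1", "P1"],
            mol_labels=["A", "B"],
        )
        rc = TABLE.cutoff
        lj_rc = 4 * eps * ((sigma / rc) ** 12 - (sigma / rc) ** 6)
        # LJ(sigma) = 0, so the shifted energy is exactly -LJ(rc)
        assert pair_interaction_energy(frame, TABLE) == pytest.approx(-lj_rc, rel=1e-12)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(42)
        frame = random_dimer_frame(rng, 20, 20, charged=True)
        ours = pair_interaction_energy(frame, TABLE)
        assert ours == pytest.approx(brute_force_energy(frame, TABLE), abs=1e-9)

    def test_symmetric_in_molecule_order(self):
        rng = np.random.default_rng(43)
        frame = random_dimer_frame(rng, 15, 25, charged=True)
        forward = pair_interaction_energy(frame, TABLE, "A", "B")
        backward = pair_interaction_energy(frame, TABLE, "B", "A")
        assert forward == pytest.approx(backward, rel=1e-12)

    def test_zero_when_molecules_beyond_cutoff(self):
        rng = np.random.default_rng(44)
        frame = random_dimer_frame(rng, 10, 10)
        frame.coords[10:] += 50.0
        assert min_interbead_distance(frame, "A", "B") > TABLE.cutoff
        assert pair_interaction_energy(frame, TABLE) == 0.0

    def test_missing_type_pair_named(self):
        frame = BeadFrame(
            coords=np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
            types=["P1", "Qd"],
            mol_labels=["A", "B"],
        )
        with pytest.raises(KeyError, match="Qd"):
            pair_interaction_energy(frame, TABLE)


class TestEnsemblePlateau:
    def test_constant_ensemble_returns_constant(self):
        times = np.linspace(0, 512, 64)
        energies = np.full((10, 64), -417.2)
        result = ensemble_plateau(EnergySeries(times, energies))
        assert result.plateau == pytest.approx(-417.2)

    def test_exponential_recovery(self):
        times = np.linspace(0, 512, 128)
        rng = np.random.default_rng(77)
        energies = -300.0 * (1 - np.exp(-times / 50.0)) + rng.normal(0, 15, (64, 128))
        result = ensemble_plateau(EnergySeries(times, energies))
        assert result.plateau == pytest.approx(-300.0, rel=0.02)

    def test_all_zero_series(self):
        times = np.linspace(0, 10, 16)
        result = ensemble_plateau(EnergySeries(times, np.zeros((3, 16))))
        assert result.plateau == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="8"):
            ensemble_plateau(EnergySeries(np.arange(5.0), np.zeros((2, 5))))

    def test_estimator_consistency_with_replicates(self):
        # error shrinks as the ensemble grows
        times = np.linspace(0, 512, 96)
        signal = -300.0 * (1 - np.exp(-times / 50.0))

        def plateau_error(n_reps, seed):
            rng = np.random.default_rng(seed)
            e = signal + rng.normal(0, 30, (n_reps, 96))
            return abs(ensemble_plateau(EnergySeries(times, e)).plateau + 300.0)

        few = np.mean([plateau_error(4, s) for s in range(5)])
        many = np.mean([plateau_error(256, s) for s in range(5)])
        assert many < few


class TestNonbondedTable:
    def test_symmetric_lookup(self):
        assert TABLE.lookup("SC3", "P1") == TABLE.lookup("P1", "SC3")

    def test_from_file(self, tmp_path):
        path = tmp_path / "table.txt"
        path.write_text("# martini subset\nP1 P1 4.5 0.47\nP1 SC3 3.5 0.43\n")
        table = NonbondedTable.from_file(path)
        assert table.lookup("SC3", "P1") == (3.5, 0.43)
        assert table.cutoff == 1.8
        assert table.relative_dielectric == 15.0

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            NonbondedTable(pairs={("P1", "P1"): (4.5, -0.1)})
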