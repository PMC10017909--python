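import numpy as np
import pytest

from dhpmd.compressibility import beta_T
from dhpmd.io_formats import Condition
from dhpmd.regions import assign_secondary_structure
from dhpmd.solvation import count_solvent_near
from dhpmd.synthetic_data import (
    ShellSpec,
    generate_jitter_trajectory,
    generate_kinetics_dataset,
    generate_solvated_box,
    generate_toy_protein,
    generate_volume_series,
    generate_volume_trajectory,
    target_volume_variance,
)
from dhpmd.volumetrics import region_volume_series


class TestToyProtein:
    def test_same_seed_bit_identical(self):
        a_top, a_fr = generate_toy_protein([("helix", 6), ("loop", 5)], seed=3)
        b_top, b_fr = generate_toy_protein([("helix", 6), ("loop", 5)], seed=3)
        assert np.array_equal(a_fr.coordinates, b_fr.coordinates)
        c_top, c_fr = generate_toy_protein([("helix", 6), ("loop", 5)], seed=4)
        assert not np.array_equal(a_fr.coordinates, c_fr.coordinates)

    def test_helix_spec_recovered_by_assignment(self):
        topology, frame = generate_toy_protein([("helix", 10)], seed=0)
        partition = assign_secondary_structure(topology, frame)
        assert [(s.ss_class, s.start, s.end) for s in partition.segments] == [
            ("helix", 1, 10)
        ]

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_toy_protein([("helix", 20)], box=(10.0, 10.0, 10.0))

    def test_sequence_length_checked(self):
        with pytest.raises(ValueError, match="length"):
            generate_toy_protein([("helix", 5)], sequence="AAA")


class TestVolumeSeriesGenerator:
    def test_variance_inversion_matches_estimator(self):
        target = 1.2e-5
        var = target_volume_variance(target, 1000.0, 313.0)
        volumes = 1000.0 + np.sqrt(var) * np.array([-1.0, 1.0])
        from dhpmd.compressibility import beta_T_from_samples

        value, _, _ = beta_T_from_samples(volumes, 313.0)
        assert value == pytest.approx(target, rel=1e-3)

    def test_unachievable_fluctuation_rejected(self):
        with pytest.raises(ValueError, match="0.2"):
            generate_volume_series(1.0, mean_volume=100.0, n=10)

    def test_deterministic(self):
        a = generate_volume_series(1e-5, n=100, seed=5)
        b = generate_volume_series(1e-5, n=100, seed=5)
        assert np.array_equal(a.volumes, b.volumes)


class TestVolumeTrajectory:
    def test_zero_target_is_rigid(self, solvated_protein):
        topology, frame, partition = solvated_protein
        loop = partition.loops()[0].name
        frames = generate_volume_trajectory(
            topology, frame, partition, {loop: 0.0}, n_frames=3, seed=1
        )
        for fr in frames:
            assert np.array_equal(fr.coordinates, frame.coordinates)

    def test_recovery_of_target_beta(self, solvated_protein):
        topology, frame, partition = solvated_protein
        loop = partition.loops()[0].name
        target = 1e-5
        frames = generate_volume_trajectory(
            topology, frame, partition, {loop: target}, n_frames=150, seed=3
        )
        series = region_volume_series(
            frames, topology, partition, loop,
            condition=Condition(500.0, 0.5, 313.0),
        )
        est = beta_T(series)
        # sampling-limited: SE of a variance at n=150 is ~12 %
        assert est.beta_T == pytest.approx(target, rel=0.35)

    def test_two_regions_rank_by_construction(self):
        topology, frame = generate_toy_protein(
            [("helix", 4), ("loop", 5), ("helix", 4), ("loop", 5), ("helix", 4)],
            seed=5, margin=5.0,
        )
        stop, sfr = generate_solvated_box(
            topology, frame, n_water=int(0.02 * float(np.prod(frame.box))), seed=6
        )
        partition = assign_secondary_structure(topology, frame)
        strong, weak = [s.name for s in partition.loops()]
        targets = {strong: 1e-5, weak: 1e-6}
        frames = generate_volume_trajectory(
            stop, sfr, partition, targets, n_frames=100, seed=7
        )
        estimates = {}
        for name in targets:
            series = region_volume_series(
                frames, stop, partition, name,
                condition=Condition(1.0, 0.1, 313.0),
            )
            estimates[name] = beta_T(series).beta_T
        assert estimates[strong] > estimates[weak]


class TestSolvatedBox:
    def test_shell_spec_count_recovered_exactly(self, small_protein):
        topology, frame, partition = small_protein
        site = topology.residue_atoms(7)
        shell = ShellSpec(site_atoms=tuple(site), n_water=3, r_min=2.5,
                          r_max=4.0, exclusion=7.0)
        stop, sfr = generate_solvated_box(
            topology, frame, n_water=10, shells=[shell], seed=9
        )
        count = count_solvent_near(sfr, stop, site, cutoff=5.0)
        assert count.n_water == 3

    def test_no_ethanol_requested_none_found(self, small_protein):
        topology, frame, _ = small_protein
        stop, sfr = generate_solvated_box(topology, frame, n_water=5, seed=2)
        count = count_solvent_near(sfr, stop, [0], cutoff=100.0)
        assert count.n_ethanol == 0

    def test_deterministic_placement(self, small_protein):
        topology, frame, _ = small_protein
        a = generate_solvated_box(topology, frame, n_water=8, n_ethanol=2, seed=6)
        b = generate_solvated_box(topology, frame, n_water=8, n_ethanol=2, seed=6)
        assert np.array_equal(a[1].coordinates, b[1].coordinates)

    def test_minimum_separation_respected(self, small_protein):
        from dhpmd.solvation import minimum_image_distance

        topology, frame, _ = small_protein
        stop, sfr = generate_solvated_box(topology, frame, n_water=15, seed=3)
        solvent = np.flatnonzero(stop.molecule_class == "water")
        oxygens = solvent[stop.element[solvent] == "O"]
        d = minimum_image_distance(
            sfr.coordinates[oxygens], sfr.coordinates[oxygens], sfr.box
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2.0 - 1e-9

    def test_impossible_placement_fails_loudly(self, small_protein):
        topology, frame, _ = small_protein
        with pytest.raises(RuntimeError, match="could not place"):
            generate_solvated_box(topology, frame, n_water=100_000, seed=0,
                                  max_attempts=20)


class TestKineticsGenerator:
    def test_noiseless_exact_curve(self):
        data = generate_kinetics_dataset(40.0, 3.0, levels=[10, 40, 100, 300],
                                         noise_cv=0.0)
        expected = 3.0 * data["substrate_mM"] / (40.0 + data["substrate_mM"])
        np.testing.assert_allclose(data["rate"], expected)
        # S = Km level sits at half of Vmax
        assert data["rate"][1] == pytest.approx(1.5)

    def test_levels_outside_assay_range_rejected(self):
        with pytest.raises(ValueError, match="300"):
            generate_kinetics_dataset(40.0, 3.0, levels=[10, 400])

    def test_seeded_noise_reproducible(self):
        a = generate_kinetics_dataset(40.0, 3.0, noise_cv=0.1, seed=8)
        b = generate_kinetics_dataset(40.0, 3.0, noise_cv=0.1, seed=8)
        assert np.array_equal(a["rate"], b["rate"])


class TestJitterTrajectory:
    def test_loops_wobble_more_than_helices(self, small_protein):
        topology, frame, partition = small_protein
        frames = generate_jitter_trajectory(
            topology, frame, partition, n_frames=60, seed=1
        )
        from dhpmd.flexibility import flexibility_profile

        profile = flexibility_profile(topology, frames)
        loop = partition.loops()[0]
        loop_rmsf = profile.rmsf.loc[loop.start:loop.end].mean()
        helix_rmsf = profile.rmsf.drop(
            index=range(loop.start, loop.end + 1)
        ).mean()
        assert loop_rmsf > helix_rmsf
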