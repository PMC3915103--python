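"""Phantom generator: determinism, field contracts, population geometry."""

import itertools

import numpy as np
import pytest

import atlasfuse as af
from atlasfuse.errors import ValidationError


class TestMakePhantom:
    def test_labels_histogram(self):
        _, lab = af.make_phantom(af.PhantomSpec(seed=1))
        assert set(np.unique(lab.data)) == {0, 1, 2, 3, 4}

    def test_same_seed_bit_identical(self):
        a_img, a_lab = af.make_phantom(af.PhantomSpec(seed=9))
        b_img, b_lab = af.make_phantom(af.PhantomSpec(seed=9))
        assert np.array_equal(a_img.data, b_img.data)
        assert np.array_equal(a_lab.data, b_lab.data)

    def test_different_seeds_differ(self):
        a_img, _ = af.make_phantom(af.PhantomSpec(seed=1))
        b_img, _ = af.make_phantom(af.PhantomSpec(seed=2))
        assert not np.array_equal(a_img.data, b_img.data)

    def test_clean_phantom_piecewise_constant_away_from_edges(self):
        spec = af.PhantomSpec(seed=0, noise_sd=0.0, bias_amplitude=0.0)
        img, lab = af.make_phantom(spec)
        from scipy.ndimage import binary_erosion

        core = binary_erosion(lab.data == 1, iterations=3)
        vals = img.data[core]
        assert vals.std() < 1.0  # flat interior once the smoothing shell is excluded

    def test_overlapping_structures_rejected(self):
        s = [
            af.Structure((16, 16, 16), (6, 6, 6), 1, 100.0),
            af.Structure((18, 16, 16), (6, 6, 6), 2, 120.0),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            af.make_phantom(af.PhantomSpec(structures=s))

    def test_structure_outside_grid_rejected(self):
        s = [af.Structure((2, 16, 16), (6, 6, 6), 1, 100.0)]
        with pytest.raises(ValidationError, match="fit"):
            af.PhantomSpec(structures=s)


class TestRandomSmoothField:
    def test_zero_max_disp_gives_zero_field(self):
        f = af.random_smooth_field((10, 10, 10), 0.0, 3.0, seed=0)
        assert f.max_magnitude() == 0.0

    def test_max_magnitude_matches_request(self):
        f = af.random_smooth_field((16, 16, 16), 2.5, 3.0, seed=4)
        assert f.max_magnitude() == pytest.approx(2.5, abs=1e-6)

    def test_seed_determinism(self):
        a = af.random_smooth_field((12, 12, 12), 3.0, 3.0, seed=8)
        b = af.random_smooth_field((12, 12, 12), 3.0, 3.0, seed=8)
        assert np.array_equal(a.data, b.data)

    def test_distinct_seeds_decorrelate(self):
        sims = []
        for s in range(10):
            a = af.random_smooth_field((12, 12, 12), 3.0, 3.0, seed=2 * s).data.ravel()
            b = af.random_smooth_field((12, 12, 12), 3.0, 3.0, seed=2 * s + 1).data.ravel()
            sims.append(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert abs(np.mean(sims)) < 0.15


class TestFieldAlgebra:
    def test_composition_equals_sequential_warp(self, rng):
        img = af.VolumeImage(
            af.make_phantom(af.PhantomSpec(seed=3, noise_sd=0.0))[0].data
        )
        outer = af.random_smooth_field(img.shape, 2.0, 4.0, seed=1)
        inner = af.random_smooth_field(img.shape, 2.0, 4.0, seed=2)
        composed = af.compose_fields(outer, inner)
        once = af.warp(img, composed, "linear")
        twice = af.warp(af.warp(img, outer, "linear"), inner, "linear")
        core = (slice(4, -4),) * 3
        assert np.abs(once.data[core] - twice.data[core]).mean() < 2.0

    def test_inverse_composes_to_near_identity(self):
        f = af.random_smooth_field((24, 24, 24), 2.0, 4.0, seed=5)
        inv = af.invert_field(f)
        residual = af.compose_fields(f, inv)  # x + inv(x) + f(x + inv(x)) - x
        core = residual.data[4:-4, 4:-4, 4:-4]
        assert np.abs(core).max() < 0.05

    def test_exponential_field_inverse_is_negated_velocity(self):
        v = af.random_smooth_field((24, 24, 24), 5.0, 4.0, seed=9)
        fwd = af.exponential_field(v)
        rev = af.exponential_field(af.DisplacementField(-v.data))
        residual = af.compose_fields(fwd, rev)
        core = residual.data[4:-4, 4:-4, 4:-4]
        # sub-voxel discretization error of the flow integration
        assert np.abs(core).max() < 0.25
        assert np.abs(core).mean() < 0.05

    def test_true_pairwise_field_maps_member_i_onto_member_j(self):
        base, _ = af.make_phantom(af.PhantomSpec(seed=6, noise_sd=0.0))
        c0 = af.random_smooth_field(base.shape, 2.0, 4.0, seed=20)
        c1 = af.random_smooth_field(base.shape, 2.0, 4.0, seed=21)
        member0 = af.warp(base, c0, "linear")
        member1 = af.warp(base, c1, "linear")
        f = af.true_pairwise_field(c0, c1)
        warped = af.warp(member0, f, "linear")
        msd_after = af.intensity_msd(member1, warped)
        msd_before = af.intensity_msd(member1, member0)
        assert msd_after < 0.5 * msd_before

    def test_oracle_fields_map_members_onto_each_other(self, default_population):
        pop, regs = default_population
        img0, _ = pop.members[0]
        img3, _ = pop.members[3]  # different mode
        warped = af.warp(img0, regs[("atlas00", "atlas03")].field, "linear")
        msd_after = af.intensity_msd(img3, warped)
        msd_before = af.intensity_msd(img3, img0)
        # the oracle warp must bring a cross-mode pair down to the
        # irreducible per-scan noise/bias floor (two scans' worth of noise)
        noise_floor = 2 * pop.spec.base.noise_sd**2
        assert msd_after < 0.35 * msd_before
        assert msd_after < 2.0 * noise_floor


class TestPopulation:
    def test_counts_and_mode_assignment(self, default_population):
        pop, _ = default_population
        assert len(pop.members) == 9
        assert sorted(pop.mode_assignment) == [0, 0, 0, 1, 1, 1, 2, 2, 2]
        assert len(pop.true_fields) == 9

    def test_determinism(self):
        spec = af.PopulationSpec(seed=2, k_modes=2, per_mode=2)
        a = af.make_population(spec)
        b = af.make_population(spec)
        assert np.array_equal(a.subject_image.data, b.subject_image.data)
        for (ai, _), (bi, _) in zip(a.members, b.members):
            assert np.array_equal(ai.data, bi.data)

    def test_within_mode_disp_must_be_smaller(self):
        with pytest.raises(ValidationError):
            af.PopulationSpec(between_mode_disp=1.0, within_mode_disp=2.0)

    def test_within_mode_image_msd_below_between_mode(self):
        wins = tries = 0
        for seed in range(3):
            pop = af.make_population(af.PopulationSpec(seed=seed, base=af.PhantomSpec(seed=seed)))
            imgs = [m[0] for m in pop.members]
            for i, j in itertools.combinations(range(9), 2):
                same = pop.mode_assignment[i] == pop.mode_assignment[j]
                if not same:
                    continue
                msd_within = af.intensity_msd(imgs[i], imgs[j])
                others = [
                    af.intensity_msd(imgs[i], imgs[k])
                    for k in range(9)
                    if pop.mode_assignment[k] != pop.mode_assignment[i]
                ]
                tries += 1
                wins += msd_within < min(others)
        assert wins / tries >= 0.95

    def test_within_mode_label_dsc_above_between_mode(self):
        pop = af.make_population(af.PopulationSpec(seed=4, base=af.PhantomSpec(seed=4)))
        labs = [m[1] for m in pop.members]
        within, between = [], []
        for i, j in itertools.combinations(range(9), 2):
            d = np.mean([af.dice(labs[i], labs[j], lab) for lab in (1, 2, 3, 4)])
            (within if pop.mode_assignment[i] == pop.mode_assignment[j] else between).append(d)
        assert np.mean(within) > np.mean(between)

    def test_subject_deforms_at_within_mode_scale(self, default_population):
        # flow of a velocity with max magnitude within_mode_disp: the
        # resulting displacement stays at that scale (well below the mode scale)
        pop, _ = default_population
        assert pop.subject_field.max_magnitude() <= 1.3 * pop.spec.within_mode_disp
        assert pop.subject_field.max_magnitude() < pop.spec.between_mode_disp / 2
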