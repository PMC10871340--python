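"""Geometry core: distances, torsions, rigid motions, chirality, scaler."""

import numpy as np
import pytest

from idpdiff.geometry import (
    Conformation,
    DegenerateScalerError,
    Ensemble,
    InvalidTransformError,
    alpha_torsions,
    apply_rigid_transform,
    canonical_coordinates,
    contact_frequencies,
    fit_distance_scaler,
    mirror,
    pair_separations,
    pairwise_distances,
    radius_of_gyration,
    random_rotation,
)
from idpdiff.synthetic import ToyEnsembleSpec, build_ideal_helix, sample_chain


def brute_force_dihedral(p0, p1, p2, p3):
    """Independent dihedral oracle via Gram-Schmidt frame construction."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_conformation(rng, L=10):
    return Conformation(sample_chain(
        ToyEnsembleSpec(model="ideal_chain", length=L, count=1,
                        seed=int(rng.integers(1 << 30)))
    ).coords[0])


class TestPairwiseDistances:
    def test_count_is_binomial(self):
        conf = random_conformation(np.random.default_rng(0), L=15)
        assert pairwise_distances(conf).shape == (105,)

    def test_two_atom_distance(self):
        conf = Conformation(np.array([[0.0, 0, 0], [3.8, 0, 0]]))
        assert pairwise_distances(conf) == pytest.approx([3.8])

    def test_rigid_motion_invariance(self, rng):
        conf = random_conformation(rng)
        moved = apply_rigid_transform(conf, random_rotation(rng),
                                      rng.standard_normal(3))
        np.testing.assert_allclose(
            pairwise_distances(conf), pairwise_distances(moved), atol=1e-9
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances(np.zeros((1, 3)))

    def test_ordering_matches_separations(self):
        seps = pair_separations(5)
        assert seps.tolist() == [1, 2, 3, 4, 1, 2, 3, 1, 2, 1]


class TestAlphaTorsions:
    def test_count(self):
        conf = random_conformation(np.random.default_rng(3), L=59)
        assert alpha_torsions(conf).angles.shape == (56,)

    def test_trans_zigzag_is_180(self):
        # planar zig-zag: all four atoms coplanar, trans configuration
        coords = np.array(
            [[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0]], dtype=float
        )
        assert alpha_torsions(coords).angles[0] == pytest.approx(180.0)

    def test_right_handed_helix_positive_and_matches_oracle(self):
        helix = build_ideal_helix(12)
        angles = alpha_torsions(helix).angles
        expected = [
            brute_force_dihedral(*helix.coords[i : i + 4]) for i in range(9)
        ]
        np.testing.assert_allclose(angles, expected, atol=1e-6)
        assert np.all(angles > 50) and np.all(angles < 55)

    def test_oracle_on_random_quadruples(self, rng):
        for _ in range(1000):
            pts = rng.standard_normal((4, 3)) * 3
            try:
                got = alpha_torsions(pts).angles[0]
            except ValueError:
                continue
            want = brute_force_dihedral(*pts)
            assert abs((got - want + 180) % 360 - 180) < 1e-6

    def test_needs_four_atoms(self):
        with pytest.raises(ValueError):
            alpha_torsions(np.zeros((3, 3)) + np.arange(3)[:, None])

    def test_unit_vectors_unit_norm(self, rng):
        conf = random_conformation(rng)
        tf = alpha_torsions(conf)
        np.testing.assert_allclose(
            np.linalg.norm(tf.unit_vectors, axis=1), 1.0, atol=1e-9
        )


class TestRadiusOfGyration:
    def test_coincident_atoms_zero(self):
        ens = np.ones((4, 3))
        # Conformation forbids coincident consecutive atoms; use raw array
        assert radius_of_gyration(ens) == pytest.approx(0.0)

    def test_two_points(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(2.0)

    def test_square_matches_brute_force(self, rng):
        a = 2.5
        coords = np.array([[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]], float)
        centroid = coords.mean(axis=0)
        brute = np.sqrt(np.mean([np.sum((c - centroid) ** 2) for c in coords]))
        assert radius_of_gyration(coords) == pytest.approx(brute)
        assert brute == pytest.approx(a / np.sqrt(2))

    def test_naive_double_loop_agreement(self, rng):
        conf = random_conformation(rng)
        centroid = conf.coords.mean(axis=0)
        naive = np.sqrt(
            sum(np.sum((c - centroid) ** 2) for c in conf.coords) / conf.length
        )
        assert radius_of_gyration(conf) == pytest.approx(naive)


class TestContactFrequencies:
    def _ens(self, coords):
        return Ensemble(sequence="A" * coords.shape[1], coords=coords)

    def test_close_pair_counts(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 3.8
        assert contact_frequencies(self._ens(coords))[0, 1] == 1.0

    def test_far_pair_does_not(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 9.0
        assert contact_frequencies(self._ens(coords))[0, 1] == 0.0

    def test_half_frequency(self):
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 5.0
        coords[1, 1, 0] = 10.0
        freq = contact_frequencies(self._ens(coords))
        assert freq[0, 1] == 0.5
        assert freq[1, 0] == 0.5  # symmetry

    def test_values_in_unit_interval(self, rng):
        ens = sample_chain(ToyEnsembleSpec(length=8, count=20, seed=5))
        freq = contact_frequencies(ens)
        assert np.all(freq >= 0) and np.all(freq <= 1)


class TestRigidTransformAndMirror:
    def test_identity(self, rng):
        conf = random_conformation(rng)
        same = apply_rigid_transform(conf, np.eye(3), np.zeros(3))
        np.testing.assert_array_equal(same.coords, conf.coords)

    def test_composition_is_group_law(self, rng):
        conf = random_conformation(rng)
        r1, r2 = random_rotation(rng), random_rotation(rng)
        t1, t2 = rng.standard_normal(3), rng.standard_normal(3)
        a = apply_rigid_transform(apply_rigid_transform(conf, r1, t1), r2, t2)
        b = apply_rigid_transform(conf, r2 @ r1, r2 @ t1 + t2)
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)

    def test_reflection_rejected(self, rng):
        conf = random_conformation(rng)
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(InvalidTransformError):
            apply_rigid_transform(conf, refl, np.zeros(3))

    def test_isometry_suite(self, rng):
        # distances to 1e-9 and torsions to 1e-6 deg under random motions
        for _ in range(20):
            conf = random_conformation(rng)
            for _ in range(10):
                moved = apply_rigid_transform(
                    conf, random_rotation(rng), 10 * rng.standard_normal(3)
                )
                np.testing.assert_allclose(
                    pairwise_distances(conf), pairwise_distances(moved),
                    atol=1e-9,
                )
                np.testing.assert_allclose(
                    alpha_torsions(conf).angles, alpha_torsions(moved).angles,
                    atol=1e-6,
                )

    def test_mirror_negates_torsions_preserves_distances(self, rng):
        for _ in range(20):
            conf = random_conformation(rng)
            m = mirror(conf)
            np.testing.assert_allclose(
                pairwise_distances(conf), pairwise_distances(m), atol=1e-9
            )
            np.testing.assert_allclose(
                alpha_torsions(m).angles, -alpha_torsions(conf).angles,
                atol=1e-6,
            )
            assert radius_of_gyration(m) == pytest.approx(
                radius_of_gyration(conf)
            )

    def test_mirror_is_involution(self, rng):
        conf = random_conformation(rng)
        np.testing.assert_allclose(
            mirror(mirror(conf)).coords, conf.coords, atol=1e-12
        )


class TestDistanceScaler:
    @pytest.fixture
    def jittered(self):
        return sample_chain(
            ToyEnsembleSpec(length=12, count=300, jitter_sigma=0.5, seed=7)
        )

    def test_roundtrip_identity(self, jittered):
        scaler = fit_distance_scaler([jittered], k_max=8)
        d = np.array([3.0, 5.5, 12.0])
        for k in (1, 3, 8, 11):  # 11 clamps to k_max
            np.testing.assert_allclose(
                scaler.invert(scaler.apply(d, k), k), d, atol=1e-9
            )

    def test_standardizes_training_data(self, jittered):
        scaler = fit_distance_scaler([jittered], k_max=50)
        from idpdiff.geometry import batch_pairwise_distances

        d = batch_pairwise_distances(jittered.coords)
        seps = pair_separations(jittered.length)
        for k in (1, 4, 9):
            vals = scaler.apply(d[:, seps == k].ravel(), k)
            assert abs(vals.mean()) < 1e-6
            assert abs(vals.std(ddof=1) - 1.0) < 1e-6

    def test_monotone_in_d(self, jittered):
        scaler = fit_distance_scaler([jittered], k_max=8)
        assert scaler.apply(5.0, 2) < scaler.apply(6.0, 2)

    def test_zero_variance_bin_raises(self):
        rigid = sample_chain(ToyEnsembleSpec(length=8, count=50, seed=3))
        with pytest.raises(DegenerateScalerError, match=r"bin"):
            fit_distance_scaler([rigid], k_max=7)


class TestCanonicalCoordinates:
    def test_reproduces_internal_coordinates(self, rng):
        conf = random_conformation(rng, L=14)
        rebuilt = canonical_coordinates(conf)
        np.testing.assert_allclose(
            pairwise_distances(rebuilt), pairwise_distances(conf), atol=1e-9
        )
        np.testing.assert_allclose(
            alpha_torsions(rebuilt).angles, alpha_torsions(conf).angles,
            atol=1e-6,
        )

    def test_rigid_motion_invariance(self, rng):
        conf = random_conformation(rng)
        moved = apply_rigid_transform(conf, random_rotation(rng),
                                      rng.standard_normal(3))
        np.testing.assert_allclose(
            canonical_coordinates(conf), canonical_coordinates(moved),
            atol=1e-9,
        )

    def test_mirror_changes_result(self, rng):
        helix = build_ideal_helix(10)
        a = canonical_coordinates(helix)
        b = canonical_coordinates(mirror(helix))
        assert np.abs(a - b).max() > 0.1
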