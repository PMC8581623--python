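"""Configuration clustering and geometric metrics."""

import itertools

import numpy as np
import pytest

from oligokin.structures import (
    GeometryError,
    OligomerStructure,
    canonical_order,
    cluster_configurations,
    dimer_binding_angles,
    principal_axis_lengths,
    superpose_rmsd,
    trimer_bending_angle,
)
from oligokin.synthetic import PseudoReceptor

BODY = PseudoReceptor.default()


def make_structure(centers, axes_deg, t=0.0):
    """Build an oligomer from per-member centers and reference-axis headings.

    Heading 0 deg points along +x; the body template is rotated so its
    orientation bead lies along the heading.
    """
    coords = []
    for (cx, cy), heading in zip(centers, axes_deg):
        a = np.deg2rad(heading)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        coords.append(BODY.bead_offsets @ rot.T + np.array([cx, cy]))
    return OligomerStructure(
        member_ids=tuple(range(len(coords))),
        coords=np.stack(coords),
        frame_time=t,
        orientation_bead=BODY.orientation_bead,
    )


def rigid_transform(s, angle_deg, shift):
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    flat = s.coords.reshape(-1, 2) @ rot.T + np.asarray(shift)
    return OligomerStructure(
        member_ids=s.member_ids,
        coords=flat.reshape(s.coords.shape),
        frame_time=s.frame_time,
        orientation_bead=s.orientation_bead,
    )


def grid_scan_rmsd(A, B, n=4096):
    """Independent superposition oracle: brute-force rotation angle scan."""
    A = A.reshape(-1, 2) - A.reshape(-1, 2).mean(axis=0)
    B = B.reshape(-1, 2) - B.reshape(-1, 2).mean(axis=0)
    best = np.inf
    for theta in np.linspace(0, 2 * np.pi, n, endpoint=False):
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        best = min(best, np.sqrt(np.mean(np.sum((A @ rot.T - B) ** 2, axis=1))))
    return best


class TestCanonicalOrder:
    def test_shuffled_copy_recovers_permutation(self):
        ref = make_structure([(0, 0), (3, 0), (0, 3)], [10, 120, 250])
        pi = (2, 0, 1)
        shuffled = OligomerStructure(
            member_ids=ref.member_ids,
            coords=ref.coords[list(pi)],
            frame_time=0.0,
            orientation_bead=ref.orientation_bead,
        )
        perm, rmsd = canonical_order(shuffled, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        # applying the returned permutation restores the reference order
        assert np.allclose(shuffled.coords[list(perm)], ref.coords)

    def test_identity_for_identical_structure(self):
        ref = make_structure([(0, 0), (3, 1)], [0, 90])
        perm, rmsd = canonical_order(ref, ref)
        assert perm == (0, 1)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_order5_matches_exhaustive_grid_oracle(self):
        rng = np.random.default_rng(7)
        ref = make_structure(rng.uniform(0, 10, (5, 2)), rng.uniform(0, 360, 5))
        s = make_structure(rng.uniform(0, 10, (5, 2)), rng.uniform(0, 360, 5))
        perm, rmsd = canonical_order(s, ref)
        oracle = min(
            grid_scan_rmsd(s.coords[list(p)], ref.coords)
            for p in itertools.permutations(range(5))
        )
        assert rmsd == pytest.approx(oracle, abs=1e-3)
        # no other permutation beats the returned one
        for p in itertools.permutations(range(5)):
            other, _ = superpose_rmsd(
                s.coords[list(p)].reshape(-1, 2), ref.coords.reshape(-1, 2)
            )
            assert rmsd <= other + 1e-12

    def test_rejects_mismatched_orders(self):
        dimer = make_structure([(0, 0), (3, 0)], [0, 180])
        trimer = make_structure([(0, 0), (3, 0), (6, 0)], [0, 0, 0])
        with pytest.raises(ValueError):
            canonical_order(dimer, trimer)


class TestClustering:
    @staticmethod
    def planted_pool(n_each=20, seed=0):
        """Head-to-head vs side-by-side dimers, randomly placed/rotated."""
        rng = np.random.default_rng(seed)
        pool, truth = [], []
        for kind in (0, 1):
            for _ in range(n_each):
                if kind == 0:  # head-to-head: both axes point at the partner
                    base = make_structure([(0, 0), (3.0, 0)], [0, 180])
                else:  # side-by-side: axes perpendicular to the interface
                    base = make_structure([(0, 0), (3.0, 0)], [90, 90])
                jitter = rng.normal(0, 0.05, base.coords.shape)
                noisy = OligomerStructure(
                    member_ids=base.member_ids,
                    coords=base.coords + jitter,
                    frame_time=0.0,
                    orientation_bead=base.orientation_bead,
                )
                pool.append(
                    rigid_transform(
                        noisy, rng.uniform(0, 360), rng.uniform(-20, 20, 2)
                    )
                )
                truth.append(kind)
        return pool, np.array(truth)

    def test_two_planted_geometries_separate_perfectly(self):
        pool, truth = self.planted_pool()
        clusters = cluster_configurations(pool, k=2, seed=0)
        assert [c.label for c in clusters] == ["2.1", "2.2"]
        for c in clusters:
            assert len(set(truth[c.member_indices])) == 1

    def test_k1_single_cluster(self):
        pool, _ = self.planted_pool(n_each=5)
        clusters = cluster_configurations(pool, k=1, seed=0)
        assert len(clusters) == 1 and clusters[0].size == len(pool)

    def test_invariant_to_member_relabeling(self):
        pool, _ = self.planted_pool()
        swapped = [
            OligomerStructure(
                member_ids=s.member_ids[::-1],
                coords=s.coords[::-1],
                frame_time=s.frame_time,
                orientation_bead=s.orientation_bead,
            )
            for s in pool
        ]
        a = cluster_configurations(pool, k=2, seed=0)
        b = cluster_configurations(swapped, k=2, seed=0)
        assert [set(c.member_indices) for c in a] == [
            set(c.member_indices) for c in b
        ]

    def test_k_larger_than_pool_rejected(self):
        pool, _ = self.planted_pool(n_each=2)
        with pytest.raises(ValueError):
            cluster_configurations(pool, k=10, seed=0)


class TestDimerAngles:
    def test_mutually_facing_axes_give_zero(self):
        d = make_structure([(0, 0), (3, 0)], [0, 180])
        m = dimer_binding_angles(d)
        assert m.theta1 == pytest.approx(0.0, abs=1e-9)
        assert m.theta2 == pytest.approx(0.0, abs=1e-9)

    def test_axes_rotated_90_clockwise(self):
        # both reference axes 90 deg clockwise (viewed from +z) of the
        # partner direction -> theta = 270 under the clockwise convention
        d = make_structure([(0, 0), (3, 0)], [-90, 90])
        m = dimer_binding_angles(d)
        assert m.theta1 == pytest.approx(270.0)
        assert m.theta2 == pytest.approx(270.0)

    def test_rigid_rotation_invariance(self):
        d = make_structure([(0, 0), (3, 0)], [35, 200])
        m0 = dimer_binding_angles(d)
        m1 = dimer_binding_angles(rigid_transform(d, 57.0, (4.2, -7.7)))
        assert m1.theta1 == pytest.approx(m0.theta1, abs=1e-9)
        assert m1.theta2 == pytest.approx(m0.theta2, abs=1e-9)

    def test_mirror_image_flips_convention(self):
        d = make_structure([(0, 0), (3, 0)], [40, 140])
        mirrored = OligomerStructure(
            member_ids=d.member_ids,
            coords=d.coords * np.array([1.0, -1.0]),
            frame_time=0.0,
            orientation_bead=d.orientation_bead,
        )
        m0, m1 = dimer_binding_angles(d), dimer_binding_angles(mirrored)
        assert m1.theta1 == pytest.approx((360 - m0.theta1) % 360, abs=1e-9)
        assert m1.theta2 == pytest.approx((360 - m0.theta2) % 360, abs=1e-9)

    def test_coincident_centers_raise(self):
        d = make_structure([(0, 0), (0, 0)], [0, 0])
        with pytest.raises(GeometryError):
            dimer_binding_angles(d)


class TestTrimerAngle:
    def test_collinear_chain_is_180(self):
        t = make_structure([(0, 0), (2.7, 0), (5.4, 0)], [0, 0, 0])
        assert trimer_bending_angle(t, cutoff=0.75).phi == pytest.approx(180.0)

    def test_equilateral_cyclic_is_60(self):
        a = 2.7
        t = make_structure(
            [(0, 0), (a, 0), (a / 2, a * np.sqrt(3) / 2)], [0, 0, 0]
        )
        assert trimer_bending_angle(t, cutoff=0.75).phi == pytest.approx(60.0)

    def test_right_angle_vertex(self):
        t = make_structure([(0, 0), (2.7, 0), (2.7, 2.7)], [0, 0, 0])
        assert trimer_bending_angle(t, cutoff=0.75).phi == pytest.approx(90.0)


class TestSpans:
    def test_rectangle_of_centers(self):
        q = make_structure(
            [(0, 0), (10, 0), (10, 4), (0, 4)], [0, 90, 180, 270]
        )
        m = principal_axis_lengths(q)
        assert m.d1 == pytest.approx(10.0)
        assert m.d2 == pytest.approx(4.0)

    def test_collinear_centers(self):
        q = make_structure([(0, 0), (5, 0), (10, 0), (15, 0)], [0, 0, 0, 0])
        m = principal_axis_lengths(q)
        assert m.d1 == pytest.approx(15.0)
        assert m.d2 == pytest.approx(0.0, abs=1e-9)

    def test_rotation_invariance(self):
        q = make_structure([(0, 0), (10, 0), (10, 4), (0, 4)], [0, 0, 0, 0])
        m0 = principal_axis_lengths(q)
        m1 = principal_axis_lengths(rigid_transform(q, 33.3, (5.0, 5.0)))
        assert m1.d1 == pytest.approx(m0.d1, abs=1e-9)
        assert m1.d2 == pytest.approx(m0.d2, abs=1e-9)
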