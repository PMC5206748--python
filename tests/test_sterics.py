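import numpy as np
import pytest

from xdc.geometry import axis_angle_rotation
from xdc.sterics import (
    Body,
    EmptyBodyError,
    buried_surface_area,
    clash_pairs,
    overlap_volume,
    sasa,
    signed_clearance,
    sphere_overlap_volume,
)
from xdc.structure import MAIN_CHAIN, Selection
from xdc.synthetic import make_toy_domain


def sphere(center, r):
    return Body(np.atleast_2d(center).astype(float), np.array([r], float))


def mc_overlap_oracle(bodyA, bodyB, n_samples=1_000_000, seed=0):
    """Monte-Carlo intersection volume: uniform samples in the joint box."""
    rng = np.random.default_rng(seed)
    lo = np.minimum(
        (bodyA.coords - bodyA.radii[:, None]).min(0),
        (bodyB.coords - bodyB.radii[:, None]).min(0),
    )
    hi = np.maximum(
        (bodyA.coords + bodyA.radii[:, None]).max(0),
        (bodyB.coords + bodyB.radii[:, None]).max(0),
    )
    pts = rng.uniform(lo, hi, size=(n_samples, 3))

    def inside(body):
        ok = np.zeros(len(pts), dtype=bool)
        for c, r in zip(body.coords, body.radii):
            ok |= np.einsum("ij,ij->i", pts - c, pts - c) <= r * r
        return ok

    frac = np.mean(inside(bodyA) & inside(bodyB))
    return float(frac * np.prod(hi - lo))


class TestOverlapVolume:
    def test_distant_spheres_have_zero_overlap_and_no_pairs(self):
        res = overlap_volume(sphere([0, 0, 0], 2.0), sphere([10, 0, 0], 2.0))
        assert res.volume == 0.0
        assert res.clash_pairs == []
        assert not res.has_clash

    def test_coincident_spheres_give_full_sphere_volume(self):
        res = overlap_volume(sphere([0, 0, 0], 2.0), sphere([0, 0, 0], 2.0), 0.3)
        assert res.volume == pytest.approx(4 / 3 * np.pi * 8, rel=0.02)

    @pytest.mark.parametrize("d", [0.5, 1.0, 1.5, 2.0])
    def test_two_sphere_lens_matches_analytic(self, d):
        # lenses comparable to or below one grid cell cannot be resolved,
        # so separations are kept where the lens spans many cells
        res = overlap_volume(sphere([0, 0, 0], 2.0), sphere([d, 0, 0], 2.0), 0.3)
        want = sphere_overlap_volume(2.0, 2.0, d)
        assert res.volume == pytest.approx(want, rel=0.02)

    def test_multi_atom_overlap_matches_monte_carlo(self, rng):
        A = Body(rng.normal(0, 1.5, (8, 3)), np.full(8, 1.7))
        B = Body(rng.normal(1.0, 1.5, (8, 3)), np.full(8, 1.6))
        got = overlap_volume(A, B, 0.3).volume
        want = mc_overlap_oracle(A, B, seed=42)
        assert got == pytest.approx(want, rel=0.02)

    def test_volume_converges_with_grid_refinement(self, rng):
        A = Body(rng.normal(0, 1.5, (6, 3)), np.full(6, 1.7))
        B = Body(rng.normal(0.8, 1.5, (6, 3)), np.full(6, 1.7))
        v_coarse = overlap_volume(A, B, 0.5).volume
        v_fine = overlap_volume(A, B, 0.25).volume
        assert abs(v_coarse - v_fine) / v_fine < 0.05

    def test_rigid_motion_invariance(self, rng):
        A = Body(rng.normal(0, 2, (10, 3)), np.full(10, 1.7))
        B = Body(rng.normal(1, 2, (10, 3)), np.full(10, 1.7))
        R = axis_angle_rotation([1, 2, 3], 53.0)
        t = np.array([7.0, -4.0, 11.0])
        A2 = Body(A.coords @ R.T + t, A.radii)
        B2 = Body(B.coords @ R.T + t, B.radii)
        v1 = overlap_volume(A, B, 0.3).volume
        v2 = overlap_volume(A2, B2, 0.3).volume
        assert v2 == pytest.approx(v1, rel=0.03, abs=0.05)

    def test_clash_pairs_iff_positive_volume(self):
        touching = overlap_volume(sphere([0, 0, 0], 2.0), sphere([3, 0, 0], 2.0), 0.3)
        assert touching.volume > 0 and len(touching.clash_pairs) == 1
        apart = overlap_volume(sphere([0, 0, 0], 2.0), sphere([4.1, 0, 0], 2.0), 0.3)
        assert apart.volume == 0.0 and not apart.clash_pairs

    def test_empty_body_raises(self):
        with pytest.raises(EmptyBodyError):
            Body(np.zeros((0, 3)), np.zeros(0))

    def test_invalid_grid_spacing_rejected(self):
        a, b = sphere([0, 0, 0], 2.0), sphere([1, 0, 0], 2.0)
        for bad in (0.05, 1.5):
            with pytest.raises(ValueError):
                overlap_volume(a, b, bad)


class TestSignedClearance:
    def test_overlapping_bodies_report_positive_volume(self):
        a, b = sphere([0, 0, 0], 2.0), sphere([1, 0, 0], 2.0)
        sc = signed_clearance(a, b, 0.3)
        assert sc.signed_score == overlap_volume(a, b, 0.3).volume > 0

    def test_one_angstrom_gap_matches_inflated_lens(self):
        # r=2 spheres, gap 1 Å (d=5); probe 1.4 inflates to r'=3.4
        sc = signed_clearance(sphere([0, 0, 0], 2.0), sphere([5, 0, 0], 2.0), 0.3)
        want = -sphere_overlap_volume(3.4, 3.4, 5.0)
        assert sc.signed_score == pytest.approx(want, rel=0.02)
        assert not sc.far_apart

    def test_far_apart_flag_beyond_probe_reach(self):
        sc = signed_clearance(sphere([0, 0, 0], 2.0), sphere([20, 0, 0], 2.0), 0.3)
        assert sc.signed_score == 0.0
        assert sc.far_apart

    def test_monotone_within_each_regime(self):
        def score(d):
            return signed_clearance(
                sphere([0, 0, 0], 2.0), sphere([d, 0, 0], 2.0), 0.25
            ).signed_score

        # pre-contact margin strictly decreases as the bodies approach
        margin = [score(d) for d in (6.5, 6.0, 5.5, 5.0, 4.5)]
        assert all(s2 < s1 for s1, s2 in zip(margin, margin[1:]))
        # once clashing, the positive volume strictly grows on approach
        clash = [score(d) for d in (3.5, 2.5, 1.5, 0.5)]
        assert all(s2 > s1 > 0 for s1, s2 in zip(clash, clash[1:]))


class TestSasa:
    def test_single_atom_matches_analytic_sphere(self):
        b = Body(np.zeros((1, 3)), np.array([1.7]))
        res = sasa(b, probe_radius=1.4, n_points=960)
        assert res.total == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_two_distant_atoms_are_additive(self):
        single = sasa(Body(np.zeros((1, 3)), np.array([1.7]))).total
        pair = sasa(
            Body(np.array([[0.0, 0, 0], [100.0, 0, 0]]), np.array([1.7, 1.7]))
        ).total
        assert pair == pytest.approx(2 * single, rel=1e-9)

    def test_total_is_sum_of_per_atom(self, rng):
        b = Body(rng.normal(0, 3, (15, 3)), np.full(15, 1.7))
        res = sasa(b)
        assert res.total == pytest.approx(float(res.per_atom.sum()), abs=1e-6)
        assert (res.per_atom >= 0).all()

    def test_cluster_matches_biotite_oracle(self, rng):
        import biotite.structure as struc

        coords = rng.normal(0, 2.5, (20, 3))
        radii = np.full(20, 1.7)
        got = sasa(Body(coords, radii), probe_radius=1.4, n_points=960).total
        arr = struc.AtomArray(20)
        arr.coord = coords.astype(np.float32)
        arr.set_annotation("element", np.array(["C"] * 20))
        want = float(
            struc.sasa(arr, probe_radius=1.4, point_number=2000, vdw_radii=radii).sum()
        )
        assert got == pytest.approx(want, rel=0.02)

    def test_point_count_floor_enforced(self):
        with pytest.raises(ValueError):
            sasa(Body(np.zeros((1, 3)), np.array([1.7])), n_points=50)


class TestBuriedSurfaceArea:
    def _two_chain_structure(self, separation):
        a = make_toy_domain(6, chain_id="A", seed=1)
        b = make_toy_domain(6, chain_id="B", seed=1).apply_transform(
            np.eye(3), np.array([separation, 0.0, 0.0])
        )
        a.chains["B"] = b.chains["B"]
        return a

    def test_distant_parts_bury_nothing(self):
        st = self._two_chain_structure(100.0)
        bsa = buried_surface_area(st, Selection.parse("A"), Selection.parse("B"))
        assert bsa == pytest.approx(0.0, abs=1e-6)

    def test_touching_parts_bury_positive_area_symmetrically(self):
        st = self._two_chain_structure(6.0)
        ab = buried_surface_area(st, Selection.parse("A"), Selection.parse("B"))
        ba = buried_surface_area(st, Selection.parse("B"), Selection.parse("A"))
        assert ab > 0
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_two_touching_spheres_match_analytic(self):
        # two atoms r=1.7, d=3.0: buried cap area per sphere is analytic
        r = 1.7 + 1.4
        d = 3.0
        # each inflated sphere loses a cap of height h = r - d/2
        h = r - d / 2
        analytic_bsa = 2 * (2 * np.pi * r * h)
        a = Body(np.array([[0.0, 0, 0]]), np.array([1.7]))
        b = Body(np.array([[d, 0, 0]]), np.array([1.7]))
        pair = Body(np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([1.7, 1.7]))
        got = sasa(a, n_points=5000).total + sasa(b, n_points=5000).total - sasa(pair, n_points=5000).total
        assert got == pytest.approx(analytic_bsa, rel=0.02)


class TestClashPairs:
    def test_pair_listing_reports_overlap_distance(self):
        pairs = clash_pairs(sphere([0, 0, 0], 2.0), sphere([3, 0, 0], 2.0))
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(1.0, abs=1e-9)

    def test_slack_widens_the_net(self):
        a, b = sphere([0, 0, 0], 2.0), sphere([4.5, 0, 0], 2.0)
        assert clash_pairs(a, b, slack=0.0) == []
        assert len(clash_pairs(a, b, slack=1.0)) == 1
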