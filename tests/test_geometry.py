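import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from xdc.errors import IllPosedError, PairingError
from xdc.geometry import (
    RigidTransform,
    axis_angle_rotation,
    domain_rotation,
    kabsch,
    kabsch_superpose,
    relative_rotation_angle,
    rmsd_between,
)
from xdc.structure import MAIN_CHAIN, Selection
from xdc.synthetic import make_toy_domain, perturb_structure


def quaternion_rmsd_oracle(P, Q, n_starts=12, seed=0):
    """Brute-force minimum RMSD via quaternion-parameterized optimization.

    Independent of the SVD path under test: parameterizes the rotation by a
    unit quaternion and minimizes numerically from many starts.
    """
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def cost(q):
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        return np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


class TestKabsch:
    def test_identical_sets_give_identity_and_zero_rmsd(self, rng):
        P = rng.normal(size=(30, 3))
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_known_rotation_recovered_exactly(self, rng):
        P = rng.normal(size=(50, 3)) * 10
        R = axis_angle_rotation([1.0, 2.0, -0.5], 37.0)
        t = np.array([4.0, -2.0, 7.0])
        Q = P @ R.T + t
        res = kabsch_superpose(P, Q)
        assert res.rmsd < 1e-9
        composed = res.transform.compose(RigidTransform(R, t).inverse())
        assert composed.angle_degrees() < 1e-6
        assert np.linalg.norm(composed.apply(P) - P, axis=1).max() < 1e-6

    def test_noisy_cloud_matches_quaternion_oracle(self, rng):
        P = rng.normal(size=(50, 3)) * 10
        R = axis_angle_rotation([0.0, 1.0, 1.0], 63.0)
        Q = P @ R.T + np.array([1.0, 2.0, 3.0]) + rng.normal(0, 0.1, size=P.shape)
        got = kabsch_superpose(P, Q).rmsd
        want = quaternion_rmsd_oracle(P, Q)
        assert got == pytest.approx(want, abs=1e-6)
        # cross-check against scipy's own implementation
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert got == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-9)

    def test_kabsch_is_optimal_among_random_rotations(self, rng):
        P = rng.normal(size=(20, 3)) * 5
        Q = P @ axis_angle_rotation([1, 0, 0], 20.0).T + rng.normal(0, 0.3, P.shape)
        best = kabsch_superpose(P, Q).rmsd
        P0, Q0 = P - P.mean(0), Q - Q.mean(0)
        for _ in range(1000):
            R = Rotation.random(random_state=rng).as_matrix()
            rmsd = np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1)))
            assert rmsd >= best - 1e-9

    def test_degenerate_inputs_raise(self, rng):
        with pytest.raises(IllPosedError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.linspace(0, 1, 10), [1.0, 0.0, 0.0])
        with pytest.raises(IllPosedError):
            kabsch(line, line)

    def test_reflection_is_corrected_to_proper_rotation(self, rng):
        P = rng.normal(size=(25, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored cloud
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)


class TestRmsdBetween:
    def test_self_rmsd_is_zero(self, toy_domain):
        sel = Selection(("A",), None, MAIN_CHAIN)
        res = rmsd_between(toy_domain, toy_domain, sel)
        mean, sd = res.per_residue_mean_sd
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert (mean, sd) == (pytest.approx(0.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))

    def test_translated_copy_without_fit_reports_the_shift(self, toy_domain):
        moved = toy_domain.apply_transform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        sel = Selection(("A",), None, MAIN_CHAIN)
        res = rmsd_between(toy_domain, moved, sel, fit=False)
        assert res.rmsd == pytest.approx(1.0, abs=1e-9)
        fitted = rmsd_between(toy_domain, moved, sel, fit=True)
        assert fitted.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_is_symmetric(self, toy_domain):
        noisy = perturb_structure(toy_domain, 0.7, seed=3)
        sel = Selection(("A",), None, MAIN_CHAIN)
        ab = rmsd_between(toy_domain, noisy, sel).rmsd
        ba = rmsd_between(noisy, toy_domain, sel).rmsd
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_gaps_are_dropped_pairwise(self, toy_domain):
        partial = toy_domain.copy()
        del partial.chains["A"].residues[(5, "")]
        sel = Selection(("A",), (1, 10), MAIN_CHAIN)
        res = rmsd_between(toy_domain, partial, sel)
        assert res.n_atoms == 9 * 4
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_too_few_paired_residues_raise(self, toy_domain):
        sel = Selection(("A",), (1, 2), MAIN_CHAIN)
        with pytest.raises(PairingError):
            rmsd_between(toy_domain, toy_domain, sel)

    def test_rmsd_squared_equals_mean_squared_deviations(self, toy_domain):
        noisy = perturb_structure(toy_domain, 0.5, seed=9)
        sel = Selection(("A",), None, MAIN_CHAIN)
        res = rmsd_between(toy_domain, noisy, sel, fit=False)
        devs = np.concatenate(
            [[d] * 4 for _, d in sorted(res.per_residue_deviation)]
        )
        # per-residue means don't reconstruct rmsd exactly; use raw atoms
        a = toy_domain.coords()
        b = noisy.coords()
        assert res.rmsd**2 == pytest.approx(np.mean(np.sum((a - b) ** 2, axis=1)), rel=1e-9)


class TestRotationAngle:
    def test_equal_transforms_give_zero(self):
        tr = RigidTransform(axis_angle_rotation([1, 1, 0], 25.0), np.zeros(3))
        assert relative_rotation_angle(tr, tr) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [1.0, 8.6, 10.0, 90.0, 179.0])
    def test_constructed_relative_rotation_recovered(self, angle):
        base = RigidTransform(axis_angle_rotation([0.3, -1.0, 2.0], 77.0), np.array([1.0, 2.0, 3.0]))
        extra = RigidTransform(axis_angle_rotation([0.0, 0.0, 1.0], angle), np.zeros(3))
        other = extra.compose(base)
        assert relative_rotation_angle(base, other) == pytest.approx(angle, abs=1e-6)

    def test_invariant_to_common_frame_change(self, rng):
        A = RigidTransform(axis_angle_rotation([1, 0, 0], 30.0), rng.normal(size=3))
        B = RigidTransform(axis_angle_rotation([0, 1, 0], 50.0), rng.normal(size=3))
        frame = RigidTransform(axis_angle_rotation([1, 1, 1], 111.0), rng.normal(size=3))
        a1 = relative_rotation_angle(A, B)
        a2 = relative_rotation_angle(frame.compose(A), frame.compose(B))
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_domain_rotation_recovers_planted_hinge_angle(self):
        # two-domain structure: domain B rotated by 8.6 deg about a hinge
        domA = make_toy_domain(10, chain_id="A", seed=1)
        domB = make_toy_domain(10, chain_id="B", seed=2)
        domB = domB.apply_transform(np.eye(3), np.array([20.0, 0.0, 0.0]))
        template = domA.copy()
        template.chains["B"] = domB.chains["B"]
        rotated = template.copy()
        R = axis_angle_rotation([0.0, 1.0, 0.3], 8.6)
        hinge = domB.coords().mean(axis=0)
        moved_b = domB.apply_transform(R, hinge - R @ hinge)
        rotated.chains["B"] = moved_b.chains["B"]
        # bury the hinge signal under a global rigid motion of the whole structure
        Rg = axis_angle_rotation([1.0, 0.0, 0.0], 40.0)
        rotated = rotated.apply_transform(Rg, np.array([5.0, -3.0, 2.0]))
        angle = domain_rotation(
            rotated, template, Selection(("A",), None, MAIN_CHAIN), Selection(("B",), None, MAIN_CHAIN)
        )
        assert angle == pytest.approx(8.6, abs=1e-6)


class TestRigidTransform:
    def test_inverse_composes_to_identity(self, rng):
        tr = RigidTransform(axis_angle_rotation(rng.normal(size=3), 33.0), rng.normal(size=3))
        ident = tr.compose(tr.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(ident.translation, 0.0, atol=1e-9)
        P = rng.normal(size=(10, 3))
        assert np.abs(tr.inverse().apply(tr.apply(P)) - P).max() < 1e-9

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(IllPosedError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))
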