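import numpy as np
import pytest

from megastitch import (
    StructureModel,
    assemble,
    clash_report,
    fragment_and_perturb,
    kabsch_superpose,
    superpose_on_overlap,
)
from megastitch.errors import (
    InsufficientAtomsError,
    ParameterError,
    SequenceMismatchError,
)
from megastitch.stitcher import RigidTransform

from .oracles import brute_force_clashes, quaternion_superpose


def _rmsd_after_fit(A, B):
    _, rmsd = kabsch_superpose(A, B)
    return rmsd


class TestKabsch:
    def test_identity_on_equal_sets(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        tf, rmsd = kabsch_superpose(P, P)
        assert rmsd < 1e-12
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(tf.translation, 0, atol=1e-10)

    def test_exact_rigid_case_recovered(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 3)) * 4
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        Q = P @ Rz.T + np.array([5.0, 0.0, 0.0])
        tf, rmsd = kabsch_superpose(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(tf.apply(Q), P, atol=1e-9)
        assert np.isclose(np.linalg.det(tf.rotation), 1.0)

    def test_reflection_excluded(self):
        # mirrored cloud cannot be matched by a proper rotation: rmsd > 0
        rng = np.random.default_rng(2)
        P = rng.normal(size=(20, 3))
        Q = P * np.array([1.0, 1.0, -1.0])
        tf, rmsd = kabsch_superpose(P, Q)
        assert np.isclose(np.linalg.det(tf.rotation), 1.0, atol=1e-9)
        assert rmsd > 0.1

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(3, 40))
            P = rng.normal(size=(n, 3)) * 5
            Q = rng.normal(size=(n, 3)) * 5
            _, r_svd = kabsch_superpose(P, Q)
            _, r_quat = quaternion_superpose(P, Q)
            assert abs(r_svd - r_quat) < 1e-8

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientAtomsError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_near_collinear_points_warn(self):
        t = np.linspace(0, 1, 10)
        P = np.column_stack([t, t, t]) + 1e-12
        with pytest.warns(UserWarning, match="collinear"):
            kabsch_superpose(P, P[::-1])

    def test_transform_algebra(self):
        rng = np.random.default_rng(4)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        from scipy.spatial.transform import Rotation

        tf = RigidTransform(Rotation.from_quat(q).as_matrix(), rng.normal(size=3))
        x = rng.normal(size=(5, 3))
        assert np.allclose(tf.inverse().apply(tf.apply(x)), x, atol=1e-12)
        assert np.allclose(tf.compose(tf.inverse()).apply(x), x, atol=1e-12)


class TestOverlapSuperposition:
    def test_exact_copy_gives_zero_rmsd(self, tube900, tube_plan):
        model, _ = tube900
        frags, _ = fragment_and_perturb(model, tube_plan, sigma=0.0, seed=5)
        overlap = tube_plan.overlaps()[0]
        sup = superpose_on_overlap(frags[0], frags[1], overlap)
        assert sup.rmsd < 1e-9
        assert sup.n_atoms == overlap[1] - overlap[0] + 1

    def test_noisy_overlap_rmsd_matches_closed_form(self, tube900, tube_plan):
        """Two copies with iid per-coordinate noise sigma differ by ~sigma*sqrt(6)
        after superposition (difference variance 2*sigma^2 per coordinate)."""
        model, _ = tube900
        sigma = 0.5
        expected = sigma * np.sqrt(6.0)
        rmsds = []
        for seed in range(30):
            frags, _ = fragment_and_perturb(model, tube_plan, sigma=sigma, seed=seed)
            sup = superpose_on_overlap(frags[0], frags[1], tube_plan.overlaps()[0])
            rmsds.append(sup.rmsd)
        mean = np.mean(rmsds)
        assert 0.9 * expected <= mean <= 1.05 * expected

    def test_shifted_numbering_raises_sequence_mismatch(self, tube900, tube_plan):
        model, _ = tube900
        frags, _ = fragment_and_perturb(model, tube_plan, sigma=0.0, seed=5)
        shifted = frags[1].copy()
        shifted.residue_number = shifted.residue_number + 1
        with pytest.raises((SequenceMismatchError, InsufficientAtomsError)):
            superpose_on_overlap(frags[0], shifted, tube_plan.overlaps()[0])

    def test_disjoint_fragments_rejected(self, tube900, tube_plan):
        model, _ = tube900
        frags, _ = fragment_and_perturb(model, tube_plan, sigma=0.0, seed=5)
        with pytest.raises(InsufficientAtomsError):
            superpose_on_overlap(frags[0], frags[2], (1, 10))


class TestAssemble:
    def test_noiseless_fragments_recover_ground_truth(self, tube900, tube_plan):
        model, _ = tube900
        frags, _ = fragment_and_perturb(model, tube_plan, sigma=0.0, seed=11)
        assembled, report = assemble(frags, tube_plan)
        assert report.total_residues == 900
        assert _rmsd_after_fit(model.coords, assembled.coords) < 1e-6

    def test_single_fragment_plan_is_identity(self, tube900):
        from megastitch import plan_fragments

        model, _ = tube900
        plan1 = plan_fragments(900, target_len=900, min_overlap=50, max_len=900)
        frags, _ = fragment_and_perturb(model, plan1, sigma=0.0, seed=2)
        assembled, report = assemble(frags, plan1)
        assert report.junction_rmsd == []
        assert np.allclose(assembled.coords, frags[0].coords)

    def test_noisy_assembly_close_to_truth_without_clashes(self, tube900, tube_plan):
        model, _ = tube900
        frags, _ = fragment_and_perturb(model, tube_plan, sigma=0.5, seed=1)
        assembled, report = assemble(frags, tube_plan)
        _, ca_t = model.ca_coords()
        _, ca_a = assembled.ca_coords()
        assert _rmsd_after_fit(ca_t, ca_a) < 1.5
        assert report.clash_count == 0

    def test_junction_rmsd_monotone_in_noise(self, tube900, tube_plan):
        model, _ = tube900
        sigmas = [0.0, 0.25, 0.5, 1.0]
        means = []
        for sigma in sigmas:
            vals = []
            for seed in (1, 2, 3):
                frags, _ = fragment_and_perturb(model, tube_plan, sigma=sigma, seed=seed)
                _, report = assemble(frags, tube_plan)
                vals.append(np.mean(report.junction_rmsd))
            means.append(np.mean(vals))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_residue_conservation_and_unique_source(self, tube900, tube_plan):
        model, _ = tube900
        frags, _ = fragment_and_perturb(model, tube_plan, sigma=0.3, seed=9)
        assembled, _ = assemble(frags, tube_plan)
        nums = assembled.residue_numbers()
        assert np.array_equal(nums, np.arange(1, 901))
        # every residue appears exactly once: spans partition the atom table
        spans = assembled.residue_index()
        assert sorted(spans) == list(range(1, 901))
        assert sum(s.stop - s.start for s in spans.values()) == len(assembled)

    def test_max_confidence_splice_prefers_high_confidence_side(self, tube900, tube_plan):
        model, _ = tube900
        frags, _ = fragment_and_perturb(model, tube_plan, sigma=0.0, seed=4)
        _, report_mid = assemble(frags, tube_plan, splice_rule="midpoint")
        _, report_conf = assemble(frags, tube_plan, splice_rule="max_confidence")
        assert report_conf.total_residues == 900
        # confidence ramps are symmetric within the overlap, so the balance
        # point stays inside the overlap interval
        for c, (a, b) in zip(report_conf.crossover_residues, tube_plan.overlaps()):
            assert a <= c <= b

    def test_fragment_count_mismatch_rejected(self, tube900, tube_plan):
        model, _ = tube900
        frags, _ = fragment_and_perturb(model, tube_plan, sigma=0.0, seed=4)
        with pytest.raises(ParameterError):
            assemble(frags[:2], tube_plan)


class TestClashReport:
    def test_ideal_tube_has_no_clashes(self, small_tube):
        model, _ = small_tube
        assert clash_report(model, cutoff=2.0) == []

    def test_pair_far_in_sequence_close_in_space(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        model = StructureModel(
            serial=[1, 2],
            atom_name=["CA", "CA"],
            residue_name=["ALA", "ALA"],
            chain_id=["A", "A"],
            residue_number=[1, 11],
            coords=coords,
            element=["C", "C"],
            confidence=[90.0, 90.0],
        )
        assert len(clash_report(model, cutoff=2.0)) == 1

    def test_bonded_neighbours_excluded(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        model = StructureModel(
            serial=[1, 2],
            atom_name=["CA", "CA"],
            residue_name=["ALA", "ALA"],
            chain_id=["A", "A"],
            residue_number=[1, 2],
            coords=coords,
            element=["C", "C"],
            confidence=[90.0, 90.0],
        )
        assert clash_report(model, cutoff=2.0) == []

    def test_matches_brute_force_on_compressed_tube(self, small_tube):
        model, _ = small_tube
        squeezed = model.copy()
        coords = squeezed.coords.copy()
        coords[:, 2] *= 0.1  # collapse helical turns onto each other
        squeezed.coords = coords
        fast = {(i, j) for i, j, _ in clash_report(squeezed, cutoff=2.0)}
        slow = brute_force_clashes(squeezed, cutoff=2.0)
        assert fast == slow and len(slow) > 0
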