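import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from megastitch import (
    MutationSpec,
    StructureModel,
    TubeParams,
    estimate_axis,
    extract_sequence,
    make_tube,
    mutation_blockage,
    radius_profile,
    rod_length,
    tunnel_summary,
)
from megastitch.errors import InsufficientAtomsError, ParameterError

from .oracles import brute_force_min_radius


def _straight_chain(n=120, spacing=3.8):
    z = np.arange(n) * spacing
    coords = np.column_stack([np.zeros(n), np.zeros(n), z])
    return StructureModel(
        serial=np.arange(1, n + 1),
        atom_name=np.array(["CA"] * n, dtype=object),
        residue_name=np.array(["ALA"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        residue_number=np.arange(1, n + 1),
        coords=coords,
        element=np.array(["C"] * n, dtype=object),
        confidence=np.full(n, 90.0),
    )


class TestAxis:
    def test_helical_tube_axis_lies_on_winding_axis(self, tube900):
        """Sliding-window centroids cancel the helical winding."""
        model, truth = tube900
        axis = estimate_axis(model)
        assert np.abs(axis.points[:, :2]).max() < 0.5
        assert axis.length > 0.9 * truth.axis.length

    def test_straight_rod_axis_is_straight(self):
        model = _straight_chain()
        axis = estimate_axis(model, window=10)
        assert np.abs(axis.points[:, :2]).max() < 1e-9

    def test_too_few_residues_rejected(self):
        with pytest.raises(InsufficientAtomsError):
            estimate_axis(_straight_chain(n=30), window=50)

    def test_scrambled_coordinates_flagged(self, tube900):
        model, _ = tube900
        scrambled = model.copy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(900)
        # shuffle whole residues while keeping sequential numbering
        coords = scrambled.coords.reshape(900, 2, 3)[perm].reshape(1800, 3)
        scrambled.coords = coords
        with pytest.warns(UserWarning, match="tortuosity"):
            estimate_axis(scrambled)


class TestRadiusProfile:
    def test_ideal_cylinder_radius_is_wall_minus_vdw(self, tube900):
        """Wall carbons at 7.7 Å from the axis leave a 6.0 Å maximal ball."""
        model, truth = tube900
        profile = radius_profile(model, truth.axis)
        interior = (profile.s > 15) & (profile.s < truth.axis.length - 15)
        assert np.all(np.abs(profile.radius[interior] - 6.0) < 0.1)

    def test_hydrophobic_lumen_lining(self, tube900):
        model, truth = tube900
        profile = radius_profile(model, truth.axis)
        interior = (profile.s > 15) & (profile.s < truth.axis.length - 15)
        assert np.all(profile.mean_hydropathy[interior] > 3.0)

    def test_matches_brute_force_minimum_exactly(self, small_tube):
        model, truth = small_tube
        profile = radius_profile(model, truth.axis)
        for i in range(0, len(profile.s), 7):
            oracle = max(0.0, brute_force_min_radius(model, profile.points[i]))
            assert profile.radius[i] == pytest.approx(oracle, abs=1e-12)

    def test_solid_rod_has_no_tunnel(self):
        model = _straight_chain()
        axis = estimate_axis(model, window=10)
        profile = radius_profile(model, axis)
        # axis stations sit on/between atoms: radii collapse to ~0
        assert profile.radius.max() < 0.5
        assert profile.blocked.any()
        summary = tunnel_summary(profile)
        assert not summary.continuous


class TestRodLength:
    def test_two_point_extent(self):
        model = _straight_chain(n=2, spacing=300.0)
        assert rod_length(model) == pytest.approx(300.0)

    def test_recovers_generator_length(self, tube900):
        model, _ = tube900
        assert rod_length(model) == pytest.approx(300.0, rel=0.02)

    def test_rigid_motion_invariance(self, tube900):
        model, _ = tube900
        rng = np.random.default_rng(8)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        moved = model.transformed(Rotation.from_quat(q).as_matrix(), rng.normal(size=3) * 50)
        assert rod_length(moved) == pytest.approx(rod_length(model), abs=1e-6)
        axis_m = estimate_axis(moved)
        profile_m = radius_profile(moved, axis_m)
        summary_m = tunnel_summary(profile_m)
        axis0 = estimate_axis(model)
        summary0 = tunnel_summary(radius_profile(model, axis0))
        assert summary_m.min_radius == pytest.approx(summary0.min_radius, abs=1e-6)
        assert summary_m.continuous == summary0.continuous


class TestTunnelSummary:
    def test_open_tube_is_continuous(self, tube900):
        model, truth = tube900
        summary = tunnel_summary(radius_profile(model, truth.axis))
        assert summary.continuous
        assert summary.min_radius == pytest.approx(6.0, abs=0.5)

    def test_blocking_atom_breaks_continuity(self, tube900):
        model, truth = tube900
        blocked = model.copy()
        mid = np.array([0.0, 0.0, 150.0])
        plug = StructureModel(
            serial=[len(model) + 1],
            atom_name=["CA"],
            residue_name=["ALA"],
            chain_id=["A"],
            residue_number=[901],
            coords=mid.reshape(1, 3),
            element=["C"],
            confidence=[90.0],
        )
        blocked = StructureModel.concat([blocked, plug])
        summary = tunnel_summary(radius_profile(blocked, truth.axis))
        assert not summary.continuous
        assert abs(summary.argmin_s - 150.0) <= 2.0

    def test_probe_larger_than_lumen_not_continuous(self, tube900):
        model, truth = tube900
        summary = tunnel_summary(radius_profile(model, truth.axis), probe=8.0)
        assert not summary.continuous


@pytest.fixture(scope="module")
def glycine_tube():
    params = TubeParams(
        n_res=300, length=150.0, inner_wall_radius=7.7, lumen_aa=("G",), seed=3
    )
    return make_tube(params)


class TestMutationBlockage:
    def test_identity_substitution_is_noop(self, glycine_tube):
        model, truth = glycine_tube
        table = mutation_blockage(model, MutationSpec(151, "G", "G"), axis=truth.axis)
        assert np.all(table["delta_radius"].to_numpy() == 0.0)

    def test_lumen_facing_gly_to_glu_narrows_tunnel(self, glycine_tube):
        """A glutamate side chain on a lumen wall glycine protrudes inward."""
        model, truth = glycine_tube
        table = mutation_blockage(model, MutationSpec(151, "G", "E"), axis=truth.axis)
        assert table["delta_radius"].min() < -0.5
        assert np.all(table["delta_radius"].to_numpy() <= 1e-12)
        assert table["s"].between(150.0 / 2 - 17, 150.0 / 2 + 17).all()

    def test_outward_facing_substitution_leaves_lumen(self, glycine_tube):
        model, truth = glycine_tube
        seq = extract_sequence(model)
        resnum = 152  # odd index -> outward-facing
        table = mutation_blockage(
            model, MutationSpec(resnum, seq[resnum - 1], "E"), axis=truth.axis
        )
        assert abs(table["delta_radius"].min()) < 0.05

    def test_wrong_wildtype_rejected(self, glycine_tube):
        model, truth = glycine_tube
        with pytest.raises(ParameterError, match="numbering"):
            mutation_blockage(model, MutationSpec(151, "A", "E"), axis=truth.axis)

    def test_parse_compact_notation(self):
        spec = MutationSpec.parse("G200E")
        assert (spec.residue_number, spec.from_aa, spec.to_aa) == (200, "G", "E")
        with pytest.raises(ParameterError):
            MutationSpec.parse("G2OOE")
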