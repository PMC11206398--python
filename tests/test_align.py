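"""Superposition correctness: oracle equivalence and rigid-motion invariance."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tkispec import (
    AtomMapping,
    DegenerateGeometryError,
    Geometry,
    ValidationError,
    crystal_vs_minimum_rmsd,
    kabsch_superpose,
    plane_anchor_align,
    rmsd_between,
)
from tkispec.ensembles import CompoundEnsemble, ConformerRecord, Role

RNG = np.random.default_rng(2024)


def random_rotation(rng=RNG):
    return Rotation.from_euler("zyx", rng.uniform(-180, 180, 3), degrees=True).as_matrix()


def brute_force_rmsd(a, b, coarse_deg=15.0):
    """Oracle: minimize RMSD over rotations by grid scan + local refinement.

    Scans Euler angles on a coarse grid, then polishes the best candidates
    with Nelder-Mead. Translation is optimal at matched centroids for any
    rotation, so both sets are centred first.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return np.sqrt(np.mean(np.sum((b @ R.T - a) ** 2, axis=1)))

    grid = np.arange(-180.0, 180.0, coarse_deg)
    mid = np.arange(-90.0, 90.1, coarse_deg)
    candidates = sorted(
        (cost(ang), ang) for ang in itertools.product(grid, mid, grid)
    )[:5]
    best = np.inf
    for _, ang in candidates:
        res = minimize(cost, ang, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-12})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_structures_have_zero_rmsd_identity_rotation(self, toy_geometry):
        result = kabsch_superpose(toy_geometry, toy_geometry)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance(self, toy_geometry):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = toy_geometry.coords @ Rz.T + np.array([3.0, -1.0, 2.5])
        result = kabsch_superpose(toy_geometry.coords, moved)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_of_rmsd(self, toy_geometry):
        other = toy_geometry.coords + RNG.normal(0, 0.1, toy_geometry.coords.shape)
        r_ab = kabsch_superpose(toy_geometry.coords, other).rmsd
        r_ba = kabsch_superpose(other, toy_geometry.coords).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_rotation_is_proper_orthogonal(self, toy_geometry):
        other = toy_geometry.coords + RNG.normal(0, 0.2, toy_geometry.coords.shape)
        R = kabsch_superpose(toy_geometry.coords, other).rotation
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("n_atoms", [4, 5, 6])
    def test_matches_brute_force_rotation_oracle(self, n_atoms):
        """Kabsch RMSD equals exhaustive rotation search to 1e-3 Å on toys."""
        rng = np.random.default_rng(100 + n_atoms)
        a = rng.normal(0, 1.5, (n_atoms, 3))
        b = a @ random_rotation(rng).T + rng.normal(0, 0.15, (n_atoms, 3))
        ours = kabsch_superpose(a, b).rmsd
        oracle = brute_force_rmsd(a, b)
        assert ours == pytest.approx(oracle, abs=1e-3)
        # cross-check against the scipy implementation as well
        _, rssd = Rotation.align_vectors(
            a - a.mean(axis=0), b - b.mean(axis=0)
        )
        assert ours == pytest.approx(rssd / np.sqrt(n_atoms), abs=1e-9)

    def test_perturbed_single_atom_toy_matches_oracle(self, toy_geometry):
        b = toy_geometry.coords.copy()
        b[2] += [0.3, -0.2, 0.15]
        ours = kabsch_superpose(toy_geometry.coords, b).rmsd
        assert ours == pytest.approx(brute_force_rmsd(toy_geometry.coords, b), abs=1e-3)

    def test_reflection_required_is_flagged_and_proper_branch_taken(self):
        a = np.array(
            [[0.0, 0, 0], [1.5, 0, 0], [0.3, 1.2, 0], [0.2, 0.4, 1.1]]
        )
        b = a.copy()
        b[:, 2] *= -1  # mirror image
        result = kabsch_superpose(a, b)
        assert result.reflection_suppressed
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)
        assert result.rmsd > 0.1

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line + 1.0)

    def test_mapping_needs_three_pairs(self):
        with pytest.raises(ValidationError):
            AtomMapping(((0, 0), (1, 1)))


class TestPlaneAnchor:
    def test_postconditions_on_random_structures(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 2.0, (8, 3))
        out = plane_anchor_align(coords, (0, 1, 2))
        np.testing.assert_allclose(out[0], 0.0, atol=1e-9)
        assert out[1, 1] == pytest.approx(0.0, abs=1e-9)
        assert out[1, 0] > 0
        np.testing.assert_allclose(out[[0, 1, 2], 2], 0.0, atol=1e-9)

    def test_already_anchored_structure_is_fixed_point(self):
        coords = np.array(
            [[0.0, 0, 0], [1.4, 0, 0], [0.7, 1.2, 0], [0.5, 0.5, 1.0]]
        )
        out = plane_anchor_align(coords, (0, 1, 2))
        np.testing.assert_allclose(out, coords, atol=1e-9)

    def test_rigid_motion_removed_by_anchoring(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(0, 2.0, (7, 3))
        moved = coords @ random_rotation(rng).T + [4.0, -2.0, 1.0]
        np.testing.assert_allclose(
            plane_anchor_align(coords, (0, 1, 2)),
            plane_anchor_align(moved, (0, 1, 2)),
            atol=1e-8,
        )

    def test_anchor_restricted_kabsch_bounds_plane_anchored_rmsd(self):
        # anchored-frame comparison can never beat the optimal Kabsch fit
        rng = np.random.default_rng(13)
        a = rng.normal(0, 2.0, (9, 3))
        b = a + rng.normal(0, 0.3, a.shape)
        anchored = rmsd_between(
            plane_anchor_align(a, (0, 1, 2)), plane_anchor_align(b, (0, 1, 2))
        )
        optimal = kabsch_superpose(a, b).rmsd
        assert anchored >= optimal - 1e-9

    def test_collinear_anchors_rejected(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [0, 1, 0.5]])
        with pytest.raises(DegenerateGeometryError):
            plane_anchor_align(coords, (0, 1, 2))


def _two_structure_ensemble(geom_a: Geometry, geom_b: Geometry, atom_map=None):
    return CompoundEnsemble(
        substituent="X",
        conformers=(
            ConformerRecord("gm", -100.0, 1.0, geom_a, Role.GLOBAL_MINIMUM),
            ConformerRecord("crystal", -99.99, 1.0, geom_b, Role.CRYSTAL_REFERENCE),
        ),
        atom_map=atom_map or {},
    )


class TestCrystalVsMinimum:
    def test_identical_geometries_give_zero(self, toy_geometry):
        ens = _two_structure_ensemble(toy_geometry, toy_geometry)
        assert crystal_vs_minimum_rmsd(ens) == pytest.approx(0.0, abs=1e-12)

    def test_named_anchor_resolution_through_atom_map(self, toy_geometry):
        ens = _two_structure_ensemble(
            toy_geometry, toy_geometry, atom_map={"C1": 0, "C4": 1, "C10": 2}
        )
        value = crystal_vs_minimum_rmsd(ens, anchors=("C1", "C4", "C10"))
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_missing_crystal_reference_rejected(self, toy_geometry):
        ens = CompoundEnsemble(
            substituent="X",
            conformers=(
                ConformerRecord("gm", -100.0, 1.0, toy_geometry, Role.GLOBAL_MINIMUM),
            ),
        )
        with pytest.raises(ValidationError, match="crystal"):
            crystal_vs_minimum_rmsd(ens)

    def test_heavy_atom_policy_ignores_hydrogens(self):
        symbols = ("C", "C", "C", "H")
        base = np.array(
            [[0.0, 0, 0], [1.4, 0, 0], [0.7, 1.2, 0], [2.0, 2.0, 2.0]]
        )
        moved = base.copy()
        moved[3] += 5.0  # only the hydrogen moves
        ens = _two_structure_ensemble(Geometry(symbols, base), Geometry(symbols, moved))
        assert crystal_vs_minimum_rmsd(ens, policy="heavy_atoms") == pytest.approx(
            0.0, abs=1e-9
        )
        assert crystal_vs_minimum_rmsd(ens, policy="all_atoms") > 0.5
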