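"""Superposition and conformational PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from polyion.chain import ChainSpec, Ensemble, Frame, poly_e
from polyion.generators import sample_saw_chain
from polyion.pca import align_frames, fit_pca, pc_bounding_area, project_onto


def spec_of(n):
    return ChainSpec(n, ("E",) * n, (-1.0,) * n)


def ensemble_from_coords(coords):
    n = coords.shape[1]
    frames = [Frame(chain_coords=coords[k], frame_index=k)
              for k in range(coords.shape[0])]
    return Ensemble(spec=spec_of(n), frames=frames)


def rigid_copies(base, n_frames, seed, mirror=False):
    rng = np.random.default_rng(seed)
    out = np.empty((n_frames, base.shape[0], 3))
    for k in range(n_frames):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-50, 50, 3)
        frame = base @ rot.T + shift
        if mirror:
            frame[:, 0] = -frame[:, 0]
        out[k] = frame
    return out


@pytest.fixture
def bent_chain():
    # non-degenerate reference conformation
    rng = np.random.default_rng(0)
    steps = rng.normal(size=(9, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([[0, 0, 0], np.cumsum(3.8 * steps, axis=0)])


class TestAlign:
    def test_rigid_transforms_collapse_to_one_structure(self, bent_chain):
        ens = ensemble_from_coords(rigid_copies(bent_chain, 6, seed=1))
        aligned = align_frames(ens).coordinates()
        for k in range(1, 6):
            np.testing.assert_allclose(aligned[k], aligned[0], atol=1e-8)

    def test_alignment_never_increases_rmsd(self, bent_chain):
        rng = np.random.default_rng(2)
        coords = rigid_copies(bent_chain, 8, seed=2)
        coords += rng.normal(0, 0.8, coords.shape)  # add internal motion
        ens = ensemble_from_coords(coords)
        aligned = align_frames(ens, reference="first_frame")
        ref_pre = coords[0] - coords[0].mean(axis=0)
        ref_post = aligned.coordinates()[0]
        for k in range(1, 8):
            pre = coords[k] - coords[k].mean(axis=0)
            rmsd_pre = np.sqrt(np.mean((pre - ref_pre) ** 2))
            rmsd_post = np.sqrt(
                np.mean((aligned.coordinates()[k] - ref_post) ** 2))
            assert rmsd_post <= rmsd_pre + 1e-9

    def test_mirror_image_not_matched(self, bent_chain):
        coords = np.stack([bent_chain,
                           rigid_copies(bent_chain, 1, 3, mirror=True)[0]])
        ens = ensemble_from_coords(coords)
        aligned = align_frames(ens, reference="first_frame").coordinates()
        # proper rotations only: the mirrored frame cannot be superposed
        rmsd = np.sqrt(np.mean((aligned[1] - aligned[0]) ** 2))
        assert rmsd > 0.5

    def test_collinear_reference_falls_back_with_warning(self):
        rod = np.zeros((3, 10, 3))
        rod[:, :, 0] = 3.8 * np.arange(10)
        ens = ensemble_from_coords(rod)
        with pytest.warns(UserWarning, match="collinear"):
            align_frames(ens, reference="mean_structure")


class TestFitPCA:
    def test_identical_frames_have_zero_eigenvalues(self, bent_chain):
        ens = ensemble_from_coords(np.repeat(bent_chain[None], 5, axis=0))
        res = fit_pca(ens)
        assert np.all(res.eigenvalues < 1e-18)

    def test_rank_one_displacement_recovered(self, bent_chain):
        shifts = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        coords = np.repeat(bent_chain[None], 5, axis=0)
        coords[:, 3, 2] += shifts          # one bead moves along z
        res = fit_pca(ensemble_from_coords(coords))
        assert res.eigenvalues[0] > 1e-6
        assert res.eigenvalues[1] < 1e-18
        scores = res.projections[:, 0]
        np.testing.assert_allclose(np.abs(scores), np.abs(shifts), atol=1e-8)

    def test_variance_conservation(self):
        ens = sample_saw_chain(poly_e(20, bead_diameter=3.8), 200, seed=6)
        aligned = align_frames(ens)
        res = fit_pca(aligned)
        coords = aligned.coordinates()
        flat = coords.reshape(200, -1)
        total_var = np.sum(np.var(flat, axis=0, ddof=1))
        assert np.sum(res.eigenvalues) == pytest.approx(total_var, rel=1e-8)

    def test_eigenvalues_sorted_components_orthonormal(self, bent_chain):
        rng = np.random.default_rng(4)
        coords = np.repeat(bent_chain[None], 30, axis=0)
        coords += rng.normal(0, 0.5, coords.shape)
        res = fit_pca(ensemble_from_coords(coords))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        gram = res.components @ res.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_sign_convention_reproducible(self, bent_chain):
        rng = np.random.default_rng(5)
        coords = np.repeat(bent_chain[None], 20, axis=0)
        coords += rng.normal(0, 0.5, coords.shape)
        r1 = fit_pca(ensemble_from_coords(coords))
        r2 = fit_pca(ensemble_from_coords(coords.copy()))
        np.testing.assert_array_equal(r1.components, r2.components)
        for k in range(r1.components.shape[0]):
            j = np.argmax(np.abs(r1.components[k]))
            assert r1.components[k, j] > 0


class TestProject:
    def test_self_projection_reproduces_scores(self, bent_chain):
        rng = np.random.default_rng(6)
        coords = np.repeat(bent_chain[None], 25, axis=0)
        coords += rng.normal(0, 0.4, coords.shape)
        ens = align_frames(ensemble_from_coords(coords))
        res = fit_pca(ens)
        again = project_onto(res, ens, align=False)
        np.testing.assert_allclose(again, res.projections, atol=1e-8)

    def test_mean_structure_projects_to_origin(self, bent_chain):
        rng = np.random.default_rng(7)
        coords = np.repeat(bent_chain[None], 25, axis=0)
        coords += rng.normal(0, 0.4, coords.shape)
        ens = align_frames(ensemble_from_coords(coords))
        res = fit_pca(ens)
        mean_ens = ensemble_from_coords(
            np.repeat(res.mean_structure[None], 2, axis=0))
        scores = project_onto(res, mean_ens, align=False)
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_bead_count_mismatch_rejected(self, bent_chain):
        ens = align_frames(ensemble_from_coords(
            rigid_copies(bent_chain, 5, seed=8)))
        res = fit_pca(ens)
        other = ensemble_from_coords(np.zeros((3, 7, 3)) +
                                     np.arange(7)[None, :, None])
        with pytest.raises(ValueError, match="mismatch"):
            project_onto(res, other)

    def test_halved_ensemble_score_variance_close_to_eigenvalues(self):
        ens = sample_saw_chain(poly_e(15, bead_diameter=3.8), 400, seed=9)
        aligned = align_frames(ens)
        res = fit_pca(aligned)
        half = Ensemble(spec=aligned.spec,
                        frames=aligned.frames[::2])
        scores = project_onto(res, half, align=False)
        for k in range(2):
            assert np.var(scores[:, k], ddof=1) == pytest.approx(
                res.eigenvalues[k], rel=0.35)


def test_bounding_area_reflects_spread():
    rng = np.random.default_rng(10)
    tight = rng.normal(0, 1.0, size=(500, 2))
    wide = rng.normal(0, 3.0, size=(500, 2))
    assert pc_bounding_area(wide) > pc_bounding_area(tight)
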