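"""Principal component analysis of aligned chain conformations.

Frames are first superposed (centroid removal + Kabsch proper rotation onto
a reference; the mean-structure reference is iterated: align, recompute the
mean, realign).  PCA is then an eigendecomposition of the covariance of the
flattened 3N coordinates.  Component signs are fixed so the
largest-magnitude loading of each component is positive, making scores
reproducible across runs.  A second ensemble (e.g. the neutral control
shown behind each panel) can be aligned to the same mean structure and
projected into the fitted component space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .chain import Ensemble, Frame

__all__ = ["PCAResult", "align_frames", "fit_pca", "project_onto",
           "pc_bounding_area"]


@dataclass
class PCAResult:
    mean_structure: np.ndarray          # (N, 3)
    components: np.ndarray              # (n_components, 3N), orthonormal rows
    eigenvalues: np.ndarray             # Å², non-increasing
    projections: np.ndarray             # (F, 2) scores on PC1/PC2
    explained_fraction: np.ndarray

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_fraction": self.explained_fraction.tolist(),
        }


def _kabsch(reference: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) minimizing RMSD of ``coords`` onto
    ``reference``; both inputs must be centred."""
    rot, _ = Rotation.align_vectors(reference, coords)
    return rot.as_matrix()


def _is_collinear(coords: np.ndarray, tol: float = 1e-8) -> bool:
    centred = coords - coords.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


def _align_to(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref_c = reference - reference.mean(axis=0)
    out = np.empty_like(coords)
    for k in range(coords.shape[0]):
        frame_c = coords[k] - coords[k].mean(axis=0)
        out[k] = frame_c @ _kabsch(ref_c, frame_c).T
    return out


def align_frames(ensemble: Ensemble,
                 reference: str = "mean_structure") -> Ensemble:
    """Remove rigid-body motion: translate each frame to zero centroid and
    rotate it onto the reference by the optimal proper rotation."""
    if ensemble.n_frames < 2:
        raise ValueError("alignment requires at least 2 frames")
    if reference not in ("mean_structure", "first_frame"):
        raise ValueError(f"unknown reference {reference!r}")
    coords = ensemble.coordinates()
    if reference == "mean_structure":
        aligned = _align_to(coords, coords[0])
        mean = aligned.mean(axis=0)
        if _is_collinear(mean):
            warnings.warn(
                "mean structure is degenerate (collinear); "
                "falling back to first-frame reference", stacklevel=2
            )
            aligned = _align_to(coords, coords[0])
        else:
            aligned = _align_to(coords, mean)
    else:
        aligned = _align_to(coords, coords[0])
    frames = [
        Frame(chain_coords=aligned[k], ions=list(fr.ions),
              box_edge=fr.box_edge, frame_index=fr.frame_index,
              frame_spacing=fr.frame_spacing)
        for k, fr in enumerate(ensemble.frames)
    ]
    meta = dict(ensemble.metadata)
    meta["aligned"] = reference
    return Ensemble(spec=ensemble.spec, salt=ensemble.salt, frames=frames,
                    metadata=meta)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for k in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


def fit_pca(aligned: Ensemble, n_components: int | None = None) -> PCAResult:
    """Eigendecomposition of the covariance of flattened aligned coordinates.

    Eigenvalues use the unbiased (1/(F−1)) normalization; their sum equals
    the total variance of the aligned coordinates.
    """
    if aligned.n_frames < 3:
        raise ValueError("PCA requires at least 3 frames")
    coords = aligned.coordinates()
    f = coords.shape[0]
    flat = coords.reshape(f, -1)
    mean_flat = flat.mean(axis=0)
    centred = flat - mean_flat
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s ** 2 / (f - 1)
    if n_components is not None:
        vt = vt[:n_components]
        eigenvalues = eigenvalues[:n_components]
    components = _fix_signs(vt)
    scores2 = centred @ components[:2].T if components.shape[0] >= 2 \
        else centred @ components.T
    total = float(np.sum(centred ** 2) / (f - 1))
    explained = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PCAResult(
        mean_structure=mean_flat.reshape(-1, 3),
        components=components, eigenvalues=eigenvalues,
        projections=scores2, explained_fraction=explained,
    )


def project_onto(pca: PCAResult, other: Ensemble,
                 align: bool = True) -> np.ndarray:
    """Scores of another ensemble's frames on the fitted PC1/PC2.

    With ``align=True`` (default) each frame is first superposed onto the
    PCA mean structure.
    """
    n = pca.mean_structure.shape[0]
    if other.spec.n_residues != n:
        raise ValueError(
            f"bead-count mismatch: PCA fitted on {n}, ensemble has "
            f"{other.spec.n_residues}"
        )
    coords = other.coordinates()
    if align:
        coords = _align_to(coords, pca.mean_structure)
    flat = coords.reshape(coords.shape[0], -1)
    centred = flat - pca.mean_structure.reshape(-1)
    return centred @ pca.components[:2].T


def pc_bounding_area(scores: np.ndarray, lo: float = 2.5,
                     hi: float = 97.5) -> float:
    """Robust PC1–PC2 bounding-box area (percentile span product), used to
    compare how much conformational space two conditions occupy."""
    span1 = np.percentile(scores[:, 0], hi) - np.percentile(scores[:, 0], lo)
    span2 = np.percentile(scores[:, 1], hi) - np.percentile(scores[:, 1], lo)
    return float(span1 * span2)
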