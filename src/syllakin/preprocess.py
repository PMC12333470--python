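"""Keypoint preprocessing: confidence gating, egocentric alignment, PCA.

Turns a :class:`~syllakin.synthetic.KeypointRecording` into the observation
sequence of the segmentation model: low-confidence keypoints are
interpolated, each frame is translated to its centroid and rotated to a
canonical heading (tail_base -> nose along +x), and the flattened aligned
poses are projected onto a small number of principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from syllakin.synthetic import KeypointRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PoseSeries",
    "PCAModel",
    "gate_and_interpolate",
    "egocentric_align",
    "fit_pca",
    "transform_pca",
]


@dataclass
class PoseSeries:
    """Egocentrically aligned poses plus the arena-frame centroid track.

    ``aligned_coords`` has the centroid at the origin and the
    tail_base -> nose axis along +x in every frame.
    """

    body_parts: tuple
    aligned_coords: np.ndarray  # (frames, parts, 2), mm
    centroid_track: np.ndarray  # (frames, 2), mm, arena frame
    heading: np.ndarray  # (frames,), rad
    fps: float

    @property
    def n_frames(self) -> int:
        return self.aligned_coords.shape[0]

    def flatten(self) -> np.ndarray:
        """Flattened (frames, 2 * parts) feature matrix for PCA."""
        return self.aligned_coords.reshape(self.n_frames, -1)


@dataclass
class PCAModel:
    """Fitted PCA: mean, orthonormal components, explained-variance fractions."""

    mean: np.ndarray  # (n_features,)
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    n_components: int


def gate_and_interpolate(rec: KeypointRecording, likelihood_threshold: float = 0.9) -> KeypointRecording:
    """Replace low-confidence keypoints by linear interpolation in time.

    Interior gaps are interpolated per part and coordinate between the nearest
    confident frames; leading/trailing gaps take the nearest confident value.
    Likelihoods of filled frames are set to the threshold. A part with no
    confident frame at all is unrecoverable and raises.
    """
    if not 0.0 <= likelihood_threshold <= 1.0:
        raise ValueError("likelihood_threshold must be in [0, 1]")
    coords = rec.coords.copy()
    lik = rec.likelihood.copy()
    n_frames = rec.n_frames
    t = np.arange(n_frames)
    for p, part in enumerate(rec.body_parts):
        good = lik[:, p] >= likelihood_threshold
        if not good.any():
            raise ValueError(f"body part {part!r} has no frame above the likelihood threshold")
        if good.all():
            continue
        for c in range(2):
            # np.interp clamps to edge values, which is the nearest-confident rule
            coords[~good, p, c] = np.interp(t[~good], t[good], coords[good, p, c])
        lik[~good, p] = likelihood_threshold
    return KeypointRecording(
        body_parts=rec.body_parts,
        coords=coords,
        likelihood=lik,
        fps=rec.fps,
        arena_size=rec.arena_size,
    )


def egocentric_align(rec: KeypointRecording, front: str = "nose", back: str = "tail_base") -> PoseSeries:
    """Translate each frame to its centroid and rotate ``back -> front`` onto +x.

    The centroid is the unweighted mean of all tracked parts. Frames where the
    two heading parts coincide reuse the previous frame's heading (first
    frame: 0) and are logged.
    """
    parts = list(rec.body_parts)
    if front not in parts or back not in parts:
        raise ValueError(f"body parts must include {front!r} and {back!r}")
    i_front, i_back = parts.index(front), parts.index(back)

    centroid = rec.coords.mean(axis=1)
    centered = rec.coords - centroid[:, None, :]
    axis = centered[:, i_front, :] - centered[:, i_back, :]
    norms = np.hypot(axis[:, 0], axis[:, 1])
    heading = np.arctan2(axis[:, 1], axis[:, 0])
    bad = norms < 1e-12
    if bad.any():
        logger.warning("%d frame(s) with coincident %s/%s; reusing previous heading", bad.sum(), front, back)
        for idx in np.flatnonzero(bad):
            heading[idx] = heading[idx - 1] if idx > 0 else 0.0

    cos_h, sin_h = np.cos(heading), np.sin(heading)
    # rotate by -heading
    rot = np.empty((rec.n_frames, 2, 2))
    rot[:, 0, 0] = cos_h
    rot[:, 0, 1] = sin_h
    rot[:, 1, 0] = -sin_h
    rot[:, 1, 1] = cos_h
    aligned = np.einsum("tij,tpj->tpi", rot, centered)
    return PoseSeries(
        body_parts=rec.body_parts,
        aligned_coords=aligned,
        centroid_track=centroid,
        heading=heading,
        fps=rec.fps,
    )


def fit_pca(pose_batches, n_components: int = 5) -> PCAModel:
    """Fit PCA on flattened aligned poses pooled over sessions."""
    if isinstance(pose_batches, PoseSeries):
        pose_batches = [pose_batches]
    X = np.concatenate([p.flatten() for p in pose_batches], axis=0)
    if n_components > X.shape[1]:
        raise ValueError(f"n_components={n_components} exceeds n_features={X.shape[1]}")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more pooled frames than features to fit PCA")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PCAModel(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=n_components,
    )


def transform_pca(model: PCAModel, pose: PoseSeries) -> np.ndarray:
    """Project a pose series onto the fitted components -> (frames, n_components)."""
    X = pose.flatten()
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(f"feature dimension {X.shape[1]} does not match model ({model.mean.shape[0]})")
    return (X - model.mean) @ model.components.T
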