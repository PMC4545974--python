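"""Rigid-body head-motion correction.

Optically tracked lip markers move both because the lips move and because
the head moves. With at least three non-collinear head-mounted reference
markers, each frame's head pose can be estimated as the least-squares rigid
transform (rotation + translation, no scaling) aligning that frame's head
markers onto their configuration at a reference frame; applying the inverse
pose to the lip markers expresses lip motion relative to the skull.

The per-frame fit is the classic SVD superposition (Kabsch) solution,
vectorized over frames with batched 3x3 SVDs. The head-frame axes inherit
the lab axes at the reference frame, so "superior-inferior" remains lab +z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InputError
from .io import MarkerRecording
from .preprocess import Trajectory

__all__ = ["RigidTransformSeries", "estimate_head_transforms", "project_lip_trajectory"]

_COLLINEARITY_TOL = 1e-8


@dataclass
class RigidTransformSeries:
    """Per-frame rigid transforms mapping lab coordinates to head coordinates.

    ``rotations[i] @ x + translations[i]`` maps lab-frame point ``x`` at
    frame ``i`` into the head frame anchored at the reference frame.
    ``residual_rms`` holds the per-frame RMS fit residual in mm — a
    diagnostic for non-rigid marker motion.
    """

    rotations: np.ndarray  # (n_frames, 3, 3)
    translations: np.ndarray  # (n_frames, 3)
    residual_rms: np.ndarray  # (n_frames,)
    reference_frame_index: int

    def __post_init__(self) -> None:
        if self.rotations.shape[0] != self.translations.shape[0]:
            raise InputError("rotation/translation length mismatch")

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(n_frames, 3)`` point series into the head frame."""
        return np.einsum("nij,nj->ni", self.rotations, points) + self.translations


def _head_marker_matrix(rec: MarkerRecording) -> np.ndarray:
    names = rec.head_markers
    if len(names) < 3:
        raise GeometryError("need >= 3 head markers")
    return np.stack([rec.markers[m] for m in names], axis=1)  # (n_frames, k, 3)


def estimate_head_transforms(
    rec: MarkerRecording, reference_frame_index: int = 0
) -> RigidTransformSeries:
    """Estimate per-frame rigid transforms aligning head markers to a reference frame.

    For each frame the returned rotation R and translation t minimise
    ``sum_k || R p_k + t - q_k ||^2`` where ``p_k`` are that frame's head
    markers and ``q_k`` their positions at ``reference_frame_index``.

    Raises
    ------
    GeometryError
        If the reference-frame head markers are (near-)collinear, which
        leaves rotation about the marker axis unconstrained.
    """
    heads = _head_marker_matrix(rec)  # (n, k, 3)
    n = heads.shape[0]
    if not 0 <= reference_frame_index < n:
        raise InputError(f"reference_frame_index {reference_frame_index} out of range")
    ref = heads[reference_frame_index]  # (k, 3)
    ref_centroid = ref.mean(axis=0)
    ref_c = ref - ref_centroid

    # collinearity check: second singular value of the centred reference set
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] <= _COLLINEARITY_TOL * max(sv[0], 1.0):
        raise GeometryError("head markers are collinear; head pose is under-determined")

    centroids = heads.mean(axis=1)  # (n, 3)
    centred = heads - centroids[:, None, :]
    # cross-covariance per frame: H_i = sum_k p_ck^T q_ck  -> (n, 3, 3)
    H = np.einsum("nki,kj->nij", centred, ref_c)
    U, S, Vt = np.linalg.svd(H)
    # proper rotation: flip the smallest singular direction if det < 0
    det = np.linalg.det(np.einsum("nij,njk->nik", U, Vt))
    D = np.repeat(np.eye(3)[None, :, :], n, axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("nij,njk,nkl->nli", U, D, Vt)  # (V D U^T): maps frame -> reference
    t = ref_centroid - np.einsum("nij,nj->ni", R, centroids)

    fitted = np.einsum("nij,nkj->nki", R, heads) + t[:, None, :]
    resid = fitted - ref[None, :, :]
    rms = np.sqrt((resid**2).sum(axis=2).mean(axis=1))
    return RigidTransformSeries(
        rotations=R,
        translations=t,
        residual_rms=rms,
        reference_frame_index=reference_frame_index,
    )


def project_lip_trajectory(
    rec: MarkerRecording, transforms: RigidTransformSeries, marker: str
) -> Trajectory:
    """Superior-inferior (z) lip displacement in the head frame, in mm.

    The lip marker is mapped through the per-frame transforms and its z
    component is returned relative to its own position at the reference
    frame, so a lip rigidly attached to the head yields a constant zero.
    """
    if marker not in rec.markers:
        raise InputError(f"unknown marker {marker!r}")
    if transforms.n_frames != rec.n_frames:
        raise InputError("transform series length does not match recording")
    in_head = transforms.apply(rec.markers[marker])
    z = in_head[:, 2]
    return Trajectory(
        samples=z - z[transforms.reference_frame_index],
        sample_rate=rec.sample_rate,
        label=marker,
    )
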