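"""The two patient-registration methods and the image-fusion transform.

Automatic registration
    A fiducial matrix with radio-opaque and tracked markers sits in the
    scan volume.  Two paired-point (absolute-orientation) fits are chained:
    image -> matrix from the radio-opaque marker observations in the CBCT,
    and matrix -> patient reference from the tracked marker observations.
    Their composition is the image -> patient-reference registration.

Surface matching
    The surgeon digitizes three orientation landmarks (right, left, center)
    and 17 points spread over the exposed posterior surface.  The landmark
    triplet seeds a paired-point fit against the model landmarks; a
    point-to-surface ICP against the segmented bone model then refines it.
    The commercial algorithm's internals are undisclosed; plain
    least-squares ICP with exact point-to-triangle correspondences is the
    stand-in here.

Image fusion
    The rigid alignment of the intraoperative CBCT to the preoperative CT
    is done by intensity registration in the clinical software.  Image
    processing is out of scope, so the fusion transform is modelled as the
    ground-truth frame chain perturbed by a small random rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._mesh import TriangleMesh
from .transforms import (
    PointSet,
    RigidTransform,
    _as_rng,
    _rotation_from_axis_angle,
    apply,
    compose,
    invert,
    relabel,
)

__all__ = [
    "RegistrationError",
    "MissingObservationError",
    "SurfaceMatchResult",
    "paired_point_register",
    "estimate_uair_transform",
    "surface_match_register",
    "fusion_transform",
]


class RegistrationError(ValueError):
    """Degenerate or invalid registration input."""


class MissingObservationError(RegistrationError):
    """Marker observations absent (e.g. matrix not visible in the scan).

    Signals a dataset that the study would exclude for image quality or
    missing data, rather than a programming error.
    """


def _kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form least-squares rotation+translation mapping source→target.

    Proper rotation is enforced: if the unconstrained optimum is a
    reflection, the singular direction with the smallest singular value is
    flipped (standard remedy).
    """
    src_c = source.mean(axis=0)
    tgt_c = target.mean(axis=0)
    H = (target - tgt_c).T @ (source - src_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = tgt_c - R @ src_c
    return R, t


def paired_point_register(
    source_pts: PointSet, target_pts: PointSet
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of labelled point correspondences.

    Minimizes sum ||T(source_i) - target_i||^2 over proper rigid motions
    (Kabsch/Horn absolute orientation).  Correspondence is by label, so the
    row order of the two sets need not agree.

    Returns
    -------
    (transform, fre_mm)
        ``transform`` maps ``source_pts.frame`` to ``target_pts.frame``;
        ``fre_mm`` is the RMS fiducial registration residual.
    """
    if len(source_pts) < 3:
        raise RegistrationError("paired-point registration needs >= 3 points")
    tgt = target_pts.reorder_like(source_pts)
    src = source_pts.coordinates
    # collinearity: second singular value of the centred configuration
    for pts in (src, tgt.coordinates):
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] < 1e-6:
            raise RegistrationError("fiducial configuration is collinear")
    R, t = _kabsch(src, tgt.coordinates)
    transform = RigidTransform(R, t, source_pts.frame, target_pts.frame)
    resid = transform.transform_points(src) - tgt.coordinates
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, fre


def estimate_uair_transform(record) -> RigidTransform:
    """Automatic registration estimate: image -> patient reference.

    Chains the two paired-point fits of the fiducial matrix: the
    radio-opaque markers localized in the CBCT give image -> matrix, the
    tracked markers give matrix -> patient reference.

    Raises
    ------
    MissingObservationError
        If either marker observation set is absent (the dataset would be
        excluded for image quality / missing data).
    """
    if record.air_obs_image is None or record.air_obs_ref is None:
        raise MissingObservationError(
            "fiducial matrix observations missing; dataset not registrable"
        )
    image_to_matrix, _ = paired_point_register(record.air_obs_image, record.air_markers_local)
    matrix_to_ref, _ = paired_point_register(record.air_markers_local, record.air_obs_ref)
    return compose(matrix_to_ref, image_to_matrix)


@dataclass(frozen=True)
class SurfaceMatchResult:
    """Outcome of landmark-initialized surface matching."""

    transform: RigidTransform      # model frame -> pick frame (preop_ct -> patient_ref)
    residual_mm: float             # final RMS point-to-surface residual
    n_iter: int
    converged: bool
    residual_history: tuple        # RMS residual after init and each update

    def to_dict(self) -> dict:
        return {
            "method": "surface_matching",
            "transform": self.transform.to_dict(),
            "residual_mm": self.residual_mm,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def surface_match_register(
    landmark_picks: PointSet,
    surface_picks: PointSet,
    model_surface: TriangleMesh,
    model_landmarks: PointSet,
    max_iter: int = 100,
    tol_mm: float = 1e-4,
) -> SurfaceMatchResult:
    """Landmark-seeded point-to-surface ICP against the bone model.

    The three landmark picks are paired-point registered to the model
    landmarks to seed the pose; ICP then alternates exact closest points on
    the model mesh with closed-form rigid updates until the RMS residual
    changes by less than ``tol_mm`` or ``max_iter`` iterations elapse.
    Non-convergence is reported in the result, not raised.

    Returns the estimated model-frame -> pick-frame transform (with the
    study's frames, preop_ct -> patient_ref).
    """
    if len(landmark_picks) != 3 or len(model_landmarks) != 3:
        raise RegistrationError("exactly 3 landmark picks/model landmarks required")
    if len(surface_picks) < 10:
        raise RegistrationError("need >= 10 surface picks")
    if surface_picks.frame != landmark_picks.frame:
        raise RegistrationError("landmark and surface picks must share a frame")

    T, _ = paired_point_register(model_landmarks, landmark_picks)  # model -> picks

    picks = surface_picks.coordinates
    model_frame = model_landmarks.frame

    def residual_of(Tcur: RigidTransform) -> tuple[float, np.ndarray]:
        # picks mapped into the model frame, matched against the mesh
        inv = invert(Tcur)
        local = inv.transform_points(picks)
        closest, dist, _ = model_surface.closest_points(local)
        return float(np.sqrt(np.mean(dist**2))), closest

    rms, corr = residual_of(T)
    history = [rms]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        corr_set = PointSet(corr, surface_picks.labels, model_frame)
        pick_set = PointSet(picks, surface_picks.labels, surface_picks.frame)
        T, _ = paired_point_register(corr_set, pick_set)
        rms_new, corr = residual_of(T)
        history.append(rms_new)
        if abs(history[-2] - rms_new) < tol_mm:
            converged = True
            break
    return SurfaceMatchResult(T, history[-1], n_iter, converged, tuple(history))


def fusion_transform(scene, noise, rng_seed) -> RigidTransform:
    """Simulated image-fusion transform: intraop CBCT -> preop CT.

    Ground-truth frame chain perturbed by a small random rigid motion
    (translation iid N(0, sigma_mm^2) per axis; rotation about a uniform
    random axis by an angle ~ N(0, sigma_deg^2)).  Deterministic per seed.
    """
    sigma_mm, sigma_deg = noise.fusion_noise_sigma_mm_deg
    truth = compose(invert(scene.T_preop_to_tracker), scene.T_image_to_tracker)
    rng = _as_rng(rng_seed)
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-12:
        axis = rng.normal(size=3)
    angle = np.radians(rng.normal(0.0, sigma_deg)) if sigma_deg > 0 else 0.0
    R = _rotation_from_axis_angle(axis, angle)
    t = rng.normal(0.0, sigma_mm, size=3) if sigma_mm > 0 else np.zeros(3)
    delta = RigidTransform(R, t, "preop_ct", "preop_ct")
    return compose(delta, truth)
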