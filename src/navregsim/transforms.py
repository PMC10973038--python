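"""Rigid-body transform algebra with explicit coordinate-frame bookkeeping.

Every quantity in the navigation error chain lives in one of five frames:

* ``intraop_cbct`` — the intraoperative cone-beam CT image volume,
* ``preop_ct``     — the preoperative CT image volume,
* ``matrix``       — the local frame of the fiducial registration matrix,
* ``patient_ref``  — the dynamic reference frame clamped to the spine,
* ``tracker``      — the optical tracking camera (simulation world frame).

A :class:`RigidTransform` maps points expressed in ``source_frame`` to the
same physical points expressed in ``target_frame``.  Composition is only
allowed when the inner frame labels agree; mischained transforms are the
single biggest hazard in a registration error pipeline, so a mismatch is a
hard :class:`FrameMismatchError` rather than a silent matrix product.

All lengths are millimetres.  Angles are degrees at the API surface and
radians internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FRAME_REGISTRY",
    "FrameMismatchError",
    "RigidTransform",
    "PointSet",
    "identity",
    "compose",
    "invert",
    "apply",
    "relabel",
    "rotation_angle_deg",
    "random_rigid",
]

#: The fixed set of coordinate-frame labels used throughout the pipeline.
FRAME_REGISTRY = frozenset(
    {"preop_ct", "intraop_cbct", "matrix", "patient_ref", "tracker"}
)

_ORTHO_TOL = 1e-9


class FrameMismatchError(ValueError):
    """Raised when transform/point frames do not chain correctly."""


def _check_frame(label: str) -> str:
    if label not in FRAME_REGISTRY:
        raise FrameMismatchError(
            f"unknown frame label {label!r}; must be one of {sorted(FRAME_REGISTRY)}"
        )
    return label


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p_target = rotation @ p_source + translation``.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with determinant +1 (checked to 1e-9).
    translation
        3-vector, millimetres.
    source_frame, target_frame
        Frame labels from :data:`FRAME_REGISTRY`.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source_frame: str
    target_frame: str

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("rotation/translation must be finite")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        _check_frame(self.source_frame)
        _check_frame(self.target_frame)

    # -- point mapping -------------------------------------------------
    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Map raw (N, 3) coordinates without frame checking."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.transform_points(points)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
            "source": self.source_frame,
            "target": self.target_frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation=np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            translation=np.asarray(d["translation"], dtype=float),
            source_frame=d["source"],
            target_frame=d["target"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class PointSet:
    """Labelled 3-D points expressed in a single coordinate frame."""

    coordinates: np.ndarray
    labels: tuple
    frame: str

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (N, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != coords.shape[0]:
            raise ValueError("labels length must match number of points")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique within a point set")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "labels", labels)
        _check_frame(self.frame)

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    def reorder_like(self, other: "PointSet") -> "PointSet":
        """Return this set with rows reordered to match ``other``'s labels."""
        if set(self.labels) != set(other.labels):
            raise ValueError(
                f"label mismatch: {sorted(self.labels)} vs {sorted(other.labels)}"
            )
        index = {lab: i for i, lab in enumerate(self.labels)}
        order = [index[lab] for lab in other.labels]
        return PointSet(self.coordinates[order], other.labels, self.frame)

    def to_dict(self) -> dict:
        return {
            "coordinates": [[float(v) for v in row] for row in self.coordinates],
            "labels": list(self.labels),
            "frame": self.frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PointSet":
        return cls(np.asarray(d["coordinates"], dtype=float), tuple(d["labels"]), d["frame"])


def point_set(coords: Iterable, frame: str, labels: Sequence[str] | None = None) -> PointSet:
    """Convenience constructor; auto-labels points ``p0, p1, ...``."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if labels is None:
        labels = tuple(f"p{i}" for i in range(coords.shape[0]))
    return PointSet(coords, tuple(labels), frame)


# ---------------------------------------------------------------------------
# transform algebra
# ---------------------------------------------------------------------------

def identity(source_frame: str, target_frame: str | None = None) -> RigidTransform:
    """Identity motion; frame labels may differ (frames that coincide)."""
    return RigidTransform(
        np.eye(3), np.zeros(3), source_frame, target_frame or source_frame
    )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Return the chained transform ``a ∘ b`` (apply ``b`` first).

    Requires ``a.source_frame == b.target_frame``; the result maps
    ``b.source_frame`` to ``a.target_frame``.
    """
    if a.source_frame != b.target_frame:
        raise FrameMismatchError(
            f"cannot compose: inner frames differ "
            f"({a.source_frame!r} != {b.target_frame!r})"
        )
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        b.source_frame,
        a.target_frame,
    )


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse motion, with source/target frame labels swapped."""
    Rt = t.rotation.T
    return RigidTransform(Rt, -Rt @ t.translation, t.target_frame, t.source_frame)


def apply(t: RigidTransform, pts: PointSet) -> PointSet:
    """Map a :class:`PointSet` through ``t``, checking the frame label."""
    if pts.frame != t.source_frame:
        raise FrameMismatchError(
            f"point set is in frame {pts.frame!r}, transform expects "
            f"{t.source_frame!r}"
        )
    return PointSet(t.transform_points(pts.coordinates), pts.labels, t.target_frame)


def relabel(t: RigidTransform, source_frame: str, target_frame: str) -> RigidTransform:
    """Reinterpret the same motion between different frame labels."""
    return RigidTransform(t.rotation, t.translation, source_frame, target_frame)


def rotation_angle_deg(t: RigidTransform) -> float:
    """Rotation angle of the transform, degrees in [0, 180]."""
    c = (np.trace(t.rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _rotation_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def random_rigid(
    rng_seed,
    max_rotation_deg: float,
    max_translation_mm: float,
    source_frame: str = "tracker",
    target_frame: str = "tracker",
) -> RigidTransform:
    """Draw a random rigid motion with bounded rotation angle and translation.

    The rotation is distributed as the uniform (Haar) measure on SO(3)
    conditioned on rotation angle <= ``max_rotation_deg``: a uniform axis and
    an angle with density proportional to ``1 - cos(theta)`` on the allowed
    interval, sampled by rejection inside the interval.  The translation is
    uniform in the ball of radius ``max_translation_mm``.  Deterministic for
    a fixed seed.
    """
    if max_rotation_deg < 0 or max_translation_mm < 0:
        raise ValueError("bounds must be non-negative")
    rng = _as_rng(rng_seed)
    theta_max = np.radians(min(max_rotation_deg, 180.0))
    if theta_max == 0.0:
        R = np.eye(3)
    else:
        # axis uniform on the sphere
        v = rng.normal(size=3)
        while np.linalg.norm(v) < 1e-12:
            v = rng.normal(size=3)
        # angle ~ (1 - cos t) on [0, theta_max]; rejection against the
        # envelope uniform * (1 - cos theta_max)
        ceil = 1.0 - np.cos(theta_max)
        while True:
            theta = rng.uniform(0.0, theta_max)
            if rng.uniform(0.0, ceil) <= 1.0 - np.cos(theta):
                break
        R = _rotation_from_axis_angle(v, theta)
    if max_translation_mm == 0.0:
        t = np.zeros(3)
    else:
        d = rng.normal(size=3)
        while np.linalg.norm(d) < 1e-12:
            d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        radius = max_translation_mm * rng.uniform() ** (1.0 / 3.0)
        t = radius * d
    return RigidTransform(R, t, source_frame, target_frame)
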