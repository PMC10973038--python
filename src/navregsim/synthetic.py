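"""Synthetic spinal-navigation scenes, noisy measurements and cohorts.

No clinical data ship with this package; this module generates the study
conditions instead.  One *scene* is the ground truth of a single
registration vertebra: a parametric posterior-arch surface (two laminar
plates meeting at a spinous ridge), three orientation landmarks, three
lamina micro-screw targets used as the accuracy reference, the fiducial
registration matrix, the dynamic reference frame, and the true rigid
transforms relating the image, preoperative-CT, matrix, patient-reference
and tracker frames.

*Measurements* are the quantities the navigation workflow would record:
planned screw points picked in the CBCT, acquired screw points digitized
with the pointer, the three landmark and 17 surface picks of the manual
registration, and the fiducial-marker observations of the automatic one.
Each is the ground-truth chain plus iid Gaussian localization noise, with
two discrete user-error modes layered on top at configurable rates:

* ``wrong_level`` — the manual registration is matched against the
  adjacent vertebra (picks displaced by the inter-level offset);
* ``drf_displaced`` — the reference frame moves between registration and
  screw acquisition.

The per-device noise magnitudes are nowhere published; the defaults in
:class:`NoiseConfig` are a calibration chosen once so that the default
cohort lands near the observed clinical accuracy ranges (see
docs/methods.md), and are tunable, not ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._mesh import TriangleMesh
from .transforms import (
    PointSet,
    RigidTransform,
    _as_rng,
    apply,
    compose,
    invert,
    random_rigid,
    relabel,
)

__all__ = [
    "GeometryParams",
    "NoiseConfig",
    "VertebraScene",
    "DatasetRecord",
    "CohortTable",
    "USER_ERRORS",
    "make_vertebra_scene",
    "simulate_measurements",
    "simulate_cohort",
]

USER_ERRORS = ("none", "wrong_level", "drf_displaced", "missing_data", "image_quality")

_SEED_MAX = 2**31 - 1


@dataclass(frozen=True)
class GeometryParams:
    """Parametric posterior-arch geometry (all lengths mm)."""

    extent_x: float = 40.0        # lateral span of the exposed surface
    extent_y: float = 35.0        # cranio-caudal span
    grid_n: int = 30              # heightfield grid resolution per axis
    ridge_height: float = 9.0     # spinous ridge prominence
    ridge_width: float = 5.0      # gaussian ridge width
    lamina_slope: float = 0.30    # lateral fall-off of the laminar plates
    sagittal_bow: float = 4.0     # cranio-caudal curvature amplitude
    spinous_bulge: float = 4.0    # cranio-caudal modulation of the ridge
    neighbor_spacing: float = 20.0  # offset to the adjacent vertebral level
    pose_max_rotation_deg: float = 20.0
    pose_max_translation_mm: float = 50.0

    def validate(self) -> None:
        if self.extent_x < 30.0 or self.extent_y < 30.0:
            raise ValueError("posterior surface must span at least 30x30 mm")
        if self.grid_n < 8:
            raise ValueError("grid_n too coarse for a usable surface")
        if self.ridge_width <= 0 or self.neighbor_spacing <= 0:
            raise ValueError("degenerate geometry parameters")


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian localization noise (mm) and discrete user-error rates.

    Sigmas are per-axis standard deviations of iid Gaussian noise.  The
    ``fusion_noise_sigma_mm_deg`` pair perturbs the image-fusion transform
    (per-axis translation sigma, rotation-angle sigma in degrees).  All
    defaults are simulation calibration, documented in docs/methods.md.
    """

    fle_image_sigma: float = 0.45      # radio-opaque marker localization in CBCT
    fle_tracker_sigma: float = 0.35    # tracked-marker localization
    pointer_sigma: float = 0.4         # manual pointer digitization
    surface_offset_sigma: float = 1.8  # pointer-tip skidding along the bone normal
    screw_plan_sigma: float = 0.4      # screw-head centre picking in the image
    fusion_noise_sigma_mm_deg: tuple = (0.7, 0.7)
    p_wrong_level: float = 0.10
    p_drf_displacement: float = 0.04
    p_missing_data: float = 0.02
    p_image_quality: float = 0.0
    drf_displacement_mm: float = 15.0

    def validate(self) -> None:
        sigmas = (
            self.fle_image_sigma, self.fle_tracker_sigma, self.pointer_sigma,
            self.surface_offset_sigma, self.screw_plan_sigma,
            *self.fusion_noise_sigma_mm_deg,
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("noise sigmas must be >= 0")
        probs = (self.p_wrong_level, self.p_drf_displacement,
                 self.p_missing_data, self.p_image_quality)
        if any(not 0.0 <= p <= 1.0 for p in probs) or sum(probs) > 1.0:
            raise ValueError("event probabilities must lie in [0,1] and sum <= 1")

    def scaled(self, k: float) -> "NoiseConfig":
        """All sigmas multiplied by ``k`` (event rates unchanged)."""
        return replace(
            self,
            fle_image_sigma=k * self.fle_image_sigma,
            fle_tracker_sigma=k * self.fle_tracker_sigma,
            pointer_sigma=k * self.pointer_sigma,
            surface_offset_sigma=k * self.surface_offset_sigma,
            screw_plan_sigma=k * self.screw_plan_sigma,
            fusion_noise_sigma_mm_deg=(
                k * self.fusion_noise_sigma_mm_deg[0],
                k * self.fusion_noise_sigma_mm_deg[1],
            ),
        )


# fixed manufactured geometry of the fiducial matrix (matrix frame, mm):
# four plate corners plus two raised posts -> non-coplanar by construction
_AIR_MARKERS_LOCAL = np.array(
    [
        [-30.0, -20.0, 0.0],
        [30.0, -20.0, 0.0],
        [30.0, 20.0, 0.0],
        [-30.0, 20.0, 0.0],
        [0.0, 0.0, 18.0],
        [15.0, -5.0, 30.0],
    ]
)


@dataclass
class VertebraScene:
    """Ground truth for one registration vertebra (tracker frame)."""

    scene_id: str
    level_index: int
    surface: TriangleMesh                  # tracker frame
    landmarks3: PointSet                   # right/left/center, tracker frame
    screw_targets: PointSet                # 3 lamina screws, tracker frame
    neighbor_offset: np.ndarray            # 3-vector to the adjacent level
    air_markers_local: PointSet            # matrix frame
    T_image_to_tracker: RigidTransform
    T_preop_to_tracker: RigidTransform
    T_matrix_to_tracker: RigidTransform
    T_ref_to_tracker: RigidTransform

    def validate(self) -> None:
        d = self.surface.distances(self.screw_targets.coordinates)
        if d.max() > 1.0:
            raise ValueError("screw targets must lie within 1 mm of the surface")
        pts = self.screw_targets.coordinates
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(pts[i] - pts[j]) < 10.0:
                    raise ValueError("screw targets must be >= 10 mm apart")
        if self.surface.distances(self.landmarks3.coordinates).max() > 1e-6:
            raise ValueError("landmarks must lie on the surface")
        m = self.air_markers_local.coordinates
        s = np.linalg.svd(m - m.mean(axis=0), compute_uv=False)
        if s[-1] <= 1.0:
            raise ValueError("fiducial markers must be non-coplanar")

    # model of the segmented preoperative CT
    def model_surface_preop(self) -> TriangleMesh:
        T = invert(self.T_preop_to_tracker)
        return self.surface.transformed(T.rotation, T.translation)

    def model_landmarks_preop(self) -> PointSet:
        return apply(invert(self.T_preop_to_tracker), self.landmarks3)

    def export(self, out_dir) -> None:
        """Write the surface as PLY plus a JSON sidecar with everything else."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.surface.export_ply(out_dir / f"{self.scene_id}.ply")
        sidecar = {
            "scene_id": self.scene_id,
            "level_index": self.level_index,
            "landmarks3": self.landmarks3.to_dict(),
            "screw_targets": self.screw_targets.to_dict(),
            "neighbor_offset": [float(v) for v in self.neighbor_offset],
            "air_markers_local": self.air_markers_local.to_dict(),
            "T_image_to_tracker": self.T_image_to_tracker.to_dict(),
            "T_preop_to_tracker": self.T_preop_to_tracker.to_dict(),
            "T_matrix_to_tracker": self.T_matrix_to_tracker.to_dict(),
            "T_ref_to_tracker": self.T_ref_to_tracker.to_dict(),
        }
        (out_dir / f"{self.scene_id}.json").write_text(json.dumps(sidecar, indent=1))


def _heightfield(params: GeometryParams):
    """Canonical posterior-arch heightfield z = f(x, y) and its mesh."""
    n = params.grid_n
    x = np.linspace(-params.extent_x / 2, params.extent_x / 2, n)
    y = np.linspace(-params.extent_y / 2, params.extent_y / 2, n)
    X, Y = np.meshgrid(x, y, indexing="ij")

    def f(xx, yy):
        amp = params.ridge_height + params.spinous_bulge * np.cos(
            np.pi * yy / params.extent_y
        )
        ridge = amp * np.exp(-(xx**2) / (2.0 * params.ridge_width**2))
        plates = -params.lamina_slope * np.abs(xx)
        bow = params.sagittal_bow * (2.0 * yy / params.extent_y) ** 2
        return ridge + plates + bow

    Z = f(X, Y)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return f, TriangleMesh(vertices, np.asarray(faces))


def make_vertebra_scene(
    rng_seed, level_index: int = 0, geometry: GeometryParams | None = None
) -> VertebraScene:
    """Generate one ground-truth vertebra scene (deterministic per seed)."""
    params = geometry or GeometryParams()
    params.validate()
    rng = _as_rng(rng_seed)
    f, canonical = _heightfield(params)

    ex, ey = params.extent_x, params.extent_y

    def on_surface(x, y):
        return np.array([x, y, float(f(np.array(x), np.array(y)))])

    landmarks = np.array(
        [
            on_surface(-0.35 * ex, 0.0),           # right
            on_surface(0.35 * ex, 0.0),            # left
            on_surface(0.0, -0.30 * ey),           # center, on the ridge
        ]
    )
    screws = np.array(
        [
            on_surface(-0.32 * ex, -0.26 * ey),
            on_surface(0.32 * ex, -0.26 * ey),
            on_surface(0.0, 0.34 * ey),
        ]
    )
    # snap to the piecewise-linear mesh so "on the surface" is exact
    landmarks = canonical.closest_points(landmarks)[0]
    screws = canonical.closest_points(screws)[0]

    # pose the vertebra in the tracker frame
    pose = random_rigid(
        rng, params.pose_max_rotation_deg, params.pose_max_translation_mm
    )
    mesh = canonical.transformed(pose.rotation, pose.translation)
    landmarks_t = pose.transform_points(landmarks)
    screws_t = pose.transform_points(screws)
    neighbor_offset = pose.rotation @ np.array([0.0, params.neighbor_spacing, 0.0])

    # fiducial matrix resting beside the incision, slightly tilted
    tilt = random_rigid(rng, 15.0, 0.0)
    R_m = pose.rotation @ tilt.rotation
    t_m = pose.rotation @ np.array([45.0, 0.0, 25.0]) + pose.translation
    T_matrix = RigidTransform(R_m, t_m, "matrix", "tracker")

    # dynamic reference frame clamped to the spinous process
    tilt2 = random_rigid(rng, 15.0, 0.0)
    R_r = pose.rotation @ tilt2.rotation
    t_r = pose.rotation @ np.array([0.0, -0.45 * ey - 10.0, 20.0]) + pose.translation
    T_ref = RigidTransform(R_r, t_r, "patient_ref", "tracker")

    T_image = random_rigid(rng, 30.0, 100.0, "intraop_cbct", "tracker")
    # supine preoperative scan: same anatomy up to a small pose change
    pose_change = random_rigid(rng, 5.0, 5.0)
    T_preop = relabel(compose(pose_change, T_image), "preop_ct", "tracker")

    scene = VertebraScene(
        scene_id=f"scene_L{level_index:03d}",
        level_index=level_index,
        surface=mesh,
        landmarks3=PointSet(landmarks_t, ("right", "left", "center"), "tracker"),
        screw_targets=PointSet(screws_t, ("s1", "s2", "s3"), "tracker"),
        neighbor_offset=neighbor_offset,
        air_markers_local=PointSet(
            _AIR_MARKERS_LOCAL, tuple(f"m{i}" for i in range(6)), "matrix"
        ),
        T_image_to_tracker=T_image,
        T_preop_to_tracker=T_preop,
        T_matrix_to_tracker=T_matrix,
        T_ref_to_tracker=T_ref,
    )
    scene.validate()
    return scene


@dataclass
class DatasetRecord:
    """One simulated patient-level dataset (everything analysis needs)."""

    scene_id: str
    level_index: int
    planned_screws: PointSet               # intraop_cbct frame
    acquired_screws: PointSet              # patient_ref frame (may miss points)
    landmark_picks: PointSet               # patient_ref frame
    surface_picks: PointSet                # patient_ref frame
    air_obs_image: Optional[PointSet]      # intraop_cbct frame; None if not seen
    air_obs_ref: Optional[PointSet]        # patient_ref frame; None if not seen
    air_markers_local: PointSet            # matrix frame (device geometry)
    model_surface: TriangleMesh            # segmented preop CT model
    model_landmarks: PointSet              # preop_ct frame
    fusion: RigidTransform                 # intraop_cbct -> preop_ct
    user_error: str = "none"
    rms_uair: Optional[float] = None
    rms_sm: Optional[float] = None

    def __post_init__(self):
        if self.user_error not in USER_ERRORS:
            raise ValueError(f"user_error must be one of {USER_ERRORS}")

    def to_dict(self) -> dict:
        d = {
            "scene_id": self.scene_id,
            "level_index": self.level_index,
            "planned_screws": self.planned_screws.to_dict(),
            "acquired_screws": self.acquired_screws.to_dict(),
            "landmark_picks": self.landmark_picks.to_dict(),
            "surface_picks": self.surface_picks.to_dict(),
            "air_obs_image": None if self.air_obs_image is None else self.air_obs_image.to_dict(),
            "air_obs_ref": None if self.air_obs_ref is None else self.air_obs_ref.to_dict(),
            "air_markers_local": self.air_markers_local.to_dict(),
            "model_vertices": self.model_surface.vertices.tolist(),
            "model_faces": self.model_surface.faces.tolist(),
            "model_landmarks": self.model_landmarks.to_dict(),
            "fusion": self.fusion.to_dict(),
            "user_error": self.user_error,
            "rms_uair": self.rms_uair,
            "rms_sm": self.rms_sm,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetRecord":
        opt = lambda x: None if x is None else PointSet.from_dict(x)
        return cls(
            scene_id=d["scene_id"],
            level_index=d["level_index"],
            planned_screws=PointSet.from_dict(d["planned_screws"]),
            acquired_screws=PointSet.from_dict(d["acquired_screws"]),
            landmark_picks=PointSet.from_dict(d["landmark_picks"]),
            surface_picks=PointSet.from_dict(d["surface_picks"]),
            air_obs_image=opt(d["air_obs_image"]),
            air_obs_ref=opt(d["air_obs_ref"]),
            air_markers_local=PointSet.from_dict(d["air_markers_local"]),
            model_surface=TriangleMesh(
                np.asarray(d["model_vertices"]), np.asarray(d["model_faces"])
            ),
            model_landmarks=PointSet.from_dict(d["model_landmarks"]),
            fusion=RigidTransform.from_dict(d["fusion"]),
            user_error=d["user_error"],
            rms_uair=d.get("rms_uair"),
            rms_sm=d.get("rms_sm"),
        )


def _farthest_point_sample(candidates: np.ndarray, k: int, rng) -> np.ndarray:
    """Indices of k well-spread candidate points (seeded farthest-point)."""
    n = candidates.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    d = np.linalg.norm(candidates - candidates[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(candidates - candidates[nxt], axis=1))
    return np.asarray(chosen)


def simulate_measurements(
    scene: VertebraScene,
    noise: NoiseConfig | None = None,
    rng_seed=0,
    force_event: str | None = None,
    n_surface_picks: int = 17,
) -> DatasetRecord:
    """Simulate the navigation measurements for one scene.

    ``force_event`` overrides the random user-error draw ("none" forces a
    clean dataset); otherwise events fire at the configured rates,
    mutually exclusively.
    """
    from .registration import fusion_transform  # local to avoid cycle

    noise = noise or NoiseConfig()
    noise.validate()
    rng = _as_rng(rng_seed)

    if force_event is not None:
        if force_event not in USER_ERRORS:
            raise ValueError(f"unknown event {force_event!r}")
        event = force_event
    else:
        r = rng.random()
        edges = np.cumsum(
            [noise.p_wrong_level, noise.p_drf_displacement,
             noise.p_missing_data, noise.p_image_quality]
        )
        names = ("wrong_level", "drf_displaced", "missing_data", "image_quality")
        event = "none"
        for name, hi in zip(names, edges):
            if r < hi:
                event = name
                break

    T_image_inv = invert(scene.T_image_to_tracker)
    T_ref_inv = invert(scene.T_ref_to_tracker)

    def jitter(shape_n, sigma):
        if sigma == 0:
            return np.zeros((shape_n, 3))
        return rng.normal(0.0, sigma, size=(shape_n, 3))

    # planned screw points, picked in the CBCT volume
    planned = PointSet(
        T_image_inv.transform_points(scene.screw_targets.coordinates)
        + jitter(3, noise.screw_plan_sigma),
        scene.screw_targets.labels,
        "intraop_cbct",
    )

    # manual-registration picks (acquired before any DRF displacement)
    wl_offset = scene.neighbor_offset if event == "wrong_level" else np.zeros(3)
    lm_true = scene.landmarks3.coordinates + wl_offset
    landmark_picks = PointSet(
        T_ref_inv.transform_points(lm_true) + jitter(3, noise.pointer_sigma),
        scene.landmarks3.labels,
        "patient_ref",
    )
    n_picks = n_surface_picks
    idx = _farthest_point_sample(scene.surface.vertices, n_picks, rng)
    pick_pts = scene.surface.vertices[idx]
    normals = scene.surface.vertex_normals[idx]
    if noise.surface_offset_sigma > 0:
        pick_pts = pick_pts + normals * rng.normal(
            0.0, noise.surface_offset_sigma, size=(n_picks, 1)
        )
    surface_picks = PointSet(
        T_ref_inv.transform_points(pick_pts + wl_offset)
        + jitter(n_picks, noise.pointer_sigma),
        tuple(f"sp{i}" for i in range(n_picks)),
        "patient_ref",
    )

    # fiducial-matrix observations (absent when the scan cannot resolve it)
    markers_tracker = scene.T_matrix_to_tracker.transform_points(
        scene.air_markers_local.coordinates
    )
    if event == "image_quality":
        air_obs_image = None
        air_obs_ref = None
    else:
        air_obs_image = PointSet(
            T_image_inv.transform_points(markers_tracker)
            + jitter(len(markers_tracker), noise.fle_image_sigma),
            scene.air_markers_local.labels,
            "intraop_cbct",
        )
        air_obs_ref = PointSet(
            T_ref_inv.transform_points(markers_tracker)
            + jitter(len(markers_tracker), noise.fle_tracker_sigma),
            scene.air_markers_local.labels,
            "patient_ref",
        )

    # screw acquisition happens last; a displaced DRF corrupts it for both
    # methods, which is what makes those datasets stand out as outliers
    T_ref_acq_inv = T_ref_inv
    if event == "drf_displaced":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = RigidTransform(
            np.eye(3), noise.drf_displacement_mm * direction, "tracker", "tracker"
        )
        T_ref_acq_inv = invert(
            relabel(compose(shift, scene.T_ref_to_tracker), "patient_ref", "tracker")
        )
    acquired_coords = (
        T_ref_acq_inv.transform_points(scene.screw_targets.coordinates)
        + jitter(3, noise.pointer_sigma)
    )
    acquired_labels = scene.screw_targets.labels
    if event == "missing_data":
        drop = int(rng.integers(3))
        keep = [i for i in range(3) if i != drop]
        acquired_coords = acquired_coords[keep]
        acquired_labels = tuple(acquired_labels[i] for i in keep)
    acquired = PointSet(acquired_coords, acquired_labels, "patient_ref")

    fusion = fusion_transform(scene, noise, int(rng.integers(_SEED_MAX)))

    return DatasetRecord(
        scene_id=scene.scene_id,
        level_index=scene.level_index,
        planned_screws=planned,
        acquired_screws=acquired,
        landmark_picks=landmark_picks,
        surface_picks=surface_picks,
        air_obs_image=air_obs_image,
        air_obs_ref=air_obs_ref,
        air_markers_local=scene.air_markers_local,
        model_surface=scene.model_surface_preop(),
        model_landmarks=scene.model_landmarks_preop(),
        fusion=fusion,
        user_error=event,
    )


@dataclass
class CohortTable:
    """A simulated cohort: records plus their ground-truth scenes."""

    records: list
    scenes: list = field(default_factory=list)
    noise: Optional[NoiseConfig] = None
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.records):
            rows.append(
                {
                    "dataset_id": i,
                    "scene_id": r.scene_id,
                    "level_index": r.level_index,
                    "user_error": r.user_error,
                    "n_acquired": len(r.acquired_screws),
                    "has_air_obs": r.air_obs_image is not None,
                    "rms_uair": r.rms_uair,
                    "rms_sm": r.rms_sm,
                }
            )
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        rec_dir = out_dir / "records"
        rec_dir.mkdir(parents=True, exist_ok=True)
        for i, r in enumerate(self.records):
            (rec_dir / f"record_{i:04d}.json").write_text(json.dumps(r.to_dict()))
        self.to_dataframe().to_csv(out_dir / "cohort.csv", index=False)
        meta = {"n_datasets": len(self.records), "seed": self.seed,
                "noise": None if self.noise is None else self.noise.__dict__ | {
                    "fusion_noise_sigma_mm_deg": list(self.noise.fusion_noise_sigma_mm_deg)}}
        (out_dir / "cohort.json").write_text(json.dumps(meta, indent=1))
        if self.scenes:
            for s in self.scenes:
                s.export(out_dir / "scenes")

    @classmethod
    def load(cls, in_dir) -> "CohortTable":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "cohort.json").read_text())
        records = []
        for i in range(meta["n_datasets"]):
            path = in_dir / "records" / f"record_{i:04d}.json"
            records.append(DatasetRecord.from_dict(json.loads(path.read_text())))
        noise = None
        if meta.get("noise"):
            nd = dict(meta["noise"])
            nd["fusion_noise_sigma_mm_deg"] = tuple(nd["fusion_noise_sigma_mm_deg"])
            noise = NoiseConfig(**nd)
        return cls(records=records, noise=noise, seed=meta.get("seed"))


def simulate_cohort(
    n_datasets: int,
    noise: NoiseConfig | None = None,
    rng_seed=0,
    geometry: GeometryParams | None = None,
    exact_error_counts: dict | None = None,
    keep_scenes: bool = True,
) -> CohortTable:
    """Simulate a cohort of independent datasets (deterministic per seed).

    ``exact_error_counts`` (e.g. ``{"wrong_level": 5, "drf_displaced": 2,
    "missing_data": 1}``) forces exactly those event counts on randomly
    chosen datasets and a clean draw everywhere else, overriding the
    probabilistic rates — useful for reproducing the study's exclusion
    bookkeeping exactly.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    noise = noise or NoiseConfig()
    noise.validate()
    rng = _as_rng(rng_seed)

    forced = [None] * n_datasets
    if exact_error_counts is not None:
        total = sum(exact_error_counts.values())
        if total > n_datasets:
            raise ValueError("more forced events than datasets")
        order = rng.permutation(n_datasets)
        forced = ["none"] * n_datasets
        pos = 0
        for name, count in exact_error_counts.items():
            if name not in USER_ERRORS:
                raise ValueError(f"unknown event {name!r}")
            for _ in range(count):
                forced[order[pos]] = name
                pos += 1

    records, scenes = [], []
    for i in range(n_datasets):
        scene_seed = int(rng.integers(_SEED_MAX))
        meas_seed = int(rng.integers(_SEED_MAX))
        scene = make_vertebra_scene(scene_seed, level_index=i, geometry=geometry)
        scene.scene_id = f"scene_{i:04d}"
        record = simulate_measurements(scene, noise, meas_seed, force_event=forced[i])
        records.append(record)
        if keep_scenes:
            scenes.append(scene)
    seed_val = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    return CohortTable(records=records, scenes=scenes, noise=noise,
                       seed=None if seed_val is None else int(seed_val))
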