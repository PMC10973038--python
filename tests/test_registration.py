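"""Registration algorithms vs. independent oracles.

Paired-point registration is checked against a generic nonlinear
least-squares optimizer (axis-angle parametrization) and its Monte-Carlo
target error against the closed-form expected-TRE formula for a fiducial
layout.  Surface matching is checked on noise-free fixed points, known
perturbations, and the forced wrong-level failure mode.
"""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

import navregsim as nv
from navregsim._mesh import TriangleMesh
from navregsim.registration import RegistrationError


def _random_transform(rng, max_deg=60, max_mm=50, src="intraop_cbct", tgt="matrix"):
    return nv.random_rigid(rng, max_deg, max_mm, src, tgt)


def optimizer_oracle(src: np.ndarray, tgt: np.ndarray):
    """Brute-force rigid fit: minimize residuals over axis-angle + translation."""

    def residual(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return (src @ R.T + params[3:] - tgt).ravel()

    best = None
    for trial in range(4):  # multistart to dodge local minima
        x0 = np.concatenate([np.random.default_rng(trial).normal(scale=0.5, size=3),
                             (tgt.mean(0) - src.mean(0))])
        sol = least_squares(residual, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    return R, best.x[3:]


def expected_tre_sq(fiducials: np.ndarray, target: np.ndarray, fle_sq: float) -> float:
    """Closed-form expected squared target registration error.

    <TRE^2> = <FLE^2>/N * (1 + (1/3) * sum_k d_k^2 / f_k^2) with d_k the
    target's distance from principal axis k of the fiducial configuration
    and f_k the RMS fiducial distance from that axis.
    """
    c = fiducials.mean(axis=0)
    X = fiducials - c
    _, _, Vt = np.linalg.svd(X)
    comps = X @ Vt.T
    t = (target - c) @ Vt.T
    total = 0.0
    for k in range(3):
        others = [j for j in range(3) if j != k]
        f_sq = np.mean(np.sum(comps[:, others] ** 2, axis=1))
        d_sq = np.sum(t[others] ** 2)
        total += d_sq / f_sq
    return fle_sq / fiducials.shape[0] * (1.0 + total / 3.0)


class TestPairedPoint:
    def test_identity_when_target_equals_source(self):
        pts = nv.point_set([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], "intraop_cbct")
        tgt = nv.PointSet(pts.coordinates, pts.labels, "matrix")
        T, fre = nv.paired_point_register(pts, tgt)
        assert np.abs(T.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(T.translation).max() < 1e-12
        assert fre < 1e-12

    def test_exact_recovery_of_known_motion(self):
        rng = np.random.default_rng(4)
        src = nv.point_set(rng.normal(scale=30, size=(5, 3)), "intraop_cbct")
        truth = _random_transform(rng)
        tgt = nv.PointSet(truth.transform_points(src.coordinates), src.labels, "matrix")
        T, fre = nv.paired_point_register(src, tgt)
        assert np.abs(T.rotation - truth.rotation).max() < 1e-9
        assert np.abs(T.translation - truth.translation).max() < 1e-9
        assert fre < 1e-9

    def test_label_correspondence_not_row_order(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(scale=20, size=(4, 3))
        truth = _random_transform(rng)
        src = nv.PointSet(coords, ("a", "b", "c", "d"), "intraop_cbct")
        perm = [2, 0, 3, 1]
        tgt = nv.PointSet(truth.transform_points(coords)[perm],
                          tuple(src.labels[i] for i in perm), "matrix")
        T, fre = nv.paired_point_register(src, tgt)
        assert fre < 1e-9

    def test_degenerate_inputs_rejected(self):
        two = nv.point_set([[0, 0, 0], [1, 0, 0]], "intraop_cbct")
        with pytest.raises(RegistrationError):
            nv.paired_point_register(two, nv.PointSet(two.coordinates, two.labels, "matrix"))
        line = nv.point_set([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], "intraop_cbct")
        with pytest.raises(RegistrationError):
            nv.paired_point_register(line, nv.PointSet(line.coordinates, line.labels, "matrix"))

    def test_agrees_with_optimizer_oracle(self):
        """100 random noisy instances: closed form == brute-force optimum."""
        rng = np.random.default_rng(12)
        probe = rng.normal(scale=40, size=(6, 3))
        for _ in range(100):
            n = int(rng.integers(4, 9))
            src = rng.normal(scale=40, size=(n, 3))
            truth = _random_transform(rng)
            tgt = truth.transform_points(src) + rng.normal(scale=0.3, size=(n, 3))
            T, _ = nv.paired_point_register(
                nv.point_set(src, "intraop_cbct"),
                nv.point_set(tgt, "matrix"),
            )
            R_o, t_o = optimizer_oracle(src, tgt)
            ours = T.transform_points(probe)
            oracle = probe @ R_o.T + t_o
            assert np.abs(ours - oracle).max() < 1e-6

    def test_reflection_degenerate_resolved_to_proper_rotation(self):
        # a near-planar configuration with noise can make the unconstrained
        # optimum a reflection; the result must still be a proper rotation
        rng = np.random.default_rng(3)
        src = rng.normal(scale=30, size=(4, 3))
        src[:, 2] *= 1e-3
        tgt = -src + rng.normal(scale=0.1, size=src.shape)  # adversarial flip
        T, _ = nv.paired_point_register(
            nv.point_set(src, "intraop_cbct"), nv.point_set(tgt, "matrix")
        )
        assert np.linalg.det(T.rotation) > 0.999


class TestAutomaticRegistration:
    def test_noise_free_equals_ground_truth_chain(self, scene, clean_record):
        T = nv.estimate_uair_transform(clean_record)
        truth = nv.compose(nv.invert(scene.T_ref_to_tracker), scene.T_image_to_tracker)
        assert np.abs(T.rotation - truth.rotation).max() < 1e-9
        assert np.abs(T.translation - truth.translation).max() < 1e-9
        assert (T.source_frame, T.target_frame) == ("intraop_cbct", "patient_ref")

    def test_missing_observations_signal_exclusion(self, scene, zero_noise):
        rec = nv.simulate_measurements(scene, zero_noise, 2, force_event="image_quality")
        with pytest.raises(nv.MissingObservationError):
            nv.estimate_uair_transform(rec)

    def test_monte_carlo_tre_matches_closed_form(self):
        """Mean squared TRE within 20% of the expected-TRE formula."""
        fiducials = np.array(
            [[-30, -20, 0], [30, -20, 0], [30, 20, 0], [-30, 20, 0], [0, 0, 18], [15, -5, 30]],
            dtype=float,
        )
        target = np.array([10.0, -60.0, -20.0])
        sigma = 0.3
        rng = np.random.default_rng(9)
        labels = tuple(f"m{i}" for i in range(len(fiducials)))
        src = nv.PointSet(fiducials, labels, "matrix")
        sq = []
        for _ in range(1500):
            obs = fiducials + rng.normal(scale=sigma, size=fiducials.shape)
            T, _ = nv.paired_point_register(src, nv.PointSet(obs, labels, "patient_ref"))
            sq.append(np.sum((T.transform_points(target) - target) ** 2))
        predicted = expected_tre_sq(fiducials, target, 3 * sigma**2)
        assert abs(np.mean(sq) - predicted) / predicted < 0.20

    def test_tre_grows_with_distance_from_fiducial_centroid(self):
        fiducials = np.array(
            [[-25, -15, 0], [25, -15, 0], [25, 15, 0], [-25, 15, 0], [0, 0, 20]], dtype=float
        )
        labels = tuple(f"m{i}" for i in range(5))
        src = nv.PointSet(fiducials, labels, "matrix")
        rng = np.random.default_rng(14)
        distances = np.array([10.0, 40.0, 80.0, 120.0])
        direction = np.array([0.3, -0.8, -0.52])
        direction /= np.linalg.norm(direction)
        means = []
        for d in distances:
            target = fiducials.mean(0) + d * direction
            errs = []
            for _ in range(400):
                obs = fiducials + rng.normal(scale=0.3, size=fiducials.shape)
                T, _ = nv.paired_point_register(src, nv.PointSet(obs, labels, "patient_ref"))
                errs.append(np.linalg.norm(T.transform_points(target) - target))
            means.append(np.mean(errs))
        slope = np.polyfit(distances, means, 1)[0]
        assert slope > 0
        assert means[-1] > means[0]

    def test_error_vanishes_with_noise(self, scene, zero_noise):
        """Registration error decays roughly linearly as sigma -> 0."""
        errs = []
        for sigma in (0.1, 0.01, 0.001):
            noise = nv.NoiseConfig(
                fle_image_sigma=sigma, fle_tracker_sigma=sigma, pointer_sigma=0,
                surface_offset_sigma=0, screw_plan_sigma=0,
                fusion_noise_sigma_mm_deg=(0, 0), p_wrong_level=0,
                p_drf_displacement=0, p_missing_data=0, p_image_quality=0,
            )
            truth = nv.compose(nv.invert(scene.T_ref_to_tracker), scene.T_image_to_tracker)
            screws_image = nv.invert(scene.T_image_to_tracker).transform_points(
                scene.screw_targets.coordinates
            )
            per_seed = []
            for seed in range(30):
                rec = nv.simulate_measurements(scene, noise, seed, force_event="none")
                T = nv.estimate_uair_transform(rec)
                per_seed.append(
                    np.linalg.norm(
                        T.transform_points(screws_image)
                        - truth.transform_points(screws_image),
                        axis=1,
                    ).mean()
                )
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]
        assert 0.03 < errs[1] / errs[0] < 0.3
        assert 0.03 < errs[2] / errs[1] < 0.3


class TestSurfaceMatching:
    def test_noise_free_fixed_point(self, clean_record):
        res = nv.surface_match_register(
            clean_record.landmark_picks,
            clean_record.surface_picks,
            clean_record.model_surface,
            clean_record.model_landmarks,
        )
        assert res.residual_mm < 1e-6
        assert res.n_iter <= 2
        assert res.converged

    def test_recovers_from_perturbed_initialization(self, scene, clean_record):
        """Landmarks off by 10 deg / 5 mm, exact surface picks: truth recovered."""
        rec = clean_record
        perturb = nv.random_rigid(31, 10.0, 0.0, "patient_ref", "patient_ref")
        lm = rec.landmark_picks.coordinates
        center = lm.mean(axis=0)
        rng = np.random.default_rng(32)
        shift = rng.normal(size=3)
        shift = 5.0 * shift / np.linalg.norm(shift)
        lm_bad = (lm - center) @ perturb.rotation.T + center + shift
        res = nv.surface_match_register(
            nv.PointSet(lm_bad, rec.landmark_picks.labels, "patient_ref"),
            rec.surface_picks,
            rec.model_surface,
            rec.model_landmarks,
        )
        truth = nv.compose(nv.invert(scene.T_ref_to_tracker), scene.T_preop_to_tracker)
        model_screws = nv.invert(scene.T_preop_to_tracker).transform_points(
            scene.screw_targets.coordinates
        )
        err = np.linalg.norm(
            res.transform.transform_points(model_screws)
            - truth.transform_points(model_screws),
            axis=1,
        ).max()
        assert err < 0.05

    def test_wrong_level_on_multi_level_spine(self, scene, zero_noise):
        """Landmarks displaced one level: ICP locks onto the adjacent copy."""
        rec = nv.simulate_measurements(scene, zero_noise, 6, force_event="none")
        off_preop = nv.invert(scene.T_preop_to_tracker).rotation @ scene.neighbor_offset
        V, F = rec.model_surface.vertices, rec.model_surface.faces
        nvtx = V.shape[0]
        multi = TriangleMesh(
            np.vstack([V, V + off_preop, V - off_preop]),
            np.vstack([F, F + nvtx, F + 2 * nvtx]),
        )
        off_ref = nv.invert(scene.T_ref_to_tracker).rotation @ scene.neighbor_offset
        lm_bad = nv.PointSet(
            rec.landmark_picks.coordinates + off_ref,
            rec.landmark_picks.labels,
            "patient_ref",
        )
        res = nv.surface_match_register(
            lm_bad, rec.surface_picks, multi, rec.model_landmarks
        )
        acc = nv.sm_error(rec, rec.fusion, res.transform)
        offset_mag = np.linalg.norm(scene.neighbor_offset)
        assert abs(acc.rms_mm - offset_mag) / offset_mag < 0.30

    def test_residual_monotone_nonincreasing(self, scene):
        noise = nv.NoiseConfig(p_wrong_level=0, p_drf_displacement=0,
                               p_missing_data=0, p_image_quality=0)
        for seed in range(5):
            rec = nv.simulate_measurements(scene, noise, seed, force_event="none")
            res = nv.surface_match_register(
                rec.landmark_picks, rec.surface_picks,
                rec.model_surface, rec.model_landmarks,
            )
            hist = np.asarray(res.residual_history)
            assert np.all(np.diff(hist) <= 1e-9)

    def test_nonconvergence_flagged_not_raised(self, scene):
        noise = nv.NoiseConfig(p_wrong_level=0, p_drf_displacement=0,
                               p_missing_data=0, p_image_quality=0)
        rec = nv.simulate_measurements(scene, noise, 1, force_event="none")
        res = nv.surface_match_register(
            rec.landmark_picks, rec.surface_picks,
            rec.model_surface, rec.model_landmarks, max_iter=1, tol_mm=1e-12,
        )
        assert not res.converged

    def test_degenerate_landmarks_rejected(self, clean_record):
        rec = clean_record
        collinear = nv.PointSet(
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float),
            rec.landmark_picks.labels, "patient_ref",
        )
        with pytest.raises(RegistrationError):
            nv.surface_match_register(
                collinear, rec.surface_picks, rec.model_surface, rec.model_landmarks
            )

    def test_error_vanishes_with_pick_noise(self, scene):
        errs = []
        truth = nv.compose(nv.invert(scene.T_ref_to_tracker), scene.T_preop_to_tracker)
        model_screws = nv.invert(scene.T_preop_to_tracker).transform_points(
            scene.screw_targets.coordinates
        )
        for sigma in (0.1, 0.01, 0.001):
            noise = nv.NoiseConfig(
                fle_image_sigma=0, fle_tracker_sigma=0, pointer_sigma=sigma,
                surface_offset_sigma=0, screw_plan_sigma=0,
                fusion_noise_sigma_mm_deg=(0, 0), p_wrong_level=0,
                p_drf_displacement=0, p_missing_data=0, p_image_quality=0,
            )
            per_seed = []
            for seed in range(15):
                rec = nv.simulate_measurements(scene, noise, seed, force_event="none")
                res = nv.surface_match_register(
                    rec.landmark_picks, rec.surface_picks,
                    rec.model_surface, rec.model_landmarks,
                )
                per_seed.append(
                    np.linalg.norm(
                        res.transform.transform_points(model_screws)
                        - truth.transform_points(model_screws),
                        axis=1,
                    ).mean()
                )
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]


class TestFusion:
    def test_zero_noise_is_exact_chain(self, scene, zero_noise):
        f = nv.fusion_transform(scene, zero_noise, 1)
        truth = nv.compose(nv.invert(scene.T_preop_to_tracker), scene.T_image_to_tracker)
        assert np.abs(f.rotation - truth.rotation).max() < 1e-12
        assert np.abs(f.translation - truth.translation).max() < 1e-12

    def test_deterministic_per_seed(self, scene):
        noise = nv.NoiseConfig()
        a = nv.fusion_transform(scene, noise, 5)
        b = nv.fusion_transform(scene, noise, 5)
        assert np.array_equal(a.rotation, b.rotation)
        assert np.array_equal(a.translation, b.translation)

    def test_translational_sd_matches_config(self, scene, zero_noise):
        from dataclasses import replace

        noise = replace(zero_noise, fusion_noise_sigma_mm_deg=(0.2, 0.2))
        truth = nv.compose(nv.invert(scene.T_preop_to_tracker), scene.T_image_to_tracker)
        deltas = []
        for seed in range(10_000):
            f = nv.fusion_transform(scene, noise, seed)
            deltas.append(nv.compose(f, nv.invert(truth)).translation)
        sd = np.asarray(deltas).std(axis=0, ddof=1)
        assert np.abs(sd - 0.2).max() < 0.01
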