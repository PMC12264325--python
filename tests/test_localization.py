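"""Gantry scheduling, stereoscopic triangulation, the Gaussian motion PDF
and the monoscopic density-argmax estimator."""

import numpy as np
import pytest

from detrack.geometry import Ray, pixel_to_ray, project_point
from detrack.localization import (
    DEFAULT_BLOCKING_SECTORS,
    LocalizationError,
    MonitoringConfig,
    MotionPDF,
    fit_pdf,
    gantry_schedule,
    monoscopic_estimate,
    prior_from_trajectory,
    run_monitoring,
    stereo_localize,
)


def grid_search_argmax(ray: Ray, pdf: MotionPDF, lo=-500.0, hi=500.0, step=0.01):
    """Dense search of the Gaussian density along the ray (oracle)."""
    t = np.arange(lo, hi + step, step)
    pts = ray.origin[None, :] + t[:, None] * ray.direction[None, :]
    d = pts - pdf.mean
    sinv = np.linalg.inv(pdf.covariance)
    q = np.einsum("ni,ij,nj->n", d, sinv, d)
    return pts[np.argmin(q)]


class TestGantrySchedule:
    def test_default_arc_contains_all_modes_in_runs(self):
        sched = gantry_schedule(n_frames=100)
        modes = sched.modes
        assert set(modes) == {"STEREO", "MONO_A", "MONO_B"}
        # contiguous runs (no rapid alternation): count transitions
        transitions = sum(a != b for a, b in zip(modes, modes[1:]))
        assert transitions <= 5
        assert modes[0] == "STEREO"  # arc starts stereoscopic

    def test_empty_sectors_all_stereo(self):
        sched = gantry_schedule(n_frames=20, blocking_sectors={})
        assert all(m == "STEREO" for m in sched.modes)

    def test_full_arc_block_removes_stereo(self):
        sched = gantry_schedule(
            n_frames=20, blocking_sectors={"B": [(-180.0, 10.0)]}
        )
        assert all(m == "MONO_A" for m in sched.modes)

    def test_simultaneous_blocking_rejected(self):
        with pytest.raises(LocalizationError):
            gantry_schedule(
                n_frames=10,
                blocking_sectors={"A": [(-100, 0)], "B": [(-50, -20)]},
            )


class TestFitPdf:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        mean = np.array([1.0, -2.0, 5.0])
        cov = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.2], [0.0, 0.2, 4.0]])
        samples = rng.multivariate_normal(mean, cov, size=1000)
        pdf = fit_pdf(samples)
        assert np.all(np.abs(pdf.mean - mean) < 0.2)
        assert np.all(np.abs(pdf.covariance - cov) < 0.15 * np.abs(cov).max())

    def test_identical_samples_floored_covariance(self):
        samples = np.tile([1.0, 2.0, 3.0], (10, 1))
        pdf = fit_pdf(samples, floor=0.01)
        assert np.allclose(pdf.mean, [1, 2, 3])
        assert np.allclose(pdf.covariance, 0.01 * np.eye(3), atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(LocalizationError):
            fit_pdf(np.zeros((3, 3)), min_samples=5)

    def test_near_linear_motion_stays_invertible(self):
        # rigid-arm coupling: all samples on a line
        t = np.linspace(-1, 1, 50)
        samples = np.outer(t, [0.23, 0.23, 0.94]) * 10
        pdf = fit_pdf(samples, floor=0.01)
        w = np.linalg.eigvalsh(pdf.covariance)
        assert w[0] >= 0.01 - 1e-12


class TestMonoscopicEstimate:
    def test_ray_through_mean_returns_mean(self):
        pdf = MotionPDF(mean=[3.0, 4.0, 5.0],
                        covariance=np.diag([1.0, 2.0, 3.0]), n_samples=10)
        ray = Ray((0, 0, 0), (3.0, 4.0, 5.0))
        assert np.allclose(monoscopic_estimate(ray, pdf), [3, 4, 5], atol=1e-9)

    def test_isotropic_covariance_is_orthogonal_projection(self):
        pdf = MotionPDF(mean=[5.0, 5.0, 0.0],
                        covariance=4.0 * np.eye(3), n_samples=10)
        ray = Ray((0, 0, 0), (1.0, 0.0, 0.0))
        est = monoscopic_estimate(ray, pdf)
        assert np.allclose(est, [5.0, 0.0, 0.0], atol=1e-9)
        # oracle: dense grid search of the density along the ray
        assert np.allclose(est, grid_search_argmax(ray, pdf), atol=0.01)

    def test_anisotropic_covariance_matches_grid_search(self):
        # SI variance 100x lateral; SI-aligned ray offset laterally
        pdf = MotionPDF(mean=[0.0, 0.0, 0.0],
                        covariance=np.diag([1.0, 1.0, 100.0]), n_samples=10)
        ray = Ray((5.0, 2.0, -50.0), (0.05, 0.0, 1.0))
        est = monoscopic_estimate(ray, pdf)
        oracle = grid_search_argmax(ray, pdf)
        assert abs(est[2] - oracle[2]) < 0.1

    def test_random_instances_match_grid_search(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(size=(3, 3))
            cov = a @ a.T + 0.5 * np.eye(3)
            pdf = MotionPDF(mean=rng.normal(scale=5, size=3),
                            covariance=cov, n_samples=10)
            ray = Ray(rng.normal(scale=20, size=3), rng.normal(size=3))
            est = monoscopic_estimate(ray, pdf)
            oracle = grid_search_argmax(ray, pdf)
            assert np.linalg.norm(est - oracle) < 0.1

    def test_estimate_always_on_ray(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            pdf = MotionPDF(mean=rng.normal(size=3),
                            covariance=a @ a.T + 0.1 * np.eye(3), n_samples=5)
            ray = Ray(rng.normal(scale=10, size=3), rng.normal(size=3))
            est = monoscopic_estimate(ray, pdf)
            t = (est - ray.origin) @ ray.direction
            assert np.linalg.norm(ray.point(t) - est) < 1e-9

    def test_limiting_covariances(self):
        ray = Ray((0.0, 10.0, 0.0), (1.0, 0.0, 0.0))
        mean = np.array([3.0, 0.0, 4.0])
        # uninformative (huge isotropic): closest ray point to the mean
        pdf = MotionPDF(mean=mean, covariance=1e6 * np.eye(3), n_samples=10)
        est = monoscopic_estimate(ray, pdf)
        assert np.allclose(est, [3.0, 10.0, 0.0], atol=1e-6)
        # tight floor: ray point nearest the mean under the Sigma metric
        pdf2 = MotionPDF(mean=mean, covariance=0.01 * np.eye(3), n_samples=10)
        est2 = monoscopic_estimate(ray, pdf2)
        assert np.allclose(est2, grid_search_argmax(ray, pdf2), atol=0.01)


class TestStereoLocalize:
    def test_exact_projections_recover_point(self, geom):
        from detrack.matching import Template

        p = np.array([4.0, -6.0, 12.0])
        tpl = {
            v: Template(pixels=np.outer([1, 2, 1], [1, 2, 1]).astype(float),
                        view=v, com_offset=(0.0, 0.0))
            for v in ("A", "B")
        }
        locs = {v: project_point(geom, v, p) for v in ("A", "B")}
        est, residual = stereo_localize(locs["A"], locs["B"], tpl, geom)
        assert np.allclose(est, p, atol=1e-6)
        assert residual < 1e-6

    def test_one_pixel_shift_sensitivity(self, geom):
        from detrack.matching import Template

        p = np.zeros(3)
        tpl = {
            v: Template(pixels=np.outer([1, 2, 1], [1, 2, 1]).astype(float),
                        view=v, com_offset=(0.0, 0.0))
            for v in ("A", "B")
        }
        la = project_point(geom, "A", p)
        lb = project_point(geom, "B", p)
        est0, _ = stereo_localize(la, lb, tpl, geom)
        est1, _ = stereo_localize((la[0] + 1, la[1]), lb, tpl, geom)
        mag = (3435 + 2185) / 3435
        assert np.linalg.norm(est1 - est0) < 2 * 0.4 / mag + 0.1


@pytest.fixture(scope="module")
def tracked_setup():
    from detrack.evaluation import SweepConfig, _Bench, _prepare_tumor

    cfg = SweepConfig()
    bench = _Bench.build(cfg)
    tumor, templates, ref = _prepare_tumor(bench, 33.0, (140.0, 35.0))
    return bench, tumor, templates, ref


class TestRunMonitoring:

    def _series(self, bench, tumor, ref, n_frames, seed=None):
        from detrack.phantom import breathing_trajectory
        from detrack.projector import acquire_series

        traj = breathing_trajectory(n_frames=n_frames, seed=1, variability=0.0)
        return acquire_series(
            bench.thorax, tumor, traj, bench.geom, protocol="SE",
            seed=seed, tumor_reference=ref, static_paths=bench.static_paths,
        ), traj

    def test_all_stereo_schedule_equals_framewise_stereo(self, tracked_setup):
        bench, tumor, templates, ref = tracked_setup
        series, traj = self._series(bench, tumor, ref, 10)
        sched = gantry_schedule(n_frames=10, blocking_sectors={})
        recs = run_monitoring(
            series, templates, bench.geom, sched,
            MonitoringConfig(technique="SE"),
        )
        assert all(r.mode == "STEREO" for r in recs)
        assert all(r.error_3d < 3.0 for r in recs)

    def test_monoscopic_estimates_lie_on_measurement_ray(self, tracked_setup):
        bench, tumor, templates, ref = tracked_setup
        series, traj = self._series(bench, tumor, ref, 40)
        # stereo first 25 frames, then mono B
        sectors = {"A": [(-180 + 25 * (190 / 39), 10.0)]}
        sched = gantry_schedule(n_frames=40, blocking_sectors=sectors)
        assert sched.modes[-1] == "MONO_B"
        recs = run_monitoring(
            series, templates, bench.geom, sched,
            MonitoringConfig(technique="SE"),
        )
        from detrack.matching import attenuation_image, normxcorr

        for rec in recs:
            if rec.mode != "MONO_B":
                continue
            frame = series.frames[rec.frame_index]
            img = attenuation_image(frame.images[("B", "SE")])
            cm = normxcorr(img, templates["B"])
            tpl = templates["B"]
            pixel = (cm.peak[0] + tpl.com_offset[0], cm.peak[1] + tpl.com_offset[1])
            ray = pixel_to_ray(bench.geom, "B", pixel)
            t = (rec.estimate - ray.origin) @ ray.direction
            assert np.linalg.norm(ray.point(t) - rec.estimate) < 1e-9

    def test_noiseless_full_schedule_success_above_95(self, tracked_setup):
        bench, tumor, templates, ref = tracked_setup
        series, traj = self._series(bench, tumor, ref, 100)
        sched = gantry_schedule(n_frames=100)
        recs = run_monitoring(
            series, templates, bench.geom, sched,
            MonitoringConfig(
                technique="SE",
                prior_pdf=prior_from_trajectory(traj, ref),
            ),
        )
        assert np.mean([r.error_3d < 3.0 for r in recs]) >= 0.95

    def test_missing_template_rejected(self, tracked_setup):
        bench, tumor, templates, ref = tracked_setup
        series, _ = self._series(bench, tumor, ref, 5)
        sched = gantry_schedule(n_frames=5, blocking_sectors={})
        with pytest.raises(LocalizationError):
            run_monitoring(
                series, {"A": templates["A"]}, bench.geom, sched,
                MonitoringConfig(technique="SE"),
            )

    def test_mono_before_enough_stereo_needs_prior(self, tracked_setup):
        bench, tumor, templates, ref = tracked_setup
        series, traj = self._series(bench, tumor, ref, 5)
        sched = gantry_schedule(
            n_frames=5, blocking_sectors={"B": [(-180.0, 10.0)]}
        )
        with pytest.raises(LocalizationError):
            run_monitoring(
                series, templates, bench.geom, sched,
                MonitoringConfig(technique="SE", prior_pdf=None),
            )
        recs = run_monitoring(
            series, templates, bench.geom, sched,
            MonitoringConfig(
                technique="SE", prior_pdf=prior_from_trajectory(traj, ref)
            ),
        )
        assert all(r.mode == "MONO_A" and r.degenerate for r in recs)
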