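"""Per-frame 3D tumor localization.

When both stereoscopic views see the tumor, the two template-matching rays
are triangulated (common-perpendicular midpoint).  When the rotating linac
gantry blocks one view, the 3D position is estimated monoscopically: a 3D
Gaussian motion PDF — fitted online from the stereoscopic estimates
accumulated so far (with a planning-trajectory prior before enough samples
exist) — is maximised along the single measurement ray.  For the ray
``x(t) = p + t d`` and PDF N(mu, S) the density argmax is the closed form

    t* = d' S^-1 (mu - p) / (d' S^-1 d).

A localization is successful when the 3D error is below 3 mm (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dual_energy import (
    DEFAULT_CUTOFF,
    DEFAULT_WN,
    DEFAULT_WS_GRID,
    ROIPair,
    acnr,
    bone_image,
    log_subtract,
    select_wb,
    select_ws,
)
from .geometry import Ray, StereoGeometry, pixel_to_ray, triangulate
from .matching import (
    Template,
    attenuation_image,
    de_matching_image,
    locate_2d,
    normxcorr,
)

__all__ = [
    "LocalizationError",
    "MotionPDF",
    "GantrySchedule",
    "LocalizationRecord",
    "MonitoringConfig",
    "gantry_schedule",
    "stereo_localize",
    "fit_pdf",
    "monoscopic_estimate",
    "run_monitoring",
    "DEFAULT_BLOCKING_SECTORS",
    "SUCCESS_THRESHOLD_MM",
]

SUCCESS_THRESHOLD_MM = 3.0

# Qualitative VMAT-arc blocking layout: the arc runs -180 deg -> 10 deg and
# alternates stereoscopic and single-view periods as the gantry sweeps
# through the tube lines of sight.
DEFAULT_BLOCKING_SECTORS = {
    "B": [(-150.0, -95.0)],  # gantry blocks Tube B -> MONO_A
    "A": [(-60.0, -5.0)],    # gantry blocks Tube A -> MONO_B
}


class LocalizationError(ValueError):
    pass


@dataclass
class MotionPDF:
    """3D Gaussian motion model in room coordinates (mm, mm^2)."""

    mean: np.ndarray
    covariance: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (3, 3):
            raise LocalizationError("covariance must be 3x3")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-9):
            raise LocalizationError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance)[0] <= 0:
            raise LocalizationError("covariance must be positive definite")


@dataclass
class GantrySchedule:
    """Per-frame view availability: STEREO, MONO_A or MONO_B."""

    modes: list
    gantry_angles: np.ndarray

    def __len__(self) -> int:
        return len(self.modes)


@dataclass
class LocalizationRecord:
    frame_index: int
    mode: str
    estimate: np.ndarray
    truth: np.ndarray | None = None
    error_3d: float = np.nan
    error_axes: np.ndarray | None = None  # (LR, AP, SI) signed, mm
    success: bool = False
    residual: float = np.nan              # stereo triangulation residual
    tie: bool = False
    degenerate: bool = False
    peak_values: dict = field(default_factory=dict)

    def finalize(self, threshold: float = SUCCESS_THRESHOLD_MM) -> None:
        if self.truth is not None:
            diff = self.estimate - self.truth
            self.error_axes = diff
            self.error_3d = float(np.linalg.norm(diff))
            self.success = bool(self.error_3d < threshold)


def gantry_schedule(
    arc_start: float = -180.0,
    arc_stop: float = 10.0,
    n_frames: int = 100,
    blocking_sectors: dict | None = None,
) -> GantrySchedule:
    """Flag each frame of a linear gantry sweep by view availability.

    *blocking_sectors* maps a view label to angle intervals (deg) during
    which the gantry blocks that view's beam; a frame whose gantry angle
    blocks Tube B is MONO_A and vice versa.  Raises if any angle blocks
    both views simultaneously.
    """
    sectors = DEFAULT_BLOCKING_SECTORS if blocking_sectors is None else blocking_sectors
    angles = np.linspace(arc_start, arc_stop, n_frames)

    def blocked(view: str, angle: float) -> bool:
        return any(lo <= angle <= hi for lo, hi in sectors.get(view, []))

    modes = []
    for ang in angles:
        ba, bb = blocked("A", ang), blocked("B", ang)
        if ba and bb:
            raise LocalizationError("both views blocked simultaneously")
        modes.append("MONO_B" if ba else "MONO_A" if bb else "STEREO")
    return GantrySchedule(modes=modes, gantry_angles=angles)


def stereo_localize(
    loc_a: tuple[float, float],
    loc_b: tuple[float, float],
    templates: dict,
    geom: StereoGeometry,
):
    """Triangulate the two per-view matches into a 3D point.

    *loc_a*/*loc_b* are correlation-peak pixel positions; each is shifted
    by its template's center-of-mass offset before ray casting.  Returns
    ``(point, residual)``.
    """
    rays = {}
    for view, loc in (("A", loc_a), ("B", loc_b)):
        tpl: Template = templates[view]
        pixel = (loc[0] + tpl.com_offset[0], loc[1] + tpl.com_offset[1])
        rays[view] = pixel_to_ray(geom, view, pixel)
    return triangulate(rays["A"], rays["B"])


def fit_pdf(samples, floor: float = 0.01, min_samples: int = 5) -> MotionPDF:
    """Sample mean/covariance of 3D positions, eigenvalue-floored.

    The floor (mm^2) keeps the covariance invertible for near-planar or
    near-linear motion such as a rigid phantom arm's coupled axes.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise LocalizationError("samples must be (n, 3)")
    if samples.shape[0] < min_samples:
        raise LocalizationError(
            f"need at least {min_samples} samples to fit the motion PDF"
        )
    mean = samples.mean(axis=0)
    if samples.shape[0] > 1:
        cov = np.cov(samples, rowvar=False)
    else:
        cov = np.zeros((3, 3))
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w, floor)
    cov = (v * w) @ v.T
    cov = 0.5 * (cov + cov.T)
    return MotionPDF(mean=mean, covariance=cov, n_samples=int(samples.shape[0]))


def monoscopic_estimate(ray: Ray, pdf: MotionPDF) -> np.ndarray:
    """Most probable tumor position along a single measurement ray."""
    sinv = np.linalg.inv(pdf.covariance)
    d = ray.direction
    t = float(d @ sinv @ (pdf.mean - ray.origin)) / float(d @ sinv @ d)
    return ray.point(t)


@dataclass
class MonitoringConfig:
    """Knobs for the per-frame monitoring loop."""

    technique: str = "DE"                  # "DE" | "SE"
    rois: dict | None = None               # view -> ROIPair (ws search)
    wb_rois: dict | None = None            # view -> ROIPair (wb search)
    ws_grid: tuple = DEFAULT_WS_GRID
    wn: float = DEFAULT_WN
    cutoff: float = DEFAULT_CUTOFF
    use_acnr: bool = True
    swap_order: bool = False
    fixed_ws: dict | None = None           # view -> ws (skip per-frame search)
    fixed_wb: dict | None = None
    success_threshold: float = SUCCESS_THRESHOLD_MM
    min_pdf_samples: int = 5
    pdf_floor: float = 0.01
    prior_pdf: MotionPDF | None = None


def _matching_image(frame, view: str, cfg: MonitoringConfig, log: dict):
    if cfg.technique == "SE":
        return attenuation_image(frame.images[(view, "SE")])
    ihe = frame.images[(view, "HE")]
    ile = frame.images[(view, "LE")]
    if cfg.fixed_ws is not None:
        ws = cfg.fixed_ws[view]
    else:
        if cfg.rois is None or view not in cfg.rois:
            raise LocalizationError("DE monitoring needs ROIs (or fixed weights)")
        ws = select_ws(ihe, ile, cfg.rois[view], cfg.ws_grid, cfg.swap_order)
    soft = log_subtract(ihe, ile, ws, cfg.swap_order)
    log.setdefault("ws", {}).setdefault(view, []).append(ws)
    if cfg.use_acnr:
        if cfg.fixed_wb is not None:
            wb = cfg.fixed_wb[view]
        else:
            wrois = (cfg.wb_rois or cfg.rois)[view]
            wb = select_wb(ihe, ile, wrois, cfg.ws_grid, cfg.swap_order)
        bone = bone_image(ihe, ile, wb, cfg.swap_order)
        soft = acnr(soft, bone, cfg.wn, cfg.cutoff)
        log.setdefault("wb", {}).setdefault(view, []).append(wb)
    return de_matching_image(soft)


def run_monitoring(
    series,
    templates: dict,
    geom: StereoGeometry,
    schedule: GantrySchedule,
    config: MonitoringConfig | None = None,
    run_log: dict | None = None,
) -> list:
    """Track the tumor over a series, following the gantry schedule.

    Per frame: match in the available view(s); triangulate in STEREO mode
    (and grow the motion-PDF sample buffer); in MONO mode cast the single
    measurement ray and maximise the Gaussian motion PDF along it, falling
    back to the configured prior until ``min_pdf_samples`` stereoscopic
    estimates exist.  Records carry per-frame truth comparisons when the
    series provides ground truth.
    """
    cfg = config or MonitoringConfig()
    if len(schedule) != series.n_frames:
        raise LocalizationError("schedule length does not match series")
    for view in ("A", "B"):
        if view not in templates:
            raise LocalizationError(f"missing template for view {view}")
    log = run_log if run_log is not None else {}
    truth = series.truth()

    records: list[LocalizationRecord] = []
    stereo_buffer: list[np.ndarray] = []
    for i, frame in enumerate(series.frames):
        mode = schedule.modes[i]
        views = ("A", "B") if mode == "STEREO" else (mode[-1],)
        locs, ties, peaks = {}, {}, {}
        for view in views:
            img = _matching_image(frame, view, cfg, log)
            cmap = normxcorr(img, templates[view])
            r, c, tie = locate_2d(cmap)
            locs[view] = (r, c)
            ties[view] = tie
            peaks[view] = cmap.peak_value

        degenerate = False
        residual = np.nan
        if mode == "STEREO":
            est, residual = stereo_localize(locs["A"], locs["B"], templates, geom)
            stereo_buffer.append(est)
        else:
            view = views[0]
            tpl = templates[view]
            r, c = locs[view]
            pixel = (r + tpl.com_offset[0], c + tpl.com_offset[1])
            ray = pixel_to_ray(geom, view, pixel)
            if len(stereo_buffer) >= cfg.min_pdf_samples:
                pdf = fit_pdf(
                    stereo_buffer, cfg.pdf_floor, cfg.min_pdf_samples
                )
            elif cfg.prior_pdf is not None:
                pdf = cfg.prior_pdf
                degenerate = True  # prior fallback flagged
            else:
                raise LocalizationError(
                    "monoscopic frame before enough stereo samples and no prior"
                )
            est = monoscopic_estimate(ray, pdf)

        rec = LocalizationRecord(
            frame_index=i,
            mode=mode,
            estimate=np.asarray(est, dtype=float),
            truth=truth[i] if truth is not None else None,
            residual=float(residual),
            tie=any(ties.values()),
            degenerate=degenerate,
            peak_values=peaks,
        )
        rec.finalize(cfg.success_threshold)
        records.append(rec)
    return records


def prior_from_trajectory(trajectory, tumor_reference, floor: float = 0.01) -> MotionPDF:
    """Planning-trajectory prior PDF (positions = reference + displacement)."""
    pos = np.asarray(tumor_reference, dtype=float)[None, :] + trajectory.positions
    return fit_pdf(pos, floor=floor, min_samples=2)
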