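"""Experiment harness: tumor size / density / mAs sweeps, DE vs SE, and the
success-rate / accuracy / precision metrics.

Success means a 3D localization error strictly below 3 mm.  Accuracy is the
signed per-axis mean of (estimate - truth) and precision its standard
deviation.  Each condition is simulated over the full gantry-arc schedule
with both techniques and several seed replicates (the desk-scale substitute
for repeated physical sessions); regions (STEREO / MONO_A / MONO_B) are
reported separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import phantom as ph
from .dual_energy import ROIPair
from .geometry import StereoGeometry, build_geometry, project_point
from .localization import (
    GantrySchedule,
    LocalizationRecord,
    MonitoringConfig,
    gantry_schedule,
    prior_from_trajectory,
    run_monitoring,
)
from .matching import make_tumor_only_volume, make_template, threshold_contour
from .phantom import (
    RIB,
    SOFT,
    SPINE,
    ThoraxConfig,
    TumorModel,
    breathing_trajectory,
    make_thorax,
    make_tumor,
    place_tumor,
)
from .projector import NOMINAL_MAS, acquire_series, static_path_images

__all__ = [
    "EvaluationError",
    "SweepConfig",
    "ExperimentReport",
    "success_rate",
    "success_rate_by_region",
    "accuracy_precision",
    "records_to_dataframe",
    "auto_rois",
    "auto_wb_rois",
    "run_condition",
    "run_sweep",
]

AXES = ("LR", "AP", "SI")
REGIONS = ("STEREO", "MONO_A", "MONO_B")


class EvaluationError(ValueError):
    pass


def success_rate(records, threshold: float = 3.0) -> float:
    """Fraction of records with 3D error strictly below *threshold* (mm)."""
    if len(records) == 0:
        raise EvaluationError("no records")
    return float(np.mean([r.error_3d < threshold for r in records]))


def success_rate_by_region(records, threshold: float = 3.0) -> dict:
    out = {}
    for region in REGIONS:
        sub = [r for r in records if r.mode == region]
        if sub:
            out[region] = success_rate(sub, threshold)
    out["ALL"] = success_rate(records, threshold)
    return out


def accuracy_precision(records) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis (mean, sd) of the signed localization error (mm)."""
    if len(records) == 0:
        raise EvaluationError("no records")
    diffs = np.array([r.error_axes for r in records])
    return diffs.mean(axis=0), diffs.std(axis=0)


def records_to_dataframe(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "frame": r.frame_index,
            "mode": r.mode,
            "err_3d": r.error_3d,
            "success": r.success,
            "residual": r.residual,
            "tie": r.tie,
            "degenerate": r.degenerate,
        }
        for a, name in enumerate(AXES):
            row[f"est_{name}"] = r.estimate[a]
            if r.truth is not None:
                row[f"tru_{name}"] = r.truth[a]
                row[f"err_{name}"] = r.error_axes[a]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Automated ROI selection for the per-frame weighting-factor search


def auto_rois(
    static_lengths: np.ndarray,
    tumor_center_px: tuple[float, float],
    roi_size: int = 8,
    search_radius: int = 30,
    min_soft_mm: float = 50.0,
) -> ROIPair:
    """Pick a bone ROI and a nearby bone-free soft-tissue ROI.

    Uses the noiseless per-material path-length images of the static thorax
    (the simulator's stand-in for a physicist outlining rib/spine regions
    near the tumor): the bone ROI maximises mean bone path length within
    *search_radius* of the tumor projection, and the soft ROI minimises it
    while staying inside the body (mean soft-tissue path above
    *min_soft_mm*) and not overlapping the bone ROI.
    """
    from .phantom import LUNG

    bone = static_lengths[..., RIB] + static_lengths[..., SPINE]
    soft = static_lengths[..., SOFT]
    lung = static_lengths[..., LUNG]
    k = roi_size
    bmean = ndimage.uniform_filter(bone, size=k, mode="constant")
    smean = ndimage.uniform_filter(soft, size=k, mode="constant")
    lmean = ndimage.uniform_filter(lung, size=k, mode="constant")

    nr, nc = bone.shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    near = (rr - tumor_center_px[0]) ** 2 + (cc - tumor_center_px[1]) ** 2 <= (
        search_radius**2
    )
    # uniform_filter output at (r, c) covers the window centered there;
    # keep centers whose window stays in bounds.
    inb = (
        (rr >= k // 2)
        & (cc >= k // 2)
        & (rr < nr - (k - k // 2 - 1))
        & (cc < nc - (k - k // 2 - 1))
    )
    cand = near & inb
    if not cand.any():
        raise EvaluationError("no ROI candidates near the tumor projection")

    # Jointly pick a high-bone window and a nearby bone-free window whose
    # *tissue* background matches the bone window's.  Bone displaces soft
    # tissue in this anatomy, so the bone path counts as soft-equivalent
    # background; with matched backgrounds the pair contrast isolates the
    # bone-mineral signal the weighting-factor search must cancel.
    bg = smean + 0.26 * lmean + bmean  # water-equivalent background, mm
    bmax = bmean[cand].max()
    if bmax <= 0:
        raise EvaluationError("no bone near the tumor projection")
    bone_cand = np.argwhere(cand & (bmean >= 0.7 * bmax))
    soft_ok = cand & (bmean <= 0.15 * bmax) & (smean >= min_soft_mm)
    if not soft_ok.any():
        soft_ok = cand & (bmean <= 0.3 * bmax)
    if not soft_ok.any():
        raise EvaluationError("could not place a soft-tissue ROI")
    soft_cand = np.argwhere(soft_ok)

    best = (np.inf, None, None)
    for br, bc in bone_cand[:: max(1, len(bone_cand) // 200)]:
        d2 = (soft_cand[:, 0] - br) ** 2 + (soft_cand[:, 1] - bc) ** 2
        nonoverlap = (np.abs(soft_cand[:, 0] - br) >= k) | (
            np.abs(soft_cand[:, 1] - bc) >= k
        )
        if not nonoverlap.any():
            continue
        mism = np.abs(bg[soft_cand[:, 0], soft_cand[:, 1]] - bg[br, bc]) + 0.005 * np.sqrt(d2)
        mism = np.where(nonoverlap, mism, np.inf)
        j = int(np.argmin(mism))
        if mism[j] < best[0]:
            best = (float(mism[j]), (int(br), int(bc)), tuple(soft_cand[j]))
    if best[1] is None:
        raise EvaluationError("could not place a soft-tissue ROI")
    (br, bc), (sr, sc) = best[1], best[2]
    sr, sc = int(sr), int(sc)

    def rect(r, c):
        r0, c0 = r - k // 2, c - k // 2
        return ((int(r0), int(r0 + k)), (int(c0), int(c0 + k)))

    return ROIPair(bone=rect(br, bc), soft=rect(sr, sc))


def auto_wb_rois(
    static_lengths: np.ndarray,
    tumor_center_px: tuple[float, float],
    roi_size: int = 8,
    search_radius: int = 30,
) -> ROIPair:
    """ROI pair for the bone-image weight: soft window WITH structure.

    The bone-image weight is chosen to suppress soft-tissue structure, so
    its metric window must contain genuine soft/lung contrast (e.g. a lung
    boundary); a uniform window would let quantum noise drive the search.
    The bone window is the strongest bone region near the tumor, as for
    the soft-tissue weight.
    """
    from .phantom import LUNG

    bone = static_lengths[..., RIB] + static_lengths[..., SPINE]
    soft = static_lengths[..., SOFT]
    lung = static_lengths[..., LUNG]
    k = roi_size
    bmean = ndimage.uniform_filter(bone, size=k, mode="constant")
    bg = soft + 0.26 * lung
    bgm = ndimage.uniform_filter(bg, size=k, mode="constant")
    bgv = np.maximum(
        ndimage.uniform_filter(bg * bg, size=k, mode="constant") - bgm**2, 0.0
    )

    nr, nc = bone.shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    near = (rr - tumor_center_px[0]) ** 2 + (cc - tumor_center_px[1]) ** 2 <= (
        search_radius**2
    )
    inb = (
        (rr >= k // 2)
        & (cc >= k // 2)
        & (rr < nr - (k - k // 2 - 1))
        & (cc < nc - (k - k // 2 - 1))
    )
    cand = near & inb
    if not cand.any():
        raise EvaluationError("no ROI candidates near the tumor projection")
    bscore = np.where(cand, bmean, -np.inf)
    br, bc = np.unravel_index(int(np.argmax(bscore)), bscore.shape)
    overlap = (np.abs(rr - br) < k) & (np.abs(cc - bc) < k)
    ok = cand & ~overlap & (bmean <= 0.15 * max(bmean[br, bc], 1e-9))
    if not ok.any():
        ok = cand & ~overlap
    sscore = np.where(ok, bgv, -np.inf)
    sr, sc = np.unravel_index(int(np.argmax(sscore)), sscore.shape)

    def rect(r, c):
        r0, c0 = r - k // 2, c - k // 2
        return ((int(r0), int(r0 + k)), (int(c0), int(c0 + k)))

    return ROIPair(bone=rect(br, bc), soft=rect(int(sr), int(sc)))


# ---------------------------------------------------------------------------
# Sweeps


@dataclass
class SweepConfig:
    """Study conditions for the desk-scale experiment matrix.

    Defaults mirror the imaging protocol being emulated (100 frames at
    1.67 Hz, ~20/5/5 mm SI/AP/LR motion, four tumor diameters, three
    printed densities, half/nominal/double mAs) at a 128 x 128 detector
    sampling of the same panel area.
    """

    detector_shape: tuple[int, int] = (128, 128)
    pixel_pitch: float = 1.6
    n_frames: int = 100
    frame_rate: float = 1.67
    period_s: float = 4.0
    amplitudes: tuple[float, float, float] = (5.0, 5.0, 20.0)
    variability: float = 0.05
    drift_mm_per_min: float = 0.0
    diameters_mm: tuple = (10.0, 20.0, 26.0, 33.0)
    densities_hu: tuple = ((140.0, 35.0), (-212.0, 246.0), (-434.0, 277.0))
    mas_factors: tuple = (("half", 0.5), ("nominal", 1.0), ("double", 2.0))
    base_diameter_mm: float = 26.0
    base_density_hu: tuple[float, float] = (140.0, 35.0)
    techniques: tuple = ("DE", "SE")
    n_seeds: int = 5
    tumor_spacing_mm: float = 1.0
    roi_size: int = 8
    roi_search: int = 30
    wb_roi_search: int = 60  # soft-structure window may sit farther out
    thorax: ThoraxConfig = field(default_factory=ThoraxConfig)


@dataclass
class ExperimentReport:
    """Aggregated sweep results plus run metadata."""

    table: pd.DataFrame
    sweep: str
    seed: int
    config: SweepConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "sweep": self.sweep,
            "seed": self.seed,
            "rows": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _child_seed(master: int, *keys) -> int:
    import zlib

    tags = [zlib.crc32(repr(k).encode()) & 0x7FFFFFFF for k in keys]
    ss = np.random.SeedSequence([int(master)] + tags)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class _Bench:
    """Shared per-sweep fixtures: thorax, geometry, static paths."""

    cfg: SweepConfig
    geom: StereoGeometry
    thorax: ph.VoxelPhantom
    static_paths: dict

    @classmethod
    def build(cls, cfg: SweepConfig) -> "_Bench":
        geom = build_geometry(
            pixel_pitch=cfg.pixel_pitch, detector_shape=cfg.detector_shape
        )
        thorax = make_thorax(cfg.thorax)
        return cls(
            cfg=cfg,
            geom=geom,
            thorax=thorax,
            static_paths=static_path_images(thorax, geom),
        )


def _prepare_tumor(bench: _Bench, diameter: float, density: tuple[float, float]):
    """Tumor model + per-view templates from the stamped planning CT."""
    cfg = bench.cfg
    hu_mean, hu_sd = density
    tumor = make_tumor(
        diameter,
        hu_mean,
        hu_sd,
        shape_seed=int(diameter * 10),
        spacing=cfg.tumor_spacing_mm,
    )
    ref = np.asarray(cfg.thorax.tumor_reference, dtype=float)
    planning = place_tumor(bench.thorax, tumor, ref)
    lung_hu = ph.MATERIAL_HU[ph.LUNG]
    threshold = 0.5 * (lung_hu + hu_mean)
    gtv = threshold_contour(planning, threshold)
    tumor_only = make_tumor_only_volume(planning, gtv)
    templates = {
        v: make_template(tumor_only, bench.geom, v, source_tumor=f"d{diameter:g}")
        for v in ("A", "B")
    }
    return tumor, templates, ref


def run_condition(
    bench: _Bench,
    tumor: TumorModel,
    templates: dict,
    tumor_reference: np.ndarray,
    technique: str,
    mas_factor: float,
    schedule: GantrySchedule,
    traj_seed: int,
    noise_seed: int,
    window_cache: dict | None = None,
) -> list:
    """Simulate one series and track it; returns LocalizationRecords."""
    cfg = bench.cfg
    traj = breathing_trajectory(
        n_frames=cfg.n_frames,
        frame_rate=cfg.frame_rate,
        period=cfg.period_s,
        amplitudes=cfg.amplitudes,
        baseline_drift=cfg.drift_mm_per_min,
        variability=cfg.variability,
        seed=traj_seed,
    )
    mas = {e: m * mas_factor for e, m in NOMINAL_MAS[technique].items()}
    series = acquire_series(
        bench.thorax,
        tumor,
        traj,
        bench.geom,
        protocol=technique,
        mAs_settings=mas,
        seed=noise_seed,
        tumor_reference=tumor_reference,
        frame_rate=cfg.frame_rate,
        static_paths=bench.static_paths,
        window_cache=window_cache,
    )
    rois, wb_rois = {}, {}
    if technique == "DE":
        for v in ("A", "B"):
            center = project_point(bench.geom, v, tumor_reference)
            rois[v] = auto_rois(
                bench.static_paths[v][0],
                center,
                roi_size=cfg.roi_size,
                search_radius=cfg.roi_search,
            )
            wb_rois[v] = auto_wb_rois(
                bench.static_paths[v][0],
                center,
                roi_size=cfg.roi_size,
                search_radius=cfg.wb_roi_search,
            )
    mon = MonitoringConfig(
        technique=technique,
        rois=rois or None,
        wb_rois=wb_rois or None,
        prior_pdf=prior_from_trajectory(traj, tumor_reference),
    )
    return run_monitoring(series, templates, bench.geom, schedule, mon)


def _aggregate(rows_records, sweep, condition, technique, cfg) -> list:
    """Per-region aggregation across seed replicates."""
    out = []
    for region in REGIONS + ("ALL",):
        rates, accs, precs, n_tot = [], [], [], 0
        for recs in rows_records:
            sub = recs if region == "ALL" else [r for r in recs if r.mode == region]
            if not sub:
                continue
            rates.append(success_rate(sub))
            a, p = accuracy_precision(sub)
            accs.append(a)
            precs.append(p)
            n_tot += len(sub)
        if not rates:
            continue
        acc = np.mean(accs, axis=0)
        prec = np.mean(precs, axis=0)
        mean_abs_si = np.mean(
            [
                np.mean(
                    [
                        abs(r.error_axes[2])
                        for r in (recs if region == "ALL" else [x for x in recs if x.mode == region])
                    ]
                )
                for recs in rows_records
            ]
        )
        row = {
            "sweep": sweep,
            "condition": condition,
            "technique": technique,
            "region": region,
            "success_rate": float(np.mean(rates)),
            "success_rate_sd": float(np.std(rates)),
            "mean_abs_err_SI": float(mean_abs_si),
            "n_frames": int(n_tot),
            "n_seeds": len(rates),
        }
        for a, name in enumerate(AXES):
            row[f"accuracy_{name}"] = float(acc[a])
            row[f"precision_{name}"] = float(prec[a])
        out.append(row)
    return out


def run_sweep(
    sweep: str,
    config: SweepConfig | None = None,
    seed: int = 0,
    bench: _Bench | None = None,
    keep_records: bool = False,
):
    """Run one experiment sweep ('size', 'density' or 'mAs').

    Returns an :class:`ExperimentReport`; with ``keep_records=True`` the
    per-frame :class:`LocalizationRecord` lists are attached as
    ``report.records[(condition, technique, replicate)]``.
    """
    cfg = config or SweepConfig()
    if bench is None:
        bench = _Bench.build(cfg)
    if sweep == "size":
        conditions = [
            (f"d={d / 10:g}cm", d, cfg.base_density_hu, 1.0) for d in cfg.diameters_mm
        ]
    elif sweep == "density":
        conditions = [
            (f"hu={hu:g}", cfg.base_diameter_mm, (hu, sd), 1.0)
            for hu, sd in cfg.densities_hu
        ]
    elif sweep == "mAs":
        conditions = [
            (f"mAs={name}", cfg.base_diameter_mm, cfg.base_density_hu, fac)
            for name, fac in cfg.mas_factors
        ]
    else:
        raise EvaluationError(f"unknown sweep {sweep!r}")

    schedule = gantry_schedule(n_frames=cfg.n_frames)
    rows, all_records = [], {}
    for label, diameter, density, mas_factor in conditions:
        tumor, templates, ref = _prepare_tumor(bench, diameter, density)
        # tumor projection windows are reused across techniques and mAs
        # settings whenever replicates share a trajectory
        caches: dict[int, dict] = {}
        for technique in cfg.techniques:
            per_seed = []
            for rep in range(cfg.n_seeds):
                # DE and SE replicates share the breathing trajectory (the
                # separate-but-identical-cycles acquisition) but draw
                # independent quantum noise.
                recs = run_condition(
                    bench,
                    tumor,
                    templates,
                    ref,
                    technique,
                    mas_factor,
                    schedule,
                    traj_seed=_child_seed(seed, label, rep, "traj"),
                    noise_seed=_child_seed(seed, label, rep, technique, "noise"),
                    window_cache=caches.setdefault(rep, {}),
                )
                per_seed.append(recs)
                if keep_records:
                    all_records[(label, technique, rep)] = recs
            rows.extend(_aggregate(per_seed, sweep, label, technique, cfg))
    report = ExperimentReport(
        table=pd.DataFrame(rows), sweep=sweep, seed=int(seed), config=cfg
    )
    if keep_records:
        report.records = all_records
    return report
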