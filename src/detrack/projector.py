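"""Stereoscopic x-ray projection simulator.

Forms high-, low-, and single-energy 2D projections of the breathing
phantom: exact Siddon voxel traversal accumulates per-material path
lengths, Beer-Lambert attenuation with one effective monoenergy per kVp
setting converts them to expected detector counts, and mAs-scaled Poisson
sampling adds quantum noise.  The static thorax is traced once per view;
the rigidly moving tumor is re-projected per frame at its continuous pose
over its detector footprint only.

Energy labels: LE (low, ~60 kVp), SE (single, ~120 kVp), HE (high,
~140 kVp), reduced to effective monoenergies of 40 / 60 / 70 keV in the
built-in attenuation table.  Tumor voxels attenuate like soft tissue scaled
by (1 + HU/1000), which makes the printed-density sweeps change projection
contrast in the simplified physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Ray, StereoGeometry, project_point
from .phantom import (
    AIR,
    LUNG,
    N_MATERIALS,
    TUMOR,
    Trajectory,
    TumorModel,
    VoxelPhantom,
)

__all__ = [
    "ProjectorError",
    "AttenuationTable",
    "DEFAULT_ATTENUATION",
    "ProjectionImage",
    "Frame",
    "ImagingSeries",
    "siddon_path_lengths",
    "material_path_images",
    "simulate_projection",
    "acquire_series",
    "NOMINAL_MAS",
    "I0_PER_MAS",
]

ENERGY_INDEX = {"LE": 0, "SE": 1, "HE": 2}

# Nominal acquisition settings: DE = (HE 140 kVp / 8 mAs, LE 60 kVp /
# 25 mAs), SE = 120 kVp / 16 mAs.
NOMINAL_MAS = {"DE": {"HE": 8.0, "LE": 25.0}, "SE": {"SE": 16.0}}

# Detector gain: expected counts per pixel per mAs in the unattenuated
# beam.  Chosen so the lung-region signal-to-noise ratio at the nominal SE
# technique is ~50 for the default thorax (see docs/methods.md).
I0_PER_MAS = 4.2e3

_CHUNK = 4096  # rays per traversal batch (memory / speed trade-off)


class ProjectorError(ValueError):
    pass


@dataclass(frozen=True)
class AttenuationTable:
    """Linear attenuation coefficients mu (1/mm) per material and energy.

    ``mu[material_id, ENERGY_INDEX[label]]``.  The tumor row is the
    unmodulated (HU = 0) soft-tissue coefficient; per-voxel HU modulation is
    applied via the path integral of HU/1000 along tumor voxels.
    """

    mu: np.ndarray  # (N_MATERIALS, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.mu, dtype=float)
        if m.shape != (N_MATERIALS, 3):
            raise ProjectorError(f"mu table must be {(N_MATERIALS, 3)}")
        object.__setattr__(self, "mu", m)

    def coeff(self, material: int, energy_label: str) -> float:
        try:
            return float(self.mu[material, ENERGY_INDEX[energy_label]])
        except KeyError as exc:
            raise ProjectorError(f"unknown energy label {energy_label!r}") from exc


# Effective monoenergy mu values (1/mm) at 40 / 60 / 70 keV.  Air, lung
# (~0.26 g/cc) and soft tissue (~water) use water-scaled coefficients; rib
# and spine are modeled as soft tissue plus a mineral fraction of cortical
# bone (0.20 and 0.25 of the cortical excess) — vertebral bodies and ribs
# are mostly marrow and trabecular bone, far below cortical density.  With
# a single mineral component, one weighting factor cancels both rib and
# spine in the log subtraction (ws* = mineral-excess HE/LE ratio ~ 0.33).
# The tumor row is the soft-tissue baseline, HU-modulated per voxel.
DEFAULT_ATTENUATION = AttenuationTable(
    mu=np.array(
        [
            #  LE       SE       HE
            [0.0, 0.0, 0.0],              # air
            [0.00697, 0.00536, 0.00502],  # lung
            [0.0268, 0.0206, 0.0193],     # soft tissue
            [0.0470, 0.0286, 0.0259],     # rib
            [0.0520, 0.0306, 0.0276],     # spine
            [0.0268, 0.0206, 0.0193],     # tumor (HU-modulated soft)
        ]
    )
)


@dataclass
class ProjectionImage:
    """One detector frame (counts)."""

    pixels: np.ndarray
    view: str
    energy_label: str
    mAs: float
    frame_index: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if np.any(self.pixels < 0):
            raise ProjectorError("projection pixels must be non-negative")


@dataclass
class Frame:
    index: int
    time: float
    displacement: np.ndarray  # (3,) mm ground-truth tumor displacement
    images: dict = field(default_factory=dict)  # (view, energy) -> ProjectionImage


@dataclass
class ImagingSeries:
    """A real-time acquisition: per-frame projections for both views."""

    frames: list
    protocol: str                  # "DE" | "SE"
    mAs: dict
    tumor_reference: np.ndarray    # (3,) mm
    trajectory: Trajectory
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def truth(self) -> np.ndarray:
        """(n, 3) continuous ground-truth tumor positions (mm, room)."""
        return self.tumor_reference[None, :] + self.trajectory.positions


# ---------------------------------------------------------------------------
# Siddon traversal


def _batch_paths(
    labels: np.ndarray,
    hu: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
    source: np.ndarray,
    dirs: np.ndarray,
    materials=None,
):
    """Exact per-material path lengths for rays from one source.

    Parameters are the voxel grid (labels/hu, mm spacing, room-mm origin of
    voxel (0,0,0) center), the common ray origin, and unit directions
    (N, 3).  Returns ``(lengths (N, N_MATERIALS) mm, hu_term (N,) mm)``
    where *hu_term* is the path integral of HU/1000 over tumor voxels.

    Implementation: all grid-plane crossing parameters per ray are clipped
    to the ray's bounding-box interval, sorted, and segment midpoints are
    mapped to voxels (the Siddon construction, vectorised over rays).
    """
    shape = labels.shape
    n = dirs.shape[0]
    out_len = np.zeros((n, N_MATERIALS))
    out_hu = np.zeros(n)

    for s in range(0, n, _CHUNK):
        d = dirs[s : s + _CHUNK]
        m = d.shape[0]
        t0 = np.zeros(m)
        t1 = np.full(m, np.inf)
        t_cols = []
        for a in range(3):
            planes = origin[a] - spacing[a] / 2 + np.arange(shape[a] + 1) * spacing[a]
            da = d[:, a]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (planes[None, :] - source[a]) / da[:, None]
            par = da == 0.0
            tlo = np.minimum(t[:, 0], t[:, -1])
            thi = np.maximum(t[:, 0], t[:, -1])
            inside = (source[a] >= planes[0]) & (source[a] <= planes[-1])
            tlo = np.where(par, -np.inf if inside else np.inf, tlo)
            thi = np.where(par, np.inf if inside else -np.inf, thi)
            t0 = np.maximum(t0, tlo)
            t1 = np.minimum(t1, thi)
            t_cols.append(t)

        miss = (t1 <= t0) | ~np.isfinite(t0) | ~np.isfinite(t1)
        t0 = np.where(miss, 0.0, t0)  # rays missing the grid collapse
        t1 = np.where(miss, 0.0, t1)
        T = np.concatenate(t_cols + [t0[:, None], t1[:, None]], axis=1)
        T = np.where(np.isfinite(T), T, t0[:, None])
        T = np.clip(T, t0[:, None], t1[:, None])
        T.sort(axis=1)
        dt = np.diff(T, axis=1)
        mid = T[:, :-1] + 0.5 * dt
        pos = source[None, None, :] + mid[..., None] * d[:, None, :]
        idx = np.floor((pos - origin) / spacing + 0.5).astype(np.int64)
        for a in range(3):
            np.clip(idx[..., a], 0, shape[a] - 1, out=idx[..., a])
        lab = labels[idx[..., 0], idx[..., 1], idx[..., 2]]
        for mat in materials if materials is not None else range(N_MATERIALS):
            out_len[s : s + _CHUNK, mat] = np.sum(dt * (lab == mat), axis=1)
        tmask = lab == TUMOR
        if tmask.any():
            hvals = hu[idx[..., 0], idx[..., 1], idx[..., 2]]
            out_hu[s : s + _CHUNK] = np.sum(dt * tmask * (hvals / 1000.0), axis=1)
    return out_len, out_hu


def siddon_path_lengths(phantom: VoxelPhantom, ray: Ray):
    """Per-material path lengths (mm) of one ray through the phantom.

    Returns ``(lengths, hu_term)``: *lengths* is an array over material ids
    and *hu_term* the HU/1000-weighted tumor path integral.  A ray missing
    the grid bounding box yields all zeros.
    """
    lengths, hu_term = _batch_paths(
        phantom.labels,
        phantom.hu,
        phantom.spacing,
        phantom.origin,
        np.asarray(ray.origin, dtype=float),
        np.asarray(ray.direction, dtype=float)[None, :],
    )
    return lengths[0], float(hu_term[0])


def _detector_dirs(geom: StereoGeometry, view: str, rows: np.ndarray, cols: np.ndarray):
    vg = geom[view]
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pos = vg.pixel_position(rr.ravel(), cc.ravel())
    d = pos - vg.source
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d


def material_path_images(
    phantom: VoxelPhantom,
    geom: StereoGeometry,
    view: str,
    rows: np.ndarray | None = None,
    cols: np.ndarray | None = None,
):
    """Per-pixel material path lengths for a full or windowed detector.

    Returns ``(lengths (nr, nc, N_MATERIALS), hu_term (nr, nc))``.
    """
    vg = geom[view]
    if rows is None:
        rows = np.arange(vg.shape[0])
    if cols is None:
        cols = np.arange(vg.shape[1])
    dirs = _detector_dirs(geom, view, rows, cols)
    lengths, hu_term = _batch_paths(
        phantom.labels, phantom.hu, phantom.spacing, phantom.origin, vg.source, dirs
    )
    nr, nc = len(rows), len(cols)
    return lengths.reshape(nr, nc, N_MATERIALS), hu_term.reshape(nr, nc)


def effective_optical_depth(
    lengths: np.ndarray, hu_term: np.ndarray, table: AttenuationTable, energy: str
) -> np.ndarray:
    """Beer-Lambert exponent: sum_m mu_m L_m + mu_tumor * integral(HU/1000)."""
    if energy not in ENERGY_INDEX:
        raise ProjectorError(f"unknown energy label {energy!r}")
    mu = table.mu[:, ENERGY_INDEX[energy]]
    return lengths @ mu + mu[TUMOR] * hu_term


def simulate_projection(
    phantom: VoxelPhantom,
    geom: StereoGeometry,
    view: str,
    energy_label: str,
    mAs: float,
    I0_per_mAs: float = I0_PER_MAS,
    noise_seed: int | None = None,
    table: AttenuationTable = DEFAULT_ATTENUATION,
    frame_index: int = 0,
    time: float = 0.0,
) -> ProjectionImage:
    """Simulate one full-detector projection of a (possibly tumor-stamped)
    phantom; ``noise_seed=None`` returns the noiseless expectation."""
    lengths, hu_term = material_path_images(phantom, geom, view)
    tau = effective_optical_depth(lengths, hu_term, table, energy_label)
    lam = I0_per_mAs * mAs * np.exp(-tau)
    if noise_seed is not None:
        lam = np.random.default_rng(noise_seed).poisson(lam).astype(float)
    return ProjectionImage(
        pixels=lam,
        view=view,
        energy_label=energy_label,
        mAs=float(mAs),
        frame_index=frame_index,
        time=time,
    )


# ---------------------------------------------------------------------------
# Moving-tumor series


def _tumor_volume(tumor: TumorModel):
    labels = np.where(tumor.mask, TUMOR, AIR).astype(np.uint8)
    return labels, tumor.hu


def tumor_path_window(
    tumor: TumorModel,
    geom: StereoGeometry,
    view: str,
    center: np.ndarray,
    margin_px: int = 4,
):
    """Tumor-only path lengths over the tumor's detector footprint.

    *center* is the tumor center-of-mass position in room mm.  Returns
    ``(rows, cols, L_tumor (nr, nc), hu_term (nr, nc))`` where rows/cols
    index the full detector.
    """
    vg = geom[view]
    labels, hu = _tumor_volume(tumor)
    origin = np.asarray(center, dtype=float) + tumor.local_origin()
    half = tumor.max_diameter / 2.0 + tumor.spacing
    corners = center + half * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    rc = np.array([project_point(geom, view, c) for c in corners])
    r0 = max(int(np.floor(rc[:, 0].min())) - margin_px, 0)
    r1 = min(int(np.ceil(rc[:, 0].max())) + margin_px, vg.shape[0] - 1)
    c0 = max(int(np.floor(rc[:, 1].min())) - margin_px, 0)
    c1 = min(int(np.ceil(rc[:, 1].max())) + margin_px, vg.shape[1] - 1)
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    dirs = _detector_dirs(geom, view, rows, cols)
    lengths, hu_term = _batch_paths(
        labels, hu, np.full(3, tumor.spacing), origin, vg.source, dirs,
        materials=(TUMOR,),
    )
    nr, nc = len(rows), len(cols)
    return rows, cols, lengths[:, TUMOR].reshape(nr, nc), hu_term.reshape(nr, nc)


def acquire_series(
    phantom: VoxelPhantom,
    tumor: TumorModel,
    trajectory: Trajectory,
    geom: StereoGeometry,
    protocol: str = "DE",
    mAs_settings: dict | None = None,
    seed: int | None = 0,
    tumor_reference=(-50.0, 0.0, 0.0),
    I0_per_mAs: float = I0_PER_MAS,
    table: AttenuationTable = DEFAULT_ATTENUATION,
    frame_rate: float = 1.67,
    phase_offset_s: float = 0.0,
    static_paths: dict | None = None,
    views: tuple[str, ...] = ("A", "B"),
    window_cache: dict | None = None,
) -> ImagingSeries:
    """Acquire a real-time series of the moving tumor in both views.

    For the DE protocol, HE and LE frames are generated at identical
    trajectory phases (the zero-misregistration idealisation of two
    identical breathing cycles); *phase_offset_s* shifts the LE trajectory
    to study misregistration.  *phantom* must be the static thorax without
    the tumor stamped; the tumor is projected separately at its continuous
    per-frame pose.  ``seed=None`` yields noiseless frames.

    *static_paths* may carry precomputed ``material_path_images`` per view
    (as returned by :func:`static_path_images`) to amortise the thorax
    traversal across series.
    """
    if protocol not in ("DE", "SE"):
        raise ProjectorError(f"unknown protocol {protocol!r}")
    mAs_settings = dict(mAs_settings or NOMINAL_MAS[protocol])
    energies = ("HE", "LE") if protocol == "DE" else ("SE",)
    if set(energies) - set(mAs_settings):
        raise ProjectorError("mAs settings do not cover the protocol energies")

    ref = np.asarray(tumor_reference, dtype=float)
    if static_paths is None:
        static_paths = static_path_images(phantom, geom, views)

    # Trajectory per energy (LE optionally phase-shifted).
    pos_by_energy = {}
    for e in energies:
        if e == "LE" and phase_offset_s != 0.0:
            tt = trajectory.times + phase_offset_s
            pos = np.stack(
                [
                    np.interp(tt, trajectory.times, trajectory.positions[:, a])
                    for a in range(3)
                ],
                axis=1,
            )
        else:
            pos = trajectory.positions
        pos_by_energy[e] = pos

    rng = np.random.default_rng(seed) if seed is not None else None
    mu = table.mu
    frames = []
    for i in range(trajectory.n_frames):
        t = float(trajectory.times[i])
        frame = Frame(index=i, time=t, displacement=trajectory.positions[i].copy())
        for view in views:
            st_len, st_hu = static_paths[view]
            # Tumor windows per distinct pose (shared between HE/LE frames
            # at the same phase, and across series via window_cache).
            win_by_energy = window_cache if window_cache is not None else {}
            for e in energies:
                key = (view, tuple(np.round(pos_by_energy[e][i], 9)))
                if key not in win_by_energy:
                    win_by_energy[key] = tumor_path_window(
                        tumor, geom, view, ref + pos_by_energy[e][i]
                    )
                rows, cols, lt, ht = win_by_energy[key]
                ei = ENERGY_INDEX[e]
                tau = st_len @ mu[:, ei] + mu[TUMOR, ei] * st_hu
                # replace lung by HU-modulated tumor along the tumor path
                delta = (mu[TUMOR, ei] - mu[LUNG, ei]) * lt + mu[TUMOR, ei] * ht
                tau = tau.copy()
                tau[np.ix_(rows, cols)] += delta
                lam = I0_per_mAs * mAs_settings[e] * np.exp(-tau)
                if rng is not None:
                    lam = rng.poisson(lam).astype(float)
                frame.images[(view, e)] = ProjectionImage(
                    pixels=lam,
                    view=view,
                    energy_label=e,
                    mAs=mAs_settings[e],
                    frame_index=i,
                    time=t,
                )
        frames.append(frame)
    return ImagingSeries(
        frames=frames,
        protocol=protocol,
        mAs=mAs_settings,
        tumor_reference=ref,
        trajectory=trajectory,
        frame_rate=frame_rate,
    )


def static_path_images(
    phantom: VoxelPhantom, geom: StereoGeometry, views: tuple[str, ...] = ("A", "B")
) -> dict:
    """Precompute thorax path images per view (reusable across series)."""
    return {v: material_path_images(phantom, geom, v) for v in views}
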