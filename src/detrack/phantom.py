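"""Digital breathing-thorax phantom.

Replaces the physical anthropomorphic phantom + motion stage with a labeled
voxel thorax (soft-tissue torso, two lungs, spine, periodic ribs), seeded
asymmetric tumor models, and a parametric breathing trajectory whose
amplitude scale matches typical lung motion (~20 mm SI, ~5 mm AP/LR
peak-to-peak).  All room coordinates follow the (LR, AP, SI) convention of
:mod:`detrack.geometry`; volume arrays are indexed ``[ix, iy, iz]`` along
those axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "MATERIALS",
    "MATERIAL_HU",
    "PhantomError",
    "TumorModel",
    "VoxelPhantom",
    "Trajectory",
    "ThoraxConfig",
    "make_tumor",
    "make_thorax",
    "breathing_trajectory",
    "place_tumor",
    "load_trajectory_csv",
    "save_trajectory_csv",
]


class PhantomError(ValueError):
    pass


# Material ids; order matters for the projector's per-material path arrays.
MATERIALS = {"air": 0, "lung": 1, "soft_tissue": 2, "rib": 3, "spine": 4, "tumor": 5}
N_MATERIALS = 6
AIR, LUNG, SOFT, RIB, SPINE, TUMOR = range(6)

# Nominal HU per material (tumor HU comes from the TumorModel).
MATERIAL_HU = {AIR: -1000.0, LUNG: -740.0, SOFT: 40.0, RIB: 700.0, SPINE: 1000.0}


@dataclass
class TumorModel:
    """A rigid tumor: boolean mask on its own local grid, plus HU texture.

    The local frame origin is the mask's center voxel; ``points()`` returns
    voxel-center coordinates (mm) of mask voxels relative to the tumor
    center of mass.
    """

    mask: np.ndarray          # 3D bool
    hu: np.ndarray            # 3D float, valid where mask
    spacing: float            # mm (isotropic local grid)
    max_diameter: float       # mm, max axis-aligned caliper extent
    hu_mean: float
    hu_sd: float
    shape_seed: int

    @property
    def volume_cm3(self) -> float:
        return float(self.mask.sum()) * self.spacing**3 / 1000.0

    def centroid_index(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return idx.mean(axis=0)

    def local_origin(self) -> np.ndarray:
        """Coordinates (mm) of voxel (0,0,0) center so COM is at 0."""
        return -self.centroid_index() * self.spacing


@dataclass
class VoxelPhantom:
    """Labeled material volume with HU, indexed [LR, AP, SI]."""

    labels: np.ndarray        # 3D uint8
    hu: np.ndarray            # 3D float
    spacing: np.ndarray       # (3,) mm/voxel
    origin: np.ndarray        # (3,) mm, room coords of voxel (0,0,0) center
    slice_thickness: float = 2.5

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.shape != self.hu.shape:
            raise PhantomError("labels and hu must have identical shape")
        if np.any(self.spacing <= 0):
            raise PhantomError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def copy(self) -> "VoxelPhantom":
        return replace(self, labels=self.labels.copy(), hu=self.hu.copy())


@dataclass
class Trajectory:
    """Per-frame rigid tumor displacement from its reference position."""

    times: np.ndarray      # (n,) s
    positions: np.ndarray  # (n, 3) mm displacement (LR, AP, SI)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.positions)
        ):
            raise PhantomError("trajectory must be finite")
        if self.positions.shape != (self.times.size, 3):
            raise PhantomError("positions must be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def peak_to_peak(self) -> np.ndarray:
        return self.positions.max(axis=0) - self.positions.min(axis=0)


# ---------------------------------------------------------------------------
# Tumor generation


def _draw_lobes(rng: np.random.Generator, n_lobes: int, amplitude: float):
    """Random smooth angular lobes: (unit centers, amplitudes, widths)."""
    centers = rng.normal(size=(n_lobes, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    amps = rng.uniform(0.3, 1.0, size=n_lobes) * amplitude
    widths = rng.uniform(0.4, 0.9, size=n_lobes)  # rad
    return centers, amps, widths


def _lobed_radius(dirs: np.ndarray, lobes, semi_axes: np.ndarray) -> np.ndarray:
    """Radius of a lobe-perturbed ellipsoid along each unit direction."""
    with np.errstate(divide="ignore"):
        base = 1.0 / np.sqrt(((dirs / semi_axes) ** 2).sum(axis=-1))
    centers, amps, widths = lobes
    pert = np.zeros(len(dirs))
    if len(amps):
        ang = np.arccos(np.clip(dirs @ centers.T, -1.0, 1.0))
        pert = (amps * np.exp(-(ang**2) / (2 * widths[None, :] ** 2))).sum(axis=1)
    return base * (1.0 + pert)


def make_tumor(
    max_diameter: float,
    hu_mean: float,
    hu_sd: float,
    shape_seed: int = 0,
    spacing: float = 1.0,
    n_lobes: int = 4,
    perturbation: float = 0.25,
    axis_ratio_range: tuple[float, float] = (0.7, 1.0),
) -> TumorModel:
    """Generate an asymmetric connected tumor blob.

    A random ellipsoid (semi-axis ratios drawn from *axis_ratio_range*) is
    perturbed by a few smooth angular lobes, then uniformly scaled so the
    maximum axis-aligned caliper extent equals *max_diameter*.  Per-voxel HU
    is drawn from N(hu_mean, hu_sd), clipped to [-1000, 3000].

    With ``perturbation=0`` and ``axis_ratio_range=(1, 1)`` the blob reduces
    to a sphere of diameter *max_diameter*.
    """
    if max_diameter <= 2 * spacing:
        raise PhantomError("tumor diameter below resolvable size")
    rng = np.random.default_rng(shape_seed)
    ratios = rng.uniform(*axis_ratio_range, size=3)
    ratios /= ratios.max()
    semi = ratios  # unit-scale semi-axes

    # Dense direction sampling (Fibonacci sphere) to measure caliper extents.
    k = np.arange(4000) + 0.5
    phi = np.arccos(1 - 2 * k / 4000)
    theta = np.pi * (1 + 5**0.5) * k
    dirs = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )
    lobes = (
        _draw_lobes(rng, n_lobes, perturbation)
        if perturbation > 0 and n_lobes > 0
        else (np.zeros((0, 3)), np.zeros(0), np.zeros(0))
    )
    radii = _lobed_radius(dirs, lobes, semi)
    surface = radii[:, None] * dirs
    extent = surface.max(axis=0) - surface.min(axis=0)
    scale = max_diameter / extent.max()

    half = max_diameter / 2.0 + 2 * spacing
    n = int(np.ceil(2 * half / spacing)) | 1  # odd grid, centered
    ax = (np.arange(n) - (n - 1) / 2.0) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    u = pts / np.maximum(r, 1e-12)[:, None]
    rmax = _lobed_radius(u, lobes, semi) * scale
    mask = (r <= rmax).reshape(n, n, n)
    mask[(n - 1) // 2, (n - 1) // 2, (n - 1) // 2] = True  # center voxel

    # Keep the largest 6-connected component.
    lab, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, nlab + 1))
        mask = lab == (1 + int(np.argmax(sizes)))

    hu = np.full(mask.shape, -1000.0)
    hu_rng = np.random.default_rng(shape_seed + 1)
    hu[mask] = np.clip(
        hu_rng.normal(hu_mean, hu_sd, size=int(mask.sum())), -1000.0, 3000.0
    )
    return TumorModel(
        mask=mask,
        hu=hu,
        spacing=float(spacing),
        max_diameter=float(max_diameter),
        hu_mean=float(hu_mean),
        hu_sd=float(hu_sd),
        shape_seed=int(shape_seed),
    )


# ---------------------------------------------------------------------------
# Thorax


@dataclass
class ThoraxConfig:
    """Geometry of the synthetic thorax (all mm)."""

    # The tumor reference sits at the isocenter (the phantom is aligned to
    # the room lasers), so the chest is offset laterally around it.  The
    # torso is a flat-walled slab — emulating a chest phantom resting on a
    # flat resin plate — so the background thickness under the oblique
    # beams is uniform and image structure comes from lungs, ribs, spine
    # and tumor.  The SI extent is generous because the oblique central
    # rays cross the anterior/posterior walls ~75 mm away from the tumor
    # plane.
    extent: tuple[float, float, float] = (340.0, 230.0, 300.0)  # LR, AP, SI
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    torso_center: tuple[float, float] = (55.0, 0.0)       # LR, AP
    torso_half: tuple[float, float] = (170.0, 105.0)      # LR, AP half-widths
    lung_semi: tuple[float, float] = (75.0, 70.0)         # tumor-side lung
    lung_centers_lr: tuple[float, float] = (-5.0, 130.0)
    lung_center_ap: float = 0.0
    contra_lung_semi: tuple[float, float] = (60.0, 70.0)
    spine_center: tuple[float, float] = (55.0, -80.0)     # LR, AP
    spine_radius: float = 16.0
    vertebra_height: float = 20.0                         # mm along SI
    disc_gap: float = 4.0                                 # mm along SI
    ribs: bool = True
    rib_depth: float = 8.0                                # mm into each wall
    rib_period: float = 22.0                              # mm along SI
    rib_width: float = 8.0                                # mm along SI
    tumor_reference: tuple[float, float, float] = (0.0, 0.0, 0.0)


def make_thorax(config: ThoraxConfig | None = None) -> VoxelPhantom:
    """Build the labeled thorax volume (no tumor stamped).

    The default layout puts the tumor reference inside the right lung so
    that view A's line of sight crosses the periodic rib bands on the torso
    shell while view B's crosses the posterior-midline spine.
    """
    cfg = config or ThoraxConfig()
    spacing = np.asarray(cfg.spacing, dtype=float)
    shape = np.ceil(np.asarray(cfg.extent) / spacing).astype(int)
    origin = -(shape - 1) / 2.0 * spacing  # centered on the isocenter

    x = origin[0] + np.arange(shape[0]) * spacing[0]
    y = origin[1] + np.arange(shape[1]) * spacing[1]
    z = origin[2] + np.arange(shape[2]) * spacing[2]
    X, Y = np.meshgrid(x, y, indexing="ij")

    hx, hy = cfg.torso_half
    tx, ty = cfg.torso_center
    torso = (np.abs(X - tx) <= hx) & (np.abs(Y - ty) <= hy)

    labels2d = np.full(X.shape, AIR, dtype=np.uint8)
    labels2d[torso] = SOFT

    for cx, semi in zip(
        cfg.lung_centers_lr, (cfg.lung_semi, cfg.contra_lung_semi)
    ):
        lung = ((X - cx) / semi[0]) ** 2 + (
            (Y - cfg.lung_center_ap) / semi[1]
        ) ** 2 <= 1.0
        labels2d[lung & torso] = LUNG

    labels = np.repeat(labels2d[:, :, None], shape[2], axis=2)

    # Spine: a stack of vertebral-body cylinders separated by soft discs.
    sx, sy = cfg.spine_center
    spine2d = (X - sx) ** 2 + (Y - sy) ** 2 <= cfg.spine_radius**2
    period = cfg.vertebra_height + cfg.disc_gap
    body = np.mod(z - z[0], period) < cfg.vertebra_height
    col = np.broadcast_to((spine2d & torso)[:, :, None], labels.shape)
    labels[col] = SOFT  # disc baseline
    labels[col & body[None, None, :]] = SPINE

    if cfg.ribs:
        # Rib plates sit just inside the anterior and posterior walls and
        # may overlie the lung periphery, as the bony cage does in a
        # radiograph; the periodic SI bands give the rib stripes the
        # oblique beams cross.
        shell = np.abs(np.abs(Y - ty) - hy) <= cfg.rib_depth
        shell &= torso
        zband = np.mod(z - z[0], cfg.rib_period) < cfg.rib_width
        rib3d = shell[:, :, None] & zband[None, None, :] & np.isin(
            labels, (SOFT, LUNG)
        )
        labels[rib3d] = RIB

    hu = np.empty(labels.shape, dtype=np.float64)
    for mat, val in MATERIAL_HU.items():
        hu[labels == mat] = val

    ph = VoxelPhantom(
        labels=labels,
        hu=hu,
        spacing=spacing,
        origin=origin,
        slice_thickness=float(spacing[2]),
    )
    # Sanity: tumor reference must sit in lung.
    ref_idx = np.round((np.asarray(cfg.tumor_reference) - origin) / spacing).astype(int)
    if labels[tuple(ref_idx)] != LUNG:
        raise PhantomError("tumor reference position is not inside the lung")
    return ph


# ---------------------------------------------------------------------------
# Breathing trajectory


def breathing_trajectory(
    n_frames: int = 100,
    frame_rate: float = 1.67,
    period: float = 4.0,
    amplitudes: tuple[float, float, float] = (5.0, 5.0, 20.0),
    baseline_drift: float = 0.0,
    variability: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Asymmetric breathing waveform with optional cycle jitter and drift.

    The SI displacement follows ``-A * cos^4(pi * t / T)`` — a waveform that
    dwells near end-exhale (displacement 0) and dips to -A at peak inhale.
    AP and LR are exactly proportional scaled copies (the rigid phantom-arm
    coupling: pitch and yaw of one arm).  *variability* is the fractional sd
    of per-cycle amplitude and period jitter; *baseline_drift* is a linear
    SI drift in mm/min.  Each axis is rescaled so the realised sampled
    peak-to-peak equals the configured amplitude exactly.
    """
    if period <= 0:
        raise PhantomError("period must be positive")
    if frame_rate <= 0:
        raise PhantomError("frame rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate

    # Per-cycle period and amplitude factors.
    n_cycles = int(np.ceil(t[-1] / period)) + 2 if n_frames > 1 else 2
    pf = np.clip(1.0 + variability * rng.standard_normal(n_cycles), 0.3, 3.0)
    af = np.clip(1.0 + variability * rng.standard_normal(n_cycles), 0.1, 3.0)
    edges = np.concatenate([[0.0], np.cumsum(pf * period)])
    cyc = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_cycles - 1)
    local_phase = (t - edges[cyc]) / (pf[cyc] * period)  # in [0, 1)
    wave = -af[cyc] * np.cos(np.pi * local_phase) ** 4

    ptp = wave.max() - wave.min()
    if ptp <= 0:
        wave = wave * 0.0
        ptp = 1.0
    unit = (wave - wave.max()) / ptp  # in [-1, 0], peak-to-peak exactly 1
    positions = np.stack([a * unit for a in amplitudes], axis=1)
    positions[:, 2] += baseline_drift * t / 60.0
    return Trajectory(times=t, positions=positions)


# ---------------------------------------------------------------------------
# Tumor placement


def place_tumor(
    phantom: VoxelPhantom,
    tumor: TumorModel,
    reference_position,
    displacement=(0.0, 0.0, 0.0),
) -> VoxelPhantom:
    """Stamp the tumor into the phantom at reference + displacement.

    The displacement is quantised to whole phantom voxels (nearest-voxel
    resampling) so the stamped voxel pattern — and hence the voxel count —
    is identical for every in-lung placement.  Raises if any stamped voxel
    would fall outside the lung.
    """
    target = np.asarray(reference_position, dtype=float) + np.asarray(
        displacement, dtype=float
    )
    # Quantise the tumor COM target to the phantom grid.
    idx_f = (target - phantom.origin) / phantom.spacing
    idx0 = np.round(idx_f).astype(int)
    snapped = phantom.origin + idx0 * phantom.spacing

    out = phantom.copy()
    # Sample the tumor mask at phantom voxel centers in the tumor local frame
    # (reference alignment: local frame origin at the snapped COM target).
    half = tumor.max_diameter / 2.0 + 2 * max(tumor.spacing, phantom.spacing.max())
    lo = np.floor((snapped - half - phantom.origin) / phantom.spacing).astype(int)
    hi = np.ceil((snapped + half - phantom.origin) / phantom.spacing).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, phantom.shape)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    grids = np.meshgrid(
        *[
            phantom.origin[a] + np.arange(lo[a], hi[a]) * phantom.spacing[a]
            for a in range(3)
        ],
        indexing="ij",
    )
    # local coordinates relative to the *reference-aligned* tumor frame,
    # using the snapped-at-reference origin so the relative pattern is fixed:
    ref_idx0 = np.round(
        (np.asarray(reference_position, dtype=float) - phantom.origin)
        / phantom.spacing
    ).astype(int)
    shift_vox = idx0 - ref_idx0  # integer voxel translation
    shift_mm = shift_vox * phantom.spacing
    local = [
        g - (phantom.origin[a] + ref_idx0[a] * phantom.spacing[a]) - shift_mm[a]
        for a, g in enumerate(grids)
    ]
    t_origin = tumor.local_origin()
    ti = [
        np.round((local[a] - t_origin[a]) / tumor.spacing).astype(int)
        for a in range(3)
    ]
    inb = np.ones(ti[0].shape, dtype=bool)
    for a in range(3):
        inb &= (ti[a] >= 0) & (ti[a] < tumor.mask.shape[a])
    sel = np.zeros(ti[0].shape, dtype=bool)
    sel[inb] = tumor.mask[ti[0][inb], ti[1][inb], ti[2][inb]]

    region_labels = out.labels[sl]
    if not np.all(np.isin(region_labels[sel], [LUNG, TUMOR])):
        raise PhantomError("tumor placement extends outside the lung")
    hu_vals = np.zeros(ti[0].shape)
    hu_vals[inb] = tumor.hu[ti[0][inb], ti[1][inb], ti[2][inb]]
    region_labels[sel] = TUMOR
    out.labels[sl] = region_labels
    region_hu = out.hu[sl]
    region_hu[sel] = hu_vals[sel]
    out.hu[sl] = region_hu
    return out


# ---------------------------------------------------------------------------
# Trajectory CSV io (columns: time_s, LR_mm, AP_mm, SI_mm)


def save_trajectory_csv(traj: Trajectory, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "time_s": traj.times,
            "LR_mm": traj.positions[:, 0],
            "AP_mm": traj.positions[:, 1],
            "SI_mm": traj.positions[:, 2],
        }
    ).to_csv(path, index=False)


def load_trajectory_csv(path) -> Trajectory:
    import pandas as pd

    df = pd.read_csv(path)
    return Trajectory(
        times=df["time_s"].to_numpy(),
        positions=df[["LR_mm", "AP_mm", "SI_mm"]].to_numpy(),
    )
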