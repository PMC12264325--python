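"""Dual-energy soft-tissue imaging: weighted log subtraction, bone-only
images, anti-correlated noise reduction (ACNR), and CNR-driven selection of
the weighting factors.

The soft-tissue image is ``log I_DEST = log I_HE - ws * log I_LE`` and the
bone image ``log I_DEB = -log I_HE + wb * log I_LE``; at the bone-cancelling
weight ``ws* = mu_bone(HE)/mu_bone(LE)`` the bone term vanishes exactly for
noiseless Beer-Lambert projections (the module's central oracle).  ACNR
adds a Gaussian-high-pass-filtered bone image to the soft-tissue image with
weight ``wn`` (default 0.9, cutoff 0.2 cycles/pixel) to cancel the
anti-correlated quantum noise the subtraction produces.

Intensities are clamped to >= 1 count before the log (Poisson zeros occur
at low mAs).  An optional ``swap_order`` computes ``log I_LE - ws *
log I_HE`` instead, which places the bone-cancelling weight above 1, as
some conventions report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import ProjectionImage

__all__ = [
    "DualEnergyError",
    "DEImage",
    "ROIPair",
    "log_subtract",
    "bone_image",
    "gaussian_highpass",
    "acnr",
    "cnr",
    "select_ws",
    "select_wb",
    "DEFAULT_WN",
    "DEFAULT_CUTOFF",
    "DEFAULT_WS_GRID",
]

DEFAULT_WN = 0.9
DEFAULT_CUTOFF = 0.2  # cycles/pixel
DEFAULT_WS_GRID = (0.2, 2.5, 0.02)
_LOG_FLOOR = 1.0


class DualEnergyError(ValueError):
    pass


@dataclass
class DEImage:
    """Log-domain dual-energy image with the weights that produced it."""

    log_pixels: np.ndarray
    view: str
    frame_index: int = 0
    ws: float | None = None
    wb: float | None = None
    wn: float | None = None

    def __post_init__(self) -> None:
        self.log_pixels = np.asarray(self.log_pixels, dtype=float)
        if not np.all(np.isfinite(self.log_pixels)):
            raise DualEnergyError("DE image must be finite")


@dataclass(frozen=True)
class ROIPair:
    """Bone and soft-tissue rectangles, half-open ((r0, r1), (c0, c1))."""

    bone: tuple[tuple[int, int], tuple[int, int]]
    soft: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for roi in (self.bone, self.soft):
            (r0, r1), (c0, c1) = roi
            if (r1 - r0) * (c1 - c0) < 25:
                raise DualEnergyError("each ROI must contain at least 25 pixels")
        (br, bc), (sr, sc) = self.bone, self.soft
        if br[0] < sr[1] and sr[0] < br[1] and bc[0] < sc[1] and sc[0] < bc[1]:
            raise DualEnergyError("bone and soft ROIs must not overlap")

    @staticmethod
    def _take(image: np.ndarray, roi) -> np.ndarray:
        (r0, r1), (c0, c1) = roi
        if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
            raise DualEnergyError("ROI out of image bounds")
        return image[r0:r1, c0:c1]

    def bone_pixels(self, image: np.ndarray) -> np.ndarray:
        return self._take(image, self.bone)

    def soft_pixels(self, image: np.ndarray) -> np.ndarray:
        return self._take(image, self.soft)


def _check_pair(ihe: ProjectionImage, ile: ProjectionImage) -> None:
    if ihe.pixels.shape != ile.pixels.shape:
        raise DualEnergyError("HE/LE shape mismatch")
    if ihe.view != ile.view:
        raise DualEnergyError("HE/LE view mismatch")


def _safe_log(pixels: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(pixels, _LOG_FLOOR))


def log_subtract(
    ihe: ProjectionImage,
    ile: ProjectionImage,
    ws: float,
    swap_order: bool = False,
) -> DEImage:
    """Soft-tissue DE image: ``log I_HE - ws * log I_LE`` elementwise."""
    _check_pair(ihe, ile)
    lh, ll = _safe_log(ihe.pixels), _safe_log(ile.pixels)
    log_pixels = (ll - ws * lh) if swap_order else (lh - ws * ll)
    return DEImage(
        log_pixels=log_pixels, view=ihe.view, frame_index=ihe.frame_index, ws=float(ws)
    )


def bone_image(
    ihe: ProjectionImage,
    ile: ProjectionImage,
    wb: float,
    swap_order: bool = False,
) -> DEImage:
    """Bone-only DE image: ``-log I_HE + wb * log I_LE`` elementwise."""
    _check_pair(ihe, ile)
    lh, ll = _safe_log(ihe.pixels), _safe_log(ile.pixels)
    log_pixels = (-ll + wb * lh) if swap_order else (-lh + wb * ll)
    return DEImage(
        log_pixels=log_pixels, view=ihe.view, frame_index=ihe.frame_index, wb=float(wb)
    )


def gaussian_highpass(image: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Frequency-domain Gaussian high-pass filter.

    ``H(f) = 1 - exp(-f^2 / (2 sigma_f^2))`` with sigma_f set so that
    ``H(cutoff) = 0.5`` (half-power interpretation of the lower cutoff
    frequency, in cycles/pixel).  The zero-frequency response is exactly 0.
    Boundaries are handled with symmetric padding.
    """
    if not 0.0 < cutoff <= 0.5:
        raise DualEnergyError("cutoff must be in (0, 0.5] cycles/pixel")
    image = np.asarray(image, dtype=float)
    pad = min(max(image.shape) // 2, 64)
    padded = np.pad(image, pad, mode="symmetric")
    fr = np.fft.fftfreq(padded.shape[0])
    fc = np.fft.fftfreq(padded.shape[1])
    f2 = fr[:, None] ** 2 + fc[None, :] ** 2
    sigma2 = cutoff**2 / (2.0 * np.log(2.0))
    H = 1.0 - np.exp(-f2 / (2.0 * sigma2))
    out = np.fft.ifft2(np.fft.fft2(padded) * H).real
    return out[pad : pad + image.shape[0], pad : pad + image.shape[1]]


def acnr(
    soft: DEImage,
    bone: DEImage,
    wn: float = DEFAULT_WN,
    cutoff: float = DEFAULT_CUTOFF,
) -> DEImage:
    """Anti-correlated noise reduction: soft + wn * highpass(bone)."""
    if soft.log_pixels.shape != bone.log_pixels.shape:
        raise DualEnergyError("soft/bone shape mismatch")
    out = soft.log_pixels + wn * gaussian_highpass(bone.log_pixels, cutoff)
    return DEImage(
        log_pixels=out,
        view=soft.view,
        frame_index=soft.frame_index,
        ws=soft.ws,
        wb=bone.wb,
        wn=float(wn),
    )


def cnr(image: np.ndarray, rois: ROIPair, eps: float = 0.0) -> float:
    """Bone contrast-to-noise ratio between the two ROIs.

    ``|mean(bone) - mean(soft)| / sd(soft)``.  A zero soft-ROI standard
    deviation raises unless a positive *eps* floor is supplied.
    """
    image = np.asarray(image, dtype=float)
    b = rois.bone_pixels(image)
    s = rois.soft_pixels(image)
    sd = float(s.std())
    if sd <= 0.0:
        if eps > 0.0:
            sd = eps
        else:
            raise DualEnergyError("degenerate ROI: zero standard deviation")
    return abs(float(b.mean()) - float(s.mean())) / sd


def _grid(grid) -> np.ndarray:
    lo, hi, step = grid
    values = np.arange(lo, hi + step / 2, step)
    if values.size == 0:
        raise DualEnergyError("empty weighting-factor grid")
    return values


def select_ws(
    ihe: ProjectionImage,
    ile: ProjectionImage,
    rois: ROIPair,
    grid=DEFAULT_WS_GRID,
    swap_order: bool = False,
    eps: float = 1e-12,
) -> float:
    """Pick the soft-tissue weight minimising the bone CNR over a grid.

    Ties (and flat degenerate profiles, e.g. no bone in the ROI) resolve to
    the smallest grid value.  Only ROI statistics are evaluated, so the
    search is cheap enough to run per frame.
    """
    _check_pair(ihe, ile)
    values = _grid(grid)
    lh, ll = _safe_log(ihe.pixels), _safe_log(ile.pixels)
    if swap_order:
        lh, ll = ll, lh
    bh, bl = rois.bone_pixels(lh), rois.bone_pixels(ll)
    sh, sl = rois.soft_pixels(lh), rois.soft_pixels(ll)
    best_ws, best = None, np.inf
    for ws in values:
        b = bh - ws * bl
        s = sh - ws * sl
        sd = max(float(s.std()), eps)
        c = abs(float(b.mean()) - float(s.mean())) / sd
        if c < best - 1e-15:
            best, best_ws = c, float(ws)
    return best_ws


def select_wb(
    ihe: ProjectionImage,
    ile: ProjectionImage,
    rois: ROIPair,
    grid=DEFAULT_WS_GRID,
    swap_order: bool = False,
    contrast_floor: float = 0.0,
    eps: float = 1e-12,
) -> float:
    """Pick the bone-image weight that best suppresses soft tissue.

    Minimises the structural variation of the bone image within the soft
    ROI (soft-tissue suppression) subject to the bone-vs-soft contrast
    staying above *contrast_floor* (bone must remain visible).  Ties break
    toward the smaller weight; if no grid point satisfies the floor, the
    constraint is dropped (degenerate no-bone fallback to the grid
    minimum).
    """
    _check_pair(ihe, ile)
    values = _grid(grid)
    lh, ll = _safe_log(ihe.pixels), _safe_log(ile.pixels)
    if swap_order:
        lh, ll = ll, lh
    bh, bl = rois.bone_pixels(lh), rois.bone_pixels(ll)
    sh, sl = rois.soft_pixels(lh), rois.soft_pixels(ll)

    def metric(wb):
        s = -sh + wb * sl
        b = -bh + wb * bl
        return float(s.std()), abs(float(b.mean()) - float(s.mean()))

    best_wb, best = None, np.inf
    for wb in values:
        sup, contrast = metric(wb)
        if contrast < contrast_floor:
            continue
        if sup < best - 1e-15:
            best, best_wb = sup, float(wb)
    if best_wb is None:  # nothing met the floor: degenerate fallback
        best_wb = float(values[0])
    return best_wb
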