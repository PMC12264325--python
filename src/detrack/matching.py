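"""Tumor template generation and normalized cross-correlation matching.

Templates are noiseless DRRs (line integrals) of the tumor-only volume at
each view's geometry, cropped to the tumor footprint with a two-pixel
margin.  Matching computes the normalized cross-correlation

    NCC(u, v) = sum_xy (I - Ibar_uv)(t - tbar) / (N sigma_I sigma_t)

over every placement, with the search image zero-padded so the correlation
map keeps the image size; the global maximum gives the tumor's 2D
location.  Matching operates on attenuation-polarity images (``-log`` of
counts for SE, negated log-domain DE images) so image and template share
contrast polarity — the NCC is mean- and scale-invariant but not
polarity-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .dual_energy import DEImage
from .geometry import StereoGeometry
from .phantom import AIR, LUNG, TUMOR, TumorModel, VoxelPhantom
from .projector import (
    AttenuationTable,
    DEFAULT_ATTENUATION,
    ENERGY_INDEX,
    ProjectionImage,
    material_path_images,
)

__all__ = [
    "MatchingError",
    "Template",
    "CorrelationMap",
    "threshold_contour",
    "make_tumor_only_volume",
    "make_template",
    "template_from_tumor",
    "normxcorr",
    "locate_2d",
    "attenuation_image",
    "de_matching_image",
]


class MatchingError(ValueError):
    pass


@dataclass
class Template:
    """Tumor DRR crop for one view."""

    pixels: np.ndarray
    view: str
    com_offset: tuple[float, float]  # tumor COM minus template center (px)
    source_tumor: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.std() == 0:
            raise MatchingError("template has zero variance")


@dataclass
class CorrelationMap:
    values: np.ndarray
    peak: tuple[int, int]
    peak_value: float
    tie: bool = False


def threshold_contour(ct_like: VoxelPhantom, threshold: float) -> np.ndarray:
    """Auto-contour the gross tumor volume by HU thresholding.

    Keeps the largest 6-connected component above *threshold* within the
    lung region (lung or tumor labels).  Raises if nothing exceeds the
    threshold.
    """
    region = np.isin(ct_like.labels, (LUNG, TUMOR))
    mask = region & (ct_like.hu > threshold)
    if not mask.any():
        raise MatchingError("thresholding produced an empty contour")
    lab, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, nlab + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def make_tumor_only_volume(ct_like: VoxelPhantom, mask: np.ndarray) -> VoxelPhantom:
    """Mask out everything but the tumor (outside voxels become air)."""
    if mask.shape != ct_like.shape:
        raise MatchingError("mask shape mismatch")
    out = ct_like.copy()
    out.hu[~mask] = -1000.0
    out.labels[~mask] = AIR
    out.labels[mask] = TUMOR
    return out


def make_template(
    tumor_volume: VoxelPhantom,
    geom: StereoGeometry,
    view: str,
    table: AttenuationTable = DEFAULT_ATTENUATION,
    energy: str = "HE",
    margin: int = 2,
    source_tumor: str = "",
) -> Template:
    """Noiseless DRR of a tumor-only volume, cropped with a 2-pixel margin.

    The template holds attenuation line integrals (not counts); its
    intensity center of mass relative to the template center is recorded in
    ``com_offset`` so a correlation peak maps back to the tumor COM on the
    detector.
    """
    lengths, hu_term = material_path_images(tumor_volume, geom, view)
    mu = table.mu[:, ENERGY_INDEX[energy]]
    drr = lengths @ mu + mu[TUMOR] * hu_term
    return _crop_template(drr, view, margin, source_tumor)


def _crop_template(drr: np.ndarray, view: str, margin: int, source_tumor: str) -> Template:
    nz = np.argwhere(drr > drr.max() * 1e-9)
    if nz.size == 0:
        raise MatchingError("tumor DRR footprint is empty")
    r0, c0 = nz.min(axis=0)
    r1, c1 = nz.max(axis=0)
    r0m, c0m = r0 - margin, c0 - margin
    r1m, c1m = r1 + margin, c1 + margin
    if r0m < 0 or c0m < 0 or r1m >= drr.shape[0] or c1m >= drr.shape[1]:
        raise MatchingError("tumor footprint (plus margin) outside detector")
    crop = drr[r0m : r1m + 1, c0m : c1m + 1]
    rr, cc = np.mgrid[0 : crop.shape[0], 0 : crop.shape[1]]
    total = crop.sum()
    com = (float((rr * crop).sum() / total), float((cc * crop).sum() / total))
    # Offset is taken from the correlation anchor pixel (shape // 2), which
    # is the template pixel that a correlation-map index corresponds to, so
    # `peak + com_offset` recovers the tumor COM for any template parity.
    center = (crop.shape[0] // 2, crop.shape[1] // 2)
    return Template(
        pixels=crop,
        view=view,
        com_offset=(com[0] - center[0], com[1] - center[1]),
        source_tumor=source_tumor,
    )


def template_from_tumor(
    tumor: TumorModel,
    geom: StereoGeometry,
    view: str,
    reference_position,
    table: AttenuationTable = DEFAULT_ATTENUATION,
    energy: str = "HE",
    margin: int = 2,
) -> Template:
    """Template directly from a TumorModel at its reference pose.

    Convenience path equivalent to projecting a tumor-only volume; used
    when no planning-CT stamping step is wanted.
    """
    from .projector import tumor_path_window

    mu = table.mu[:, ENERGY_INDEX[energy]]
    rows, cols, lt, ht = tumor_path_window(
        tumor, geom, view, np.asarray(reference_position, dtype=float), margin_px=margin + 2
    )
    drr_win = mu[TUMOR] * (lt + ht)
    # Embed in a frame so the crop margin logic applies uniformly.
    tpl = _crop_template(drr_win, view, margin, source_tumor="model")
    return tpl


def normxcorr(image: np.ndarray, template: Template | np.ndarray) -> CorrelationMap:
    """Normalized cross-correlation of a template over a search image.

    The image is zero-padded by half the template size on each border so
    the output has the image's shape; ``values[r, c]`` is the correlation
    with the template centered at image pixel (r, c).  Windows with zero
    variance get correlation 0.
    """
    t = template.pixels if isinstance(template, Template) else np.asarray(template, float)
    image = np.asarray(image, dtype=float)
    th, tw = t.shape
    if th > image.shape[0] or tw > image.shape[1]:
        raise MatchingError("template larger than search image")
    ts = t.std()
    if ts == 0:
        raise MatchingError("template has zero variance")

    pad_r = (th // 2, th - 1 - th // 2)
    pad_c = (tw // 2, tw - 1 - tw // 2)
    P = np.pad(image, (pad_r, pad_c), mode="constant")
    n = t.size
    tz = t - t.mean()

    ones = np.ones_like(t)
    s1 = signal.fftconvolve(P, ones, mode="valid")
    s2 = signal.fftconvolve(P * P, ones, mode="valid")
    cross = signal.fftconvolve(P, tz[::-1, ::-1], mode="valid")

    num = cross - s1 * tz.sum() / n  # tz.sum() ~ 0; kept for exactness
    var = np.maximum(s2 - s1 * s1 / n, 0.0)
    denom = np.sqrt(var) * np.sqrt((tz * tz).sum())
    scale = np.sqrt((t * t).sum() * n)  # threshold scale for "zero" variance
    values = np.where(denom > 1e-12 * max(scale, 1.0), num / np.maximum(denom, 1e-300), 0.0)

    peak, tie = _argmax_with_ties(values)
    return CorrelationMap(
        values=values, peak=peak, peak_value=float(values[peak]), tie=tie
    )


def _argmax_with_ties(values: np.ndarray) -> tuple[tuple[int, int], bool]:
    flat = int(np.argmax(values))
    peak = np.unravel_index(flat, values.shape)
    ties = np.argwhere(values == values[peak])
    return (int(peak[0]), int(peak[1])), len(ties) > 1


def locate_2d(cmap: CorrelationMap) -> tuple[int, int, bool]:
    """Integer-pixel tumor location: global correlation maximum.

    Ties break toward the smallest row, then the smallest column, and are
    flagged.  Returns ``(row, col, tie_flag)``.
    """
    if cmap.values.size == 0:
        raise MatchingError("empty correlation map")
    peak, tie = _argmax_with_ties(cmap.values)
    return peak[0], peak[1], tie


def attenuation_image(proj: ProjectionImage) -> np.ndarray:
    """Attenuation-polarity search image for SE matching: -log(counts)."""
    return -np.log(np.maximum(proj.pixels, 1.0))


def de_matching_image(de: DEImage) -> np.ndarray:
    """Attenuation-polarity search image from a log-domain DE image."""
    return -de.log_pixels
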