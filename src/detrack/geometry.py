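"""Room-mounted stereoscopic kV imaging geometry.

Two fixed source/flat-panel assemblies view the treatment isocenter at
oblique angles (polar angle from the vertical, azimuthal spread about the
patient axis).  Room coordinates are right-handed with origin at the
isocenter and axes (LR, AP, SI): +x toward the patient's left, +y anterior
(up for a supine patient), +z superior.  Sources sit below the couch
(posterior-inferior), detectors on the opposite side of the isocenter.

Pixel convention: continuous pixel coordinates (row, col); the center of
pixel (0, 0) is at one detector corner and the detector center falls at
((rows-1)/2, (cols-1)/2).  Rows increase toward inferior, columns along the
remaining in-plane axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "Ray",
    "ViewGeometry",
    "StereoGeometry",
    "build_geometry",
    "project_point",
    "pixel_to_ray",
    "triangulate",
]

# Default imager parameters (source-isocenter 3435 mm, isocenter-detector
# 2185 mm, 512x512 panel at 0.4 mm pitch, beams at polar 48 deg and
# azimuth +/-45 deg).
DEFAULT_SID = 3435.0
DEFAULT_IDD = 2185.0
DEFAULT_SHAPE = (512, 512)
DEFAULT_PITCH = 0.4
DEFAULT_POLAR_DEG = 48.0
DEFAULT_AZIMUTH_DEG = {"A": -45.0, "B": 45.0}

_SI = np.array([0.0, 0.0, 1.0])


class GeometryError(ValueError):
    """Degenerate imaging geometry or projection request."""


@dataclass(frozen=True)
class Ray:
    """A half-line in room coordinates (origin in mm, unit direction)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0.0:
            raise GeometryError("ray direction must be nonzero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point(self, t: float | np.ndarray) -> np.ndarray:
        return self.origin + np.multiply.outer(t, self.direction)


@dataclass(frozen=True)
class ViewGeometry:
    """One source/detector assembly."""

    source: np.ndarray          # (3,) mm
    detector_center: np.ndarray  # (3,) mm
    row_axis: np.ndarray        # unit, in detector plane
    col_axis: np.ndarray        # unit, in detector plane
    pixel_pitch: float          # mm/pixel
    shape: tuple[int, int]      # rows, cols

    @property
    def normal(self) -> np.ndarray:
        """Unit central-ray direction (source toward detector)."""
        n = self.detector_center - self.source
        return n / np.linalg.norm(n)

    def pixel_position(self, row, col) -> np.ndarray:
        """3D position of continuous pixel coordinates on the panel."""
        rows, cols = self.shape
        dr = (np.asarray(row, dtype=float) - (rows - 1) / 2.0) * self.pixel_pitch
        dc = (np.asarray(col, dtype=float) - (cols - 1) / 2.0) * self.pixel_pitch
        return (
            self.detector_center
            + np.multiply.outer(dr, self.row_axis)
            + np.multiply.outer(dc, self.col_axis)
        )


@dataclass(frozen=True)
class StereoGeometry:
    """The stereoscopic pair, keyed by view label 'A' / 'B'."""

    views: dict[str, ViewGeometry] = field(default_factory=dict)
    sid: float = DEFAULT_SID
    idd: float = DEFAULT_IDD

    def __getitem__(self, view: str) -> ViewGeometry:
        return self.views[view]

    @property
    def magnification(self) -> float:
        return (self.sid + self.idd) / self.sid


def _view_geometry(
    sid: float,
    idd: float,
    polar_deg: float,
    azimuth_deg: float,
    pixel_pitch: float,
    shape: tuple[int, int],
) -> ViewGeometry:
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(azimuth_deg)
    # Source below (posterior, -y) and inferior (-z), spread +/- in LR with
    # azimuth measured about the vertical from the inferior direction.
    u = np.array(
        [np.sin(th) * np.sin(ph), -np.cos(th), -np.sin(th) * np.cos(ph)]
    )
    source = sid * u
    center = -idd * u  # opposite side of the isocenter, on the central ray
    w = -u  # central ray direction source -> isocenter -> detector
    # Rows toward inferior: project -SI onto the detector plane.
    r = _SI - np.dot(_SI, w) * w
    nr = np.linalg.norm(r)
    if nr < 1e-12:  # central ray along SI; fall back to AP for rows
        r = np.array([0.0, 1.0, 0.0]) - w[1] * w
        nr = np.linalg.norm(r)
    row_axis = -r / nr
    col_axis = np.cross(w, row_axis)
    return ViewGeometry(
        source=source,
        detector_center=center,
        row_axis=row_axis,
        col_axis=col_axis,
        pixel_pitch=float(pixel_pitch),
        shape=(int(shape[0]), int(shape[1])),
    )


def build_geometry(
    sid: float = DEFAULT_SID,
    idd: float = DEFAULT_IDD,
    polar_deg: float = DEFAULT_POLAR_DEG,
    azimuth_deg: dict[str, float] | None = None,
    pixel_pitch: float = DEFAULT_PITCH,
    detector_shape: tuple[int, int] = DEFAULT_SHAPE,
) -> StereoGeometry:
    """Construct the stereoscopic geometry from imaging parameters.

    Parameters
    ----------
    sid, idd:
        Source-to-isocenter and isocenter-to-detector distances (mm).
    polar_deg:
        Polar angle of each source direction from the vertical (deg).
    azimuth_deg:
        Mapping view label -> azimuthal angle (deg); default {'A': -45,
        'B': +45}.
    pixel_pitch, detector_shape:
        Panel sampling (mm/pixel and rows x cols).
    """
    if sid <= 0 or idd <= 0:
        raise GeometryError("distances must be positive")
    if pixel_pitch <= 0:
        raise GeometryError("pixel pitch must be positive")
    if detector_shape[0] <= 0 or detector_shape[1] <= 0:
        raise GeometryError("detector shape must be positive")
    if azimuth_deg is None:
        azimuth_deg = dict(DEFAULT_AZIMUTH_DEG)
    views = {
        label: _view_geometry(sid, idd, polar_deg, az, pixel_pitch, detector_shape)
        for label, az in azimuth_deg.items()
    }
    return StereoGeometry(views=views, sid=float(sid), idd=float(idd))


def project_point(geom: StereoGeometry, view: str, p) -> tuple[float, float]:
    """Project a 3D room point onto a view's panel (continuous pixels)."""
    vg = geom[view]
    p = np.asarray(p, dtype=float)
    d = p - vg.source
    n = vg.normal
    denom = float(np.dot(d, n))
    if abs(denom) < 1e-12:
        raise GeometryError("ray parallel to detector plane")
    t = float(np.dot(vg.detector_center - vg.source, n)) / denom
    if t <= 0:
        raise GeometryError("point projects behind the source")
    x = vg.source + t * d
    rel = x - vg.detector_center
    rows, cols = vg.shape
    row = float(np.dot(rel, vg.row_axis)) / vg.pixel_pitch + (rows - 1) / 2.0
    col = float(np.dot(rel, vg.col_axis)) / vg.pixel_pitch + (cols - 1) / 2.0
    return row, col


def pixel_to_ray(geom: StereoGeometry, view: str, pixel) -> Ray:
    """Cast the ray from a view's source through a (row, col) pixel."""
    vg = geom[view]
    row, col = float(pixel[0]), float(pixel[1])
    rows, cols = vg.shape
    if not (-0.5 <= row <= rows - 0.5 and -0.5 <= col <= cols - 0.5):
        raise GeometryError(f"pixel {(row, col)} outside detector bounds")
    pos = vg.pixel_position(row, col)
    return Ray(origin=vg.source, direction=pos - vg.source)


def triangulate(ray_a: Ray, ray_b: Ray, parallel_tol: float = 1e-9):
    """Midpoint of the common perpendicular between two (skew) rays.

    Returns ``(point, residual)`` where *residual* is half the length of
    the common-perpendicular segment — a quality metric for how far the two
    back-projected rays miss each other.
    """
    da, db = ray_a.direction, ray_b.direction
    cross = np.cross(da, db)
    denom = float(np.dot(cross, cross))
    if denom < parallel_tol:
        raise GeometryError("rays are (near-)parallel; cannot triangulate")
    w0 = ray_a.origin - ray_b.origin
    a = float(np.dot(da, da))
    b = float(np.dot(da, db))
    c = float(np.dot(db, db))
    d = float(np.dot(da, w0))
    e = float(np.dot(db, w0))
    den = a * c - b * b
    ta = (b * e - c * d) / den
    tb = (a * e - b * d) / den
    pa = ray_a.point(ta)
    pb = ray_b.point(tb)
    midpoint = 0.5 * (pa + pb)
    residual = 0.5 * float(np.linalg.norm(pa - pb))
    return midpoint, residual
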