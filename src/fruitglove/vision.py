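"""Pin-hole camera geometry: depth, RGB+NIR fusion, area and volume.

The palm-mounted optical board carries a stereo pair of VGA cameras with a
laser pointer between them (camera-laser baseline H = 2.5 cm).  All geometry
here is plain parallel-axis pin-hole triangulation:

* depth from stereo disparity, ``Z = f·H / (xL − xR)``;
* depth from the projected laser dot's offset from the principal point
  (same relation, usable with a single camera over a short range);
* RGB+NIR fusion under a planar-object assumption — the NIR frame is a
  horizontally shifted copy of the visible frame, shift ``f·H/Z``;
* a distance-invariant projected area ``t = a_CI·Z²/f²`` for a segmented
  near-circular object of ``a_CI`` pixels, converted to cm² through a
  calibration polynomial, and from there to the radius and volume of the
  assumed sphere.

Pixel coordinates are 0-based, origin top-left, x rightward; the principal
point sits at the image centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CameraModel",
    "DepthEstimate",
    "FusedImage",
    "GeometryError",
    "focal_from_fov",
    "stereo_depth",
    "disparity_for_depth",
    "laser_depth",
    "merge_nir",
    "distance_invariant_area",
    "area_to_cm2",
    "radius_from_area",
    "sphere_volume",
    "max_visible_diameter",
    "undistort",
]

#: Depth window (cm) over which laser triangulation is trusted.
LASER_RELIABLE_RANGE_CM = (3.0, 7.3)

#: Printed pixel->cm2 area calibration cubic (highest degree first).
#: Hardware-specific: fitted on ten reference circles with the glove camera.
AREA_POLY_DEFAULT = (-4.45e-12, 1.11e-7, 2.05e-3, -0.395)

#: Identity conversion — for an ideal pin-hole camera t is already in cm²
#: (Z in cm, a_CI and f in pixels), so no empirical correction applies.
AREA_POLY_IDENTITY = (0.0, 0.0, 1.0, 0.0)


class GeometryError(ValueError):
    """Raised for degenerate geometric configurations."""


def focal_from_fov(width_px: int, fov_deg: float) -> float:
    """Focal length in pixels from horizontal field of view."""
    if not 0.0 < fov_deg < 180.0:
        raise GeometryError("fov must lie in (0, 180) degrees")
    return (width_px / 2.0) / math.tan(math.radians(fov_deg) / 2.0)


@dataclass(frozen=True)
class CameraModel:
    """Pin-hole camera with an optional laser/stereo baseline.

    ``baseline_cm`` is the camera-camera distance in stereo mode, or the
    camera-laser distance when triangulating the laser dot (both 2.5 cm on
    the glove's board).
    """

    width_px: int
    height_px: int
    f_px: float
    baseline_cm: float = 2.5

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0 or self.f_px <= 0 or self.baseline_cm < 0:
            raise GeometryError("camera dimensions, focal length and baseline must be positive")

    @classmethod
    def from_fov(
        cls, width_px: int, height_px: int, fov_deg: float, baseline_cm: float = 2.5
    ) -> "CameraModel":
        return cls(width_px, height_px, focal_from_fov(width_px, fov_deg), baseline_cm)

    @property
    def fov_deg(self) -> float:
        return math.degrees(2.0 * math.atan((self.width_px / 2.0) / self.f_px))

    @property
    def principal_point(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


@dataclass(frozen=True)
class DepthEstimate:
    Z_cm: float
    source: str  # ir_sensor | laser | stereo
    reliable: bool

    def __post_init__(self) -> None:
        if self.Z_cm <= 0:
            raise GeometryError("depth must be positive")


def stereo_depth(xL: float, xR: float, cam: CameraModel) -> float:
    """Depth Z (cm) from the horizontal disparity of a rectified stereo pair."""
    d = xL - xR
    if d == 0:
        raise GeometryError("zero disparity: object at infinity")
    return cam.f_px * cam.baseline_cm / d


def disparity_for_depth(Z: float, cam: CameraModel) -> float:
    """Horizontal disparity (px) of a point at depth Z (cm); inverse of
    :func:`stereo_depth`."""
    if Z <= 0:
        raise GeometryError("depth must be positive")
    return cam.f_px * cam.baseline_cm / Z


def laser_depth(dot_offset_px: float, cam: CameraModel) -> DepthEstimate:
    """Depth from the laser dot's offset from the principal point.

    The laser beam is parallel to the optical axis at baseline H, so the dot
    images at offset ``f·H/Z`` — identical to a stereo disparity.  The short
    baseline limits the trustworthy window to 3-7.3 cm; outside it the
    estimate is returned but marked unreliable.
    """
    if dot_offset_px <= 0:
        raise GeometryError("laser dot offset must be positive")
    z = cam.f_px * cam.baseline_cm / dot_offset_px
    lo, hi = LASER_RELIABLE_RANGE_CM
    return DepthEstimate(Z_cm=z, source="laser", reliable=lo <= z <= hi)


@dataclass
class FusedImage:
    """4-channel visible+NIR composite.

    ``rgbi`` is (H, W, 4) with R, G, B copied from the visible camera and I
    the NIR frame shifted into the visible frame's coordinates;
    ``oob`` flags pixels whose NIR source fell outside the NIR frame.
    """

    rgbi: np.ndarray
    oob: np.ndarray


def merge_nir(vis: np.ndarray, nir: np.ndarray, Z: float, cam: CameraModel) -> FusedImage:
    """Fuse a visible RGB frame with the second camera's NIR frame.

    Under the planar-object assumption all pixels share depth Z, so the NIR
    image is the visible image translated by the stereo disparity:
    ``I(x, y) = NIR(x − f·H/Z, y)``.  Out-of-bounds source pixels get I = 0
    and are flagged.
    """
    vis = np.asarray(vis)
    nir = np.asarray(nir)
    if vis.ndim != 3 or vis.shape[2] != 3:
        raise GeometryError("vis must be an (H, W, 3) RGB image")
    if nir.shape[:2] != vis.shape[:2]:
        raise GeometryError("vis and nir dimensions differ")
    if Z <= 0:
        raise GeometryError("depth must be positive")
    shift = disparity_for_depth(Z, cam)
    nir_f = nir.astype(float)
    if nir_f.ndim == 3:
        nir_f = nir_f.mean(axis=2)
    # I(x,y) = NIR(x - shift, y): translate the NIR frame rightward by shift.
    i_chan = ndimage.shift(nir_f, (0.0, shift), order=1, mode="constant", cval=0.0)
    w = vis.shape[1]
    xs = np.arange(w, dtype=float) - shift
    oob_cols = (xs < 0) | (xs > w - 1)
    oob = np.zeros(vis.shape[:2], dtype=bool)
    oob[:, oob_cols] = True
    rgbi = np.dstack([vis.astype(float), i_chan])
    return FusedImage(rgbi=rgbi, oob=oob)


def distance_invariant_area(a_ci: float, Z: float, f_px: float) -> float:
    """Distance-invariant area ``t = a_CI·Z²/f²`` of a segmented object.

    ``a_ci`` is the segmented pixel count at depth Z; scaling by (Z/f)²
    removes the perspective shrinkage so the same physical object yields the
    same t at any distance.  Reported as a magnitude (the pin-hole image
    inversion sign is dropped).
    """
    if a_ci < 0 or Z <= 0 or f_px <= 0:
        raise GeometryError("a_ci must be >= 0 and Z, f positive")
    return a_ci * Z * Z / (f_px * f_px)


@dataclass(frozen=True)
class AreaEstimate:
    area_cm2: float
    clamped: bool


def area_to_cm2(t: float, coefficients=AREA_POLY_DEFAULT) -> AreaEstimate:
    """Convert distance-invariant area t to cm² via the calibration cubic.

    The default coefficients are the glove camera's empirical fit on ten
    reference circles; an ideal pin-hole camera uses
    :data:`AREA_POLY_IDENTITY`.  Negative raw results (t below the
    calibrated span) are clamped to 0 and flagged.
    """
    if t < 0:
        raise GeometryError("t must be >= 0")
    raw = float(np.polyval(coefficients, t))
    return AreaEstimate(area_cm2=max(raw, 0.0), clamped=raw < 0.0)


def radius_from_area(A: float) -> float:
    """Radius (cm) of the circle of area A (cm²): r = sqrt(A/π)."""
    if A < 0:
        raise GeometryError("area must be >= 0")
    return math.sqrt(A / math.pi)


def sphere_volume(A: float) -> float:
    """Volume (cm³) of the sphere whose great-circle area is A (cm²)."""
    r = radius_from_area(A)
    return (4.0 / 3.0) * math.pi * r**3


def max_visible_diameter(Z: float, cam: CameraModel) -> float:
    """Largest object diameter (cm) fully visible at depth Z: 2·Z·tan(FOV/2)."""
    if Z < 0:
        raise GeometryError("depth must be >= 0")
    return 2.0 * Z * math.tan(math.radians(cam.fov_deg) / 2.0)


def undistort(image: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Lens-undistortion hook.

    Synthetic scenes are distortion-free, so this is the identity; a real
    deployment would slot a checkerboard-calibrated undistortion here.
    """
    return image
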