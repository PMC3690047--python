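"""Laser-seeded interactive segmentation, seed tracking and the moving fovea.

The user points the glove's red laser at the object of interest.  Each frame,
the brightest red dot becomes a segmentation *seed*; seeds persist across
frames (tracked with Lucas-Kanade optical flow, expiring after a
time-to-live) so the object stays segmented while the hand moves.  A fuzzy
connectedness region growing extracts the object from the live seed set, and
a small "moving fovea" window centred on the laser dot restricts the stereo
disparity computation to the object's neighbourhood.

The fuzzy criterion: pixel q belongs to the object if some 4-connected path
from a seed reaches it with every link affinity at least theta, where the
link affinity between neighbours p, q is a Gaussian in their intensity step,
``mu(p, q) = exp(−(I(p) − I(q))² / 2σ²)`` on the per-pixel channel mean.
Thresholding that max-min path strength at theta is equivalent to connected
components over the pixel graph that keeps only edges with
``|ΔI| ≤ σ·sqrt(−2·ln θ)``, which is how it is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy import ndimage
from skimage.registration import optical_flow_ilk

__all__ = [
    "Seed",
    "SeedSet",
    "SegMask",
    "FoveaWindow",
    "SegmentationError",
    "detect_laser_dot",
    "advance_seeds",
    "fuzzy_segment",
    "fovea_disparity",
    "mask_area",
]

DEFAULT_TTL = 30
DEFAULT_THETA = 0.7
DEFAULT_SIGMA = 25.0
DOT_SCORE_THRESHOLD = 60
DOT_MIN_RED = 200


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Seed:
    """A laser-deposited seed point with a frame time-to-live."""

    x: float
    y: float
    ttl: int = DEFAULT_TTL


@dataclass
class SeedSet:
    """The live seed population for one tracked object."""

    seeds: list[Seed] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def add(self, x: float, y: float, ttl: int = DEFAULT_TTL) -> None:
        self.seeds.append(Seed(x, y, ttl))

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions."""
        if not self.seeds:
            return np.empty((0, 2))
        return np.array([(s.x, s.y) for s in self.seeds], dtype=float)


@dataclass
class SegMask:
    """Binary object mask produced by the fuzzy segmentation."""

    mask: np.ndarray

    @property
    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


def mask_area(mask: SegMask) -> int:
    """Segmented pixel count a_CI — the object's area in pixels."""
    return mask.pixel_count


@dataclass(frozen=True)
class FoveaWindow:
    """Moving-fovea window, typically centred on the last laser dot."""

    cx: int
    cy: int
    half_w: int = 64
    half_h: int = 64

    def clip(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        h, w = shape[:2]
        y0, y1 = max(0, self.cy - self.half_h), min(h, self.cy + self.half_h)
        x0, x1 = max(0, self.cx - self.half_w), min(w, self.cx + self.half_w)
        if y0 >= y1 or x0 >= x1:
            raise SegmentationError("fovea window lies outside the image")
        return slice(y0, y1), slice(x0, x1)


def _intensity(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img


def detect_laser_dot(
    rgb: np.ndarray,
    score_threshold: float = DOT_SCORE_THRESHOLD,
    min_red: float = DOT_MIN_RED,
) -> Optional[tuple[int, int]]:
    """Locate the projected laser dot: the brightest red point of the image.

    Redness score s = R − max(G, B); the dot is the argmax of s among pixels
    with s ≥ ``score_threshold`` and R ≥ ``min_red``.  Ties break to the
    smallest (y, x).  Returns (x, y) or None when no pixel qualifies.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise SegmentationError("detect_laser_dot expects an (H, W, 3) image")
    r = rgb[..., 0].astype(np.int32)
    s = r - np.maximum(rgb[..., 1], rgb[..., 2]).astype(np.int32)
    ok = (s >= score_threshold) & (r >= min_red)
    if not ok.any():
        return None
    s_masked = np.where(ok, s, np.iinfo(np.int32).min)
    # argmax scans row-major, so the first maximum has smallest (y, x)
    flat = int(np.argmax(s_masked))
    y, x = divmod(flat, rgb.shape[1])
    return (x, y)


def advance_seeds(
    seeds: SeedSet,
    prev: np.ndarray,
    cur: np.ndarray,
    new_dot: Optional[tuple[float, float]] = None,
    ttl_init: int = DEFAULT_TTL,
) -> SeedSet:
    """One frame step of the seed tracker.

    Every live seed is displaced by the optical flow between ``prev`` and
    ``cur`` (dense iterative Lucas-Kanade, sampled at the seed position) and
    its ttl decremented; seeds that expire or leave the frame are dropped.
    The current frame's freshly detected dot, if any, joins with a full ttl.
    """
    prev_i = _intensity(prev)
    cur_i = _intensity(cur)
    if prev_i.shape != cur_i.shape:
        raise SegmentationError("frame dimensions differ")
    h, w = cur_i.shape
    out = SeedSet()
    if seeds.seeds:
        if np.array_equal(prev_i, cur_i):
            flow_v = flow_u = np.zeros_like(cur_i)
        else:
            # flow maps cur coords -> prev coords; a seed moves by its negative
            flow_v, flow_u = optical_flow_ilk(cur_i, prev_i, radius=7)
        for s in seeds:
            if s.ttl <= 1:
                continue
            yi = int(round(min(max(s.y, 0), h - 1)))
            xi = int(round(min(max(s.x, 0), w - 1)))
            nx = s.x - float(flow_u[yi, xi])
            ny = s.y - float(flow_v[yi, xi])
            if 0 <= nx <= w - 1 and 0 <= ny <= h - 1:
                out.seeds.append(Seed(nx, ny, s.ttl - 1))
    if new_dot is not None:
        out.add(new_dot[0], new_dot[1], ttl_init)
    return out


def fuzzy_segment(
    image: np.ndarray,
    seeds: SeedSet,
    theta: float = DEFAULT_THETA,
    sigma: float = DEFAULT_SIGMA,
    smooth_sigma: float = 0.0,
) -> SegMask:
    """Fuzzy-connectedness region growing from the laser seed set.

    A pixel joins the object when some 4-connected path from a seed keeps
    every link affinity ``exp(−ΔI²/2σ²)`` at or above ``theta``; the output
    is the union over all seeds.  ``smooth_sigma > 0`` applies a Gaussian
    pre-filter to the intensity before growing (useful on noisy frames).
    """
    if not seeds.seeds:
        raise SegmentationError("fuzzy_segment needs at least one live seed")
    if not 0.0 < theta <= 1.0:
        raise SegmentationError("theta must lie in (0, 1]")
    inten = _intensity(image)
    if smooth_sigma > 0:
        inten = ndimage.gaussian_filter(inten, smooth_sigma)
    h, w = inten.shape
    delta = sigma * np.sqrt(-2.0 * np.log(theta)) if theta < 1.0 else 0.0

    idx = np.arange(h * w).reshape(h, w)
    horiz = np.abs(np.diff(inten, axis=1)) <= delta
    vert = np.abs(np.diff(inten, axis=0)) <= delta
    rows = np.concatenate([idx[:, :-1][horiz], idx[:-1, :][vert]])
    cols = np.concatenate([idx[:, 1:][horiz], idx[1:, :][vert]])
    data = np.ones(rows.size, dtype=np.int8)
    graph = coo_matrix((data, (rows, cols)), shape=(h * w, h * w))
    _, labels = connected_components(graph, directed=False)

    seed_labels = set()
    for s in seeds:
        yi = int(round(s.y))
        xi = int(round(s.x))
        if 0 <= yi < h and 0 <= xi < w:
            seed_labels.add(int(labels[yi * w + xi]))
    if not seed_labels:
        raise SegmentationError("no seed lies inside the image")
    mask = np.isin(labels.reshape(h, w), sorted(seed_labels))
    return SegMask(mask=mask)


def fovea_disparity(
    left: np.ndarray,
    right: np.ndarray,
    window: FoveaWindow,
    max_disp: int,
    block: int = 7,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Block-matching disparity restricted to the fovea window.

    For a rectified, horizontally aligned pair the search is 1-D along the
    row: for each candidate disparity d the per-pixel cost is the block SAD
    between ``left[y, x]`` and ``right[y, x − d]``; the winning d is returned
    per pixel of the (clipped) window.  Returns the window disparity map and
    the (row, col) slices it covers in the full image.
    """
    li = _intensity(left)
    ri = _intensity(right)
    if li.shape != ri.shape:
        raise SegmentationError("stereo pair dimensions differ")
    ys, xs = window.clip(li.shape)
    h, w = li.shape
    costs = np.empty((max_disp + 1, ys.stop - ys.start, xs.stop - xs.start))
    big = 1e12
    for d in range(max_disp + 1):
        shifted = np.full_like(ri, big)
        if d == 0:
            shifted = ri
        else:
            shifted[:, d:] = ri[:, :-d]
        sad = ndimage.uniform_filter(np.abs(li - shifted), size=block, mode="nearest")
        costs[d] = sad[ys, xs]
    disp = np.argmin(costs, axis=0).astype(np.int32)
    return disp, (ys, xs)
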