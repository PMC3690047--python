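"""Synthetic scenes, grasp traces and calibration tables with ground truth.

No physical glove is needed to exercise the pipeline: this module renders
the inputs the hardware would produce, each paired with a machine-readable
truth record sufficient to score every downstream stage.

* :func:`render_scene` — a near-spherical fruit imaged by a pin-hole camera:
  a flat-coloured disk of pixel radius ``f·R/Z`` on a dark background, an
  optional red-saturated laser dot placed at the triangulation-consistent
  offset ``f·H/Z`` from the principal point (so single-camera laser depth is
  exercised end to end), an optional NIR frame shifted by the same
  disparity, and additive Gaussian pixel noise.  The dot colour keeps the
  channel-mean luminance of the fruit flesh so the seeded region growing
  crosses from the dot into the fruit, as it does on real frames where the
  dot blooms into fruit-lit pixels.
* :func:`simulate_trace` — a multi-finger grasp pressure record: per grasp a
  trapezoidal pulse whose plateau is the fruit's turgor pressure scaled by
  each finger's contact quality, plus Gaussian noise; mimics a session of
  grasping several fruits in sequence.
* :func:`simulate_calibration` — noisy (raw, reference) pairs drawn from a
  known transfer function, emulating the syringe-press calibration rig.

All generators are pure functions of their spec: the same spec (including
its seed) produces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import disk as draw_disk

from .calibration import CalibrationModel, CalibrationPair
from .grading import DEFAULT_FINGERS, GraspTrace
from .vision import CameraModel, disparity_for_depth

__all__ = [
    "SceneSpec",
    "SceneRender",
    "TraceSpec",
    "SimulationError",
    "DEFAULT_SIM_CAMERA",
    "render_scene",
    "simulate_trace",
    "simulate_calibration",
]


class SimulationError(ValueError):
    pass


#: Wide-angle VGA simulator camera (120 deg FOV, 2.5 cm laser baseline).
#: The wide FOV lets fruit of radius up to 4 cm at 4-7 cm depth fit in
#: frame together with a triangulation-consistent laser dot.
DEFAULT_SIM_CAMERA = CameraModel.from_fov(640, 480, 120.0, 2.5)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered fruit scene."""

    radius_cm: float = 3.0
    z_cm: float = 6.0
    camera: CameraModel = DEFAULT_SIM_CAMERA
    fruit_rgb: tuple[int, int, int] = (150, 190, 140)
    background_rgb: tuple[int, int, int] = (15, 15, 15)
    laser: bool = True
    dot_rgb: tuple[int, int, int] = (255, 150, 75)
    dot_radius_px: int = 4
    noise_sd: float = 0.0
    nir: bool = False
    nir_fruit: int = 200
    nir_background: int = 10
    seed: int = 0


@dataclass
class SceneRender:
    """A rendered scene plus its ground truth."""

    rgb: np.ndarray
    nir: np.ndarray | None
    mask: np.ndarray
    truth: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out / "scene.png", self.rgb)
        if self.nir is not None:
            iio.imwrite(out / "scene_nir.png", self.nir)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def render_scene(spec: SceneSpec) -> SceneRender:
    """Rasterize the scene described by ``spec``.

    The fruit disk is centred vertically; horizontally it is placed as close
    to the laser dot as the frame allows (the dot must land on the fruit for
    the seeded segmentation to start there).  Raises when the fruit cannot
    fit fully inside the frame.
    """
    cam = spec.camera
    if spec.radius_cm <= 0 or spec.z_cm <= 0:
        raise SimulationError("radius and depth must be positive")
    r_px = cam.f_px * spec.radius_cm / spec.z_cm
    h, w = cam.height_px, cam.width_px
    margin = 1.0
    if 2 * r_px > min(h, w) - 2 * margin:
        raise SimulationError(
            f"fruit of radius {spec.radius_cm} cm at {spec.z_cm} cm projects to "
            f"{2 * r_px:.0f} px, larger than the {w}x{h} frame"
        )
    cy = h / 2.0
    px, py = cam.principal_point
    if spec.laser:
        dot_x = px + disparity_for_depth(spec.z_cm, cam)
        dot_y = py
        # keep the dot well inside the fruit and the fruit inside the frame
        lo = max(r_px + margin, dot_x - 0.7 * r_px)
        hi = min(w - r_px - margin, dot_x + 0.7 * r_px)
        if lo > hi:
            raise SimulationError("laser dot cannot land on an in-frame fruit")
        cx = min(max(dot_x, lo), hi)
        if dot_x > w - 1 - margin:
            raise SimulationError("laser dot falls outside the frame")
    else:
        cx = w / 2.0
        dot_x = dot_y = None

    rgb = np.empty((h, w, 3), dtype=float)
    rgb[:] = spec.background_rgb
    rr, cc = draw_disk((cy, cx), r_px, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    rgb[rr, cc] = spec.fruit_rgb
    if spec.laser:
        dr, dc = draw_disk((dot_y, dot_x), spec.dot_radius_px, shape=(h, w))
        rgb[dr, dc] = spec.dot_rgb

    nir = None
    nir_shift = disparity_for_depth(spec.z_cm, cam)
    if spec.nir:
        nir_f = np.full((h, w), float(spec.nir_background))
        nrr, ncc = draw_disk((cy, cx - nir_shift), r_px, shape=(h, w))
        nir_f[nrr, ncc] = spec.nir_fruit

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
        if spec.nir:
            nir_f = nir_f + rng.normal(0.0, spec.noise_sd, nir_f.shape)
    rgb_u8 = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    if spec.nir:
        nir = np.clip(np.rint(nir_f), 0, 255).astype(np.uint8)

    truth = {
        "z_cm": spec.z_cm,
        "radius_cm": spec.radius_cm,
        "center_xy": [cx, cy],
        "r_px": r_px,
        "a_ci_px": int(mask.sum()),
        "area_cm2": float(np.pi * spec.radius_cm**2),
        "volume_cm3": float(4.0 / 3.0 * np.pi * spec.radius_cm**3),
        "dot_xy": None if dot_x is None else [float(dot_x), float(dot_y)],
        "nir_shift_px": float(nir_shift),
        "camera": {
            "width_px": cam.width_px,
            "height_px": cam.height_px,
            "f_px": cam.f_px,
            "baseline_cm": cam.baseline_cm,
        },
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
    }
    return SceneRender(rgb=rgb_u8, nir=nir, mask=mask, truth=truth)


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one simulated grasping session."""

    turgor_kpa: tuple[float, ...] = (250.0,)
    contact_quality: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    fingers: tuple[str, ...] = DEFAULT_FINGERS
    pulse_s: float = 3.0
    gap_s: float = 2.0
    rise_s: float = 0.3
    noise_sd_kpa: float = 0.0
    sample_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.contact_quality) != len(self.fingers):
            raise SimulationError("one contact quality per finger required")
        if self.pulse_s <= 2 * self.rise_s:
            raise SimulationError("pulse too short for its rise/fall ramps")
        if self.gap_s <= 0:
            raise SimulationError("grasp pulses must not overlap")


def _trapezoid(t: np.ndarray, t0: float, t1: float, rise: float) -> np.ndarray:
    """Unit-amplitude trapezoidal pulse on [t0, t1] with linear ramps."""
    up = np.clip((t - t0) / rise, 0.0, 1.0)
    down = np.clip((t1 - t) / rise, 0.0, 1.0)
    return np.minimum(up, down)


def simulate_trace(spec: TraceSpec) -> tuple[GraspTrace, dict]:
    """Simulate a session of sequential grasps.

    Each grasp ``g`` contributes, on finger ``i``, a trapezoidal pulse with
    plateau ``turgor_kpa[g] * contact_quality[i]``; Gaussian noise is added
    and the result clipped at zero (sensors read no negative pressure).
    The truth dict lists event sample boundaries and intended pressures.
    """
    n_grasps = len(spec.turgor_kpa)
    period = spec.pulse_s + spec.gap_s
    total_s = spec.gap_s + n_grasps * period
    n = int(round(total_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    rng = np.random.default_rng(spec.seed)
    pressures: dict[str, np.ndarray] = {}
    events = []
    for g, turgor in enumerate(spec.turgor_kpa):
        t0 = spec.gap_s + g * period
        t1 = t0 + spec.pulse_s
        events.append(
            {
                "start": int(round(t0 * spec.sample_rate)),
                "end": int(round(t1 * spec.sample_rate)),
                "turgor_kpa": float(turgor),
            }
        )
    for i, finger in enumerate(spec.fingers):
        v = np.zeros(n)
        for g, turgor in enumerate(spec.turgor_kpa):
            t0 = spec.gap_s + g * period
            v += turgor * spec.contact_quality[i] * _trapezoid(t, t0, t0 + spec.pulse_s, spec.rise_s)
        if spec.noise_sd_kpa > 0:
            v = v + rng.normal(0.0, spec.noise_sd_kpa, n)
        pressures[finger] = np.clip(v, 0.0, None)
    trace = GraspTrace(sample_rate=spec.sample_rate, pressures=pressures)
    truth = {
        "events": events,
        "contact_quality": dict(zip(spec.fingers, spec.contact_quality)),
        "sample_rate": spec.sample_rate,
        "seed": spec.seed,
    }
    return trace, truth


def simulate_calibration(
    true_model: CalibrationModel,
    n: int,
    noise_frac: float = 0.0,
    seed: int = 0,
    x_range: tuple[float, float] | None = None,
) -> list[CalibrationPair]:
    """Noisy calibration pairs from a known transfer function.

    ``n`` raw values on an even grid over the model's valid range (or
    ``x_range``), each reference reading perturbed multiplicatively:
    ``y = model(x)·(1 + eps)``, ``eps ~ N(0, noise_frac²)`` — emulating the
    repeat-and-average bench procedure.
    """
    if n < 2:
        raise SimulationError("need at least two calibration points")
    lo, hi = x_range if x_range is not None else true_model.valid_range
    x = np.linspace(lo, hi, n)
    y = np.asarray(true_model.predict(x), dtype=float)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + rng.normal(0.0, noise_frac, n))
    return [CalibrationPair(float(a), float(b)) for a, b in zip(x, y)]
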