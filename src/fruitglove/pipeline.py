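"""End-to-end measurement: image + optional trace -> one FruitReport.

The measurement chain mirrors a single glove interaction:

1. distance gating — the IR sensor's reading (``z_hint_cm``) wakes the
   optical path only inside its 5-25 cm activation window;
2. laser dot detection in the RGB frame, seeding the segmentation;
3. depth selection — laser triangulation when its estimate falls in the
   trusted 3-7.3 cm window, else the IR reading, else no geometry (the
   laser method is the more precise of the two, so it wins when reliable);
4. fuzzy segmentation from the seed, pixel count, distance-invariant area,
   cm² conversion, sphere radius and volume;
5. optional NIR fusion at the chosen depth;
6. grasp detection and turgor classification from the pressure trace;
7. the weighted quality score and alert flag.

Fields for stages whose inputs are missing stay ``None``; flags record why.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import segmentation as seg
from . import vision
from .config import PipelineConfig
from .grading import (
    FruitReport,
    GraspTrace,
    alert,
    classify_ripeness,
    detect_grasps,
    quality_score,
)

__all__ = ["run_measure", "PipelineError"]


class PipelineError(ValueError):
    pass


def _choose_depth(
    dot: Optional[tuple[int, int]],
    z_hint_cm: Optional[float],
    cfg: PipelineConfig,
) -> Optional[vision.DepthEstimate]:
    if dot is not None:
        px, _ = cfg.camera.principal_point
        offset = abs(dot[0] - px)
        if offset > 0:
            est = vision.laser_depth(offset, cfg.camera)
            lo, hi = cfg.laser_range_cm
            if lo <= est.Z_cm <= hi:
                return est
    if z_hint_cm is not None:
        lo, hi = cfg.ir_range_cm
        return vision.DepthEstimate(
            Z_cm=z_hint_cm, source="ir_sensor", reliable=lo <= z_hint_cm <= hi
        )
    return None


def run_measure(
    rgb: Optional[np.ndarray] = None,
    nir: Optional[np.ndarray] = None,
    trace: Optional[GraspTrace] = None,
    z_hint_cm: Optional[float] = None,
    config: Optional[PipelineConfig] = None,
) -> FruitReport:
    """Measure one fruit from an RGB frame and/or a grasp pressure trace.

    ``z_hint_cm`` plays the IR distance sensor's role.  Raises when neither
    a usable image (with detectable laser dot) nor a trace is supplied.
    """
    cfg = config or PipelineConfig()
    report = FruitReport()
    scfg = cfg.segmentation

    dot = None
    if rgb is not None:
        rgb = vision.undistort(np.asarray(rgb), cfg.camera)
        dot = seg.detect_laser_dot(
            rgb, score_threshold=scfg.dot_score_threshold, min_red=scfg.dot_min_red
        )
        if dot is None:
            report.flags.append("no_laser_dot")

    # IR activation gate: with an out-of-window IR reading and no laser dot,
    # the optical system would never have been powered on.
    if z_hint_cm is not None and not (cfg.ir_range_cm[0] <= z_hint_cm <= cfg.ir_range_cm[1]):
        report.flags.append("ir_out_of_activation_range")
        if dot is None:
            rgb = None

    if rgb is not None and dot is not None:
        depth = _choose_depth(dot, z_hint_cm, cfg)
        if depth is None:
            report.flags.append("no_depth_source")
        else:
            report.depth_cm = depth.Z_cm
            report.depth_source = depth.source
            seeds = seg.SeedSet()
            seeds.add(dot[0], dot[1], scfg.ttl_init)
            mask = seg.fuzzy_segment(
                rgb, seeds, theta=scfg.theta, sigma=scfg.sigma,
                smooth_sigma=scfg.smooth_sigma,
            )
            a_ci = seg.mask_area(mask)
            t = vision.distance_invariant_area(a_ci, depth.Z_cm, cfg.camera.f_px)
            est = vision.area_to_cm2(t, cfg.area_poly)
            if est.clamped:
                report.flags.append("area_clamped")
            report.area_cm2 = est.area_cm2
            report.radius_cm = vision.radius_from_area(est.area_cm2)
            report.volume_cm3 = vision.sphere_volume(est.area_cm2)
            if nir is not None:
                fused = vision.merge_nir(rgb, nir, depth.Z_cm, cfg.camera)
                report.flags.append(
                    "nir_fused" if not fused.oob.all() else "nir_fusion_empty"
                )

    if trace is not None:
        gcfg = cfg.grading
        events = detect_grasps(
            trace, on_kPa=gcfg.on_kpa, min_duration_s=gcfg.min_duration_s,
            valid_ratio=gcfg.valid_ratio,
        )
        if events:
            report.pressure_kPa = float(np.median([e.pressure_kPa for e in events]))
            report.ripeness = classify_ripeness(report.pressure_kPa)
            if len(events) > 1:
                report.flags.append(f"n_grasps={len(events)}")
        else:
            report.flags.append("no_grasp_detected")

    if report.pressure_kPa is None and report.area_cm2 is None:
        raise PipelineError("no usable input: need an image with a laser dot or a grasp trace")

    gcfg = cfg.grading
    features = {}
    if report.pressure_kPa is not None:
        features["pressure_kPa"] = report.pressure_kPa
    if report.volume_cm3 is not None:
        features["volume_cm3"] = report.volume_cm3
    scored = {k: v for k, v in features.items() if gcfg.weights.get(k, 0.0) > 0}
    if scored:
        report.quality = quality_score(scored, gcfg.weights, gcfg.ranges)
        report.alert = alert(report.quality, gcfg.alert_threshold)
    return report
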