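"""Sensor transfer functions and calibration fits.

The glove carries four kinds of analog sensors, each needing a mapping from
raw electrical output (volts or 10-bit ADC counts) to a physical quantity:

* an MPX5700-style pressure transducer with a manufacturer transfer function
  (:func:`transducer_pressure`), optionally corrected by a linear probe
  calibration (:func:`probe_pressure`);
* fingertip force-sensitive resistors (FSRs), whose resistance falls with
  force as an inverse power law, calibrated either with a power-law or a
  degree-2 polynomial fit (:func:`fsr_pressure`);
* a short-range IR distance sensor with a power-law distance curve
  (:func:`ir_distance`);
* finger-bend sensors, mapped to finger angle linearly
  (:func:`bend_to_angle`) or to the diameter of a grasped sphere through an
  interpolating spline over reference-sphere calibration points
  (:func:`fit_bend_spline` / :func:`bend_to_diameter`).

:func:`fit_model` fits fresh calibration tables (linear, degree-2 polynomial
or power law, the power law via log-log least squares) and reports r² on the
original scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "CalibrationPair",
    "CalibrationModel",
    "CalibrationError",
    "transducer_pressure",
    "probe_pressure",
    "fsr_pressure",
    "ir_distance",
    "IRReading",
    "fit_model",
    "fit_bend_spline",
    "bend_to_diameter",
    "bend_to_angle",
    "kgfcm2_to_kpa",
    "kpa_to_kgfcm2",
    "REFERENCE_BEND_CALIBRATION",
]

#: kPa -> kgf/cm2 (one technical atmosphere is 98.0665 kPa).
KPA_TO_KGFCM2 = 0.101972
KGFCM2_TO_KPA = 98.0665

#: Volts-per-kPa slope of the MPX5700 transfer function, as calibrated.
TRANSDUCER_SENSITIVITY_V_PER_KPA = 0.064290
#: Typical transducer offset voltage.
TRANSDUCER_OFFSET_V = 0.2

# Probe (water-chamber + transducer) linear correction, r^2 = 0.99.
PROBE_SLOPE = 0.83
PROBE_INTERCEPT = -0.02

# FSR transfer functions fitted on the syringe-press calibration rig.
FSR_POWER_COEFFS = (3.29, -2.061)          # P = 3.29 x^-2.061, r^2 = 0.99
FSR_POLY2_COEFFS = (0.0802, -0.77, 2.606)  # P = 0.0802x^2 - 0.77x + 2.606, r^2 = 0.95

# SHARP GP2D120XJ00F distance curve, D(cm) = 2736.24 adc^-0.9909.
IR_POWER_COEFFS = (2736.24, -0.9909)
#: Object-present activation gate of the IR sensor, cm.
IR_ACTIVATION_RANGE_CM = (5.0, 25.0)

#: Reference-sphere calibration of the finger-bend sensor:
#: (raw 10-bit ADC reading, sphere diameter in mm).
REFERENCE_BEND_CALIBRATION = ((887, 25.0), (859, 50.0), (826, 100.0), (809, 150.0))

_FORM_NPARAMS = {"linear": 2, "poly2": 3, "power": 2}


class CalibrationError(ValueError):
    """Raised for domain errors and degenerate calibration fits."""


@dataclass(frozen=True)
class CalibrationPair:
    """One calibration observation: raw sensor reading vs. reference value."""

    x_raw: float
    y_ref: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_raw) and math.isfinite(self.y_ref)):
            raise CalibrationError("calibration pair must be finite")


@dataclass
class CalibrationModel:
    """A fitted sensor transfer function.

    Parameters
    ----------
    form
        One of ``linear`` (y = c0·x + c1), ``poly2`` (y = c0·x² + c1·x + c2),
        ``power`` (y = c0·x^c1) or ``spline`` (natural cubic through knots).
        Polynomial coefficients are stored highest degree first, as numpy's
        ``polyval`` expects.
    coefficients
        Model coefficients; empty for ``spline`` (knots carry the data).
    knots
        ``(x, y)`` pairs for spline models, strictly increasing in x.
    valid_range
        Observed span of the raw input; evaluation outside it is
        extrapolation and flagged by :func:`bend_to_diameter`.
    """

    form: str
    coefficients: list[float] = field(default_factory=list)
    knots: list[tuple[float, float]] | None = None
    input_units: str = ""
    output_units: str = ""
    r_squared: float = 1.0
    valid_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.form in _FORM_NPARAMS:
            if len(self.coefficients) != _FORM_NPARAMS[self.form]:
                raise CalibrationError(
                    f"{self.form} model needs {_FORM_NPARAMS[self.form]} coefficients,"
                    f" got {len(self.coefficients)}"
                )
        elif self.form == "spline":
            if self.knots is None or len(self.knots) < 3:
                raise CalibrationError("spline model needs >= 3 knots")
        else:
            raise CalibrationError(f"unknown model form {self.form!r}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise CalibrationError("r_squared must lie in [0, 1]")
        if not self.valid_range[0] < self.valid_range[1]:
            raise CalibrationError("valid_range must be non-degenerate")
        self._spline = None
        if self.form == "spline":
            kx = np.asarray([k[0] for k in self.knots], dtype=float)
            ky = np.asarray([k[1] for k in self.knots], dtype=float)
            self._spline = CubicSpline(kx, ky, bc_type="natural")

    def predict(self, x):
        """Evaluate the transfer function at ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        if self.form == "linear" or self.form == "poly2":
            y = np.polyval(self.coefficients, x)
        elif self.form == "power":
            a, b = self.coefficients
            if np.any(x <= 0):
                raise CalibrationError("power model requires x > 0")
            y = a * np.power(x, b)
        else:
            y = self._spline(x)
        return float(y) if y.ndim == 0 else y

    __call__ = predict

    def to_dict(self) -> dict:
        d = {
            "form": self.form,
            "coefficients": [float(c) for c in self.coefficients],
            "input_units": self.input_units,
            "output_units": self.output_units,
            "r_squared": round(float(self.r_squared), 6),
            "valid_range": [float(v) for v in self.valid_range],
        }
        if self.knots is not None:
            d["knots"] = [[float(x), float(y)] for x, y in self.knots]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            form=d["form"],
            coefficients=list(d.get("coefficients", [])),
            knots=[tuple(k) for k in d["knots"]] if "knots" in d else None,
            input_units=d.get("input_units", ""),
            output_units=d.get("output_units", ""),
            r_squared=d.get("r_squared", 1.0),
            valid_range=tuple(d.get("valid_range", (0.0, 1.0))),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def transducer_pressure(X: float, A: float = TRANSDUCER_OFFSET_V) -> float:
    """Pressure (kgf/cm²) from the MPX5700 transducer output voltage.

    ``(X − A) / 0.064290`` converts volts above the offset ``A`` to kPa;
    the 0.101972 factor converts kPa to kgf/cm².  Negative values are
    returned unclamped — the caller decides how to treat sub-offset output.
    """
    if not math.isfinite(X):
        raise CalibrationError("X must be finite")
    return ((X - A) / TRANSDUCER_SENSITIVITY_V_PER_KPA) * KPA_TO_KGFCM2


def probe_pressure(P0: float) -> float:
    """Probe-corrected pressure (kgf/cm²) from transducer pressure ``P0``."""
    if not math.isfinite(P0):
        raise CalibrationError("P0 must be finite")
    return PROBE_SLOPE * P0 + PROBE_INTERCEPT


def fsr_pressure(x: float, form: str = "power"):
    """Fingertip pressure (kgf/cm²) from FSR voltage ``x``.

    ``form='power'`` uses the inverse power law 3.29·x^−2.061 (the FSR's
    theoretical response and the better fit, r²=0.99); ``form='poly2'``
    uses the degree-2 polynomial alternative (r²=0.95).
    """
    x = np.asarray(x, dtype=float)
    if form == "power":
        if np.any(x <= 0):
            raise CalibrationError("power-form FSR calibration requires x > 0")
        a, b = FSR_POWER_COEFFS
        y = a * np.power(x, b)
    elif form == "poly2":
        y = np.polyval(FSR_POLY2_COEFFS, x)
    else:
        raise CalibrationError(f"unknown FSR form {form!r}")
    return float(y) if y.ndim == 0 else y


@dataclass(frozen=True)
class IRReading:
    distance_cm: float
    in_activation_range: bool


def ir_distance(adc: float) -> IRReading:
    """Distance (cm) from the IR sensor's raw ADC value, with activation gate.

    The sensor's voltage-distance curve is non-linear; the fitted power law
    D = 2736.24·adc^−0.9909 inverts it.  ``in_activation_range`` is True when
    the distance falls in the 5-25 cm window that wakes the optical system.
    """
    if not (math.isfinite(adc) and adc > 0):
        raise CalibrationError("IR reading requires adc > 0")
    a, b = IR_POWER_COEFFS
    d = a * adc**b
    lo, hi = IR_ACTIVATION_RANGE_CM
    return IRReading(distance_cm=d, in_activation_range=lo <= d <= hi)


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def _as_xy(pairs: Iterable[CalibrationPair]) -> tuple[np.ndarray, np.ndarray]:
    pts = list(pairs)
    x = np.asarray([p.x_raw for p in pts], dtype=float)
    y = np.asarray([p.y_ref for p in pts], dtype=float)
    return x, y


def fit_model(
    pairs: Sequence[CalibrationPair],
    form: str,
    input_units: str = "",
    output_units: str = "",
) -> CalibrationModel:
    """Least-squares fit of a calibration table.

    Power-law fits run as ordinary least squares in log-log space (requires
    strictly positive x and y); r² is always reported on the original scale,
    so the three forms are directly comparable.
    """
    if form not in _FORM_NPARAMS:
        raise CalibrationError(f"fit_model cannot fit form {form!r}")
    x, y = _as_xy(pairs)
    n_min = _FORM_NPARAMS[form]
    if x.size < n_min:
        raise CalibrationError(f"{form} fit needs >= {n_min} pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate calibration table: constant x_raw")
    if form == "linear":
        coeffs = np.polyfit(x, y, 1)
        y_hat = np.polyval(coeffs, x)
    elif form == "poly2":
        coeffs = np.polyfit(x, y, 2)
        y_hat = np.polyval(coeffs, x)
    else:  # power
        if np.any(x <= 0) or np.any(y <= 0):
            raise CalibrationError("power fit requires x_raw > 0 and y_ref > 0")
        b, log_a = np.polyfit(np.log(x), np.log(y), 1)
        coeffs = np.array([math.exp(log_a), b])
        y_hat = coeffs[0] * np.power(x, coeffs[1])
    return CalibrationModel(
        form=form,
        coefficients=[float(c) for c in coeffs],
        input_units=input_units,
        output_units=output_units,
        r_squared=_r_squared(y, y_hat),
        valid_range=(float(x.min()), float(x.max())),
    )


def fit_bend_spline(
    pairs: Sequence[CalibrationPair] = None,
    input_units: str = "adc",
    output_units: str = "mm",
) -> CalibrationModel:
    """Natural cubic interpolating spline through bend-sensor knots.

    Defaults to the reference-sphere calibration table
    (:data:`REFERENCE_BEND_CALIBRATION`).  x_raw must be strictly monotone;
    knots are stored sorted by ascending ADC value and the spline passes
    exactly through every knot.
    """
    if pairs is None:
        pairs = [CalibrationPair(x, y) for x, y in REFERENCE_BEND_CALIBRATION]
    x, y = _as_xy(pairs)
    if x.size < 3:
        raise CalibrationError("spline needs >= 3 calibration pairs")
    d = np.diff(x)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise CalibrationError("spline calibration requires strictly monotone x_raw")
    order = np.argsort(x)
    x, y = x[order], y[order]
    return CalibrationModel(
        form="spline",
        knots=[(float(a), float(b)) for a, b in zip(x, y)],
        input_units=input_units,
        output_units=output_units,
        r_squared=1.0,
        valid_range=(float(x[0]), float(x[-1])),
    )


@dataclass(frozen=True)
class DiameterEstimate:
    diameter_mm: float
    extrapolated: bool


def bend_to_diameter(model: CalibrationModel, raw: float) -> DiameterEstimate:
    """Grasped-sphere diameter from a raw bend reading via the spline.

    Readings outside the calibrated ADC span are clamped to the nearest
    knot and flagged ``extrapolated``.
    """
    if model.form != "spline":
        raise CalibrationError("bend_to_diameter needs a spline model")
    lo, hi = model.valid_range
    clamped = min(max(float(raw), lo), hi)
    return DiameterEstimate(
        diameter_mm=float(model.predict(clamped)),
        extrapolated=not (lo <= raw <= hi),
    )


def bend_to_angle(
    raw: float, closed_ref: float, open_ref: float, full_angle_deg: float = 180.0
) -> float:
    """Finger angle (degrees) from a raw bend reading.

    Linear map through the two per-user calibration endpoints: the
    completely-closed reading maps to 0° and the completely-open reading to
    ``full_angle_deg`` (convention; configurable).  Clamped to the range.
    """
    if closed_ref == open_ref:
        raise CalibrationError("closed and open references must differ")
    frac = (raw - closed_ref) / (open_ref - closed_ref)
    return full_angle_deg * min(max(frac, 0.0), 1.0)


def kgfcm2_to_kpa(p: float) -> float:
    """kgf/cm² -> kPa (1 kgf/cm² = 98.0665 kPa)."""
    return p * KGFCM2_TO_KPA


def kpa_to_kgfcm2(p: float) -> float:
    """kPa -> kgf/cm²."""
    return p / KGFCM2_TO_KPA
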