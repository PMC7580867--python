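"""Fluorescence <-> pH calibration for the carboxyfluorescein indicator.

The standard curve is a 4-parameter log-sigmoid in pH,

    RFU(pH) = r_min + (r_max - r_min) / (1 + 10**(hill * (pKa' - pH)))

which matches fluorescein-type photochemistry (apparent pKa near 6.4,
ex/em 485/535 nm).  When the sigmoid cannot describe the standards, the
fit falls back to shape-free monotone interpolation of the standards
themselves.  Both directions of the map are exposed; the inverse is
analytic in sigmoid mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, isotonic_regression

from .errors import CalibrationError, OperatingRangeError


@dataclass(frozen=True)
class CalibrationStandard:
    """One standard: medium with indicator set to a known pH."""

    ph: float
    rfu: float

    def __post_init__(self):
        if not self.rfu >= 0:
            raise CalibrationError("standard RFU must be non-negative")


def _sigmoid(ph, r_min, r_max, apparent_pka, hill_slope):
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (hill_slope * (apparent_pka - ph)))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted, invertible pH -> RFU map over ``valid_ph_range``.

    ``fallback_points`` is ``None`` in sigmoid mode; in interpolation mode
    it holds the monotone (ph, rfu) node arrays and the sigmoid parameters
    describe only the node envelope (r_min/r_max are the end-point RFUs).
    """

    r_min: float
    r_max: float
    apparent_pka: float
    hill_slope: float
    valid_ph_range: tuple[float, float]
    fit_residual_rms: float = 0.0
    fallback_points: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if not (self.r_max > self.r_min >= 0):
            raise CalibrationError("calibration requires r_max > r_min >= 0")
        lo, hi = self.valid_ph_range
        if not hi > lo:
            raise CalibrationError("valid_ph_range must be increasing")

    @property
    def is_interpolated(self) -> bool:
        return self.fallback_points is not None

    def _forward(self, ph):
        """Evaluate the map with no range checks (simulator internals)."""
        if self.is_interpolated:
            nodes_ph, nodes_rfu = self.fallback_points
            return np.interp(ph, nodes_ph, nodes_rfu)
        return _sigmoid(ph, self.r_min, self.r_max, self.apparent_pka, self.hill_slope)

    def ph_to_rfu(self, ph):
        """Expected RFU at ``ph``; errors outside ``valid_ph_range``."""
        arr = np.atleast_1d(np.asarray(ph, dtype=float))
        lo, hi = self.valid_ph_range
        if np.any(arr < lo - 1e-9) or np.any(arr > hi + 1e-9):
            raise OperatingRangeError(
                f"pH outside calibration range [{lo:.3f}, {hi:.3f}]"
            )
        out = self._forward(arr)
        return float(out[0]) if np.ndim(ph) == 0 else out

    def rfu_to_ph(self, rfu, ph_tol: float = 0.05):
        """pH at an observed ``rfu``.

        Sigmoid mode uses the exact analytic inverse; interpolation mode
        the monotone inverse of the node table.  Readings mapping up to
        ``ph_tol`` beyond ``valid_ph_range`` are clamped with a warning;
        anything further (or at/beyond the sigmoid asymptotes) raises
        :class:`OperatingRangeError`.
        """
        arr = np.atleast_1d(np.asarray(rfu, dtype=float))
        lo, hi = self.valid_ph_range
        if self.is_interpolated:
            nodes_ph, nodes_rfu = self.fallback_points
            if np.any(arr < nodes_rfu[0]) or np.any(arr > nodes_rfu[-1]):
                raise OperatingRangeError(
                    "RFU outside the interpolation range of the standards"
                )
            ph = np.interp(arr, nodes_rfu, nodes_ph)
        else:
            if np.any(arr <= self.r_min) or np.any(arr >= self.r_max):
                raise OperatingRangeError(
                    f"RFU at or beyond the calibration asymptotes "
                    f"({self.r_min:.0f}, {self.r_max:.0f})"
                )
            ph = self.apparent_pka - np.log10(
                (self.r_max - self.r_min) / (arr - self.r_min) - 1.0
            ) / self.hill_slope
        if np.any(ph < lo - ph_tol) or np.any(ph > hi + ph_tol):
            raise OperatingRangeError(
                f"RFU maps outside the calibrated pH range [{lo:.3f}, {hi:.3f}]"
            )
        clipped = np.clip(ph, lo, hi)
        if np.any(clipped != ph):
            warnings.warn(
                f"pH clamped to calibration range [{lo:.3f}, {hi:.3f}]",
                stacklevel=2,
            )
        return float(clipped[0]) if np.ndim(rfu) == 0 else clipped


def _coerce_standards(standards):
    pairs = []
    for s in standards:
        if isinstance(s, CalibrationStandard):
            pairs.append((s.ph, s.rfu))
        else:
            ph, rfu = s
            pairs.append((float(ph), float(rfu)))
    arr = np.asarray(pairs, dtype=float)
    order = np.argsort(arr[:, 0])
    return arr[order, 0], arr[order, 1]


def fit_calibration(
    standards,
    residual_ceiling_frac: float = 0.05,
    monotone_tolerance_frac: float = 0.10,
    force_interpolation: bool = False,
) -> CalibrationCurve:
    """Least-squares sigmoid fit of calibration standards.

    Requires at least 4 standards spanning at least 1.5 pH units and a
    monotone (up to noise) RFU-vs-pH trend.  If the sigmoid fit fails to
    converge or its residual RMS exceeds ``residual_ceiling_frac`` of the
    fitted dynamic range, the curve falls back to monotone interpolation
    of the (isotonic-regressed) standards.

    ``standards`` may be :class:`CalibrationStandard` objects, ``(ph,
    rfu)`` pairs, or anything iterable yielding such pairs.
    """
    ph, rfu = _coerce_standards(standards)
    if len(ph) < 4:
        raise CalibrationError(
            f"need at least 4 calibration standards, got {len(ph)}"
        )
    span = ph[-1] - ph[0]
    if span < 1.5:
        raise CalibrationError(
            f"standards span only {span:.2f} pH units; need >= 1.5"
        )
    if np.any(np.isnan(rfu)) or np.any(rfu < 0):
        raise CalibrationError("standard RFU values must be finite and >= 0")
    data_range = float(rfu.max() - rfu.min())
    if data_range <= 0:
        raise CalibrationError("standards have zero dynamic range")
    drops = np.diff(rfu)
    if np.any(drops < -monotone_tolerance_frac * data_range):
        raise CalibrationError(
            "standards are non-monotone beyond the noise tolerance; "
            "check plate handling or gain settings"
        )
    valid_range = (float(ph[0]), float(ph[-1]))

    if not force_interpolation:
        p0 = (float(rfu.min()), float(rfu.max()), float(np.median(ph)), 1.0)
        bounds = (
            [0.0, 0.0, ph[0] - 3.0, 0.05],
            [np.inf, np.inf, ph[-1] + 3.0, 20.0],
        )
        try:
            popt, _ = curve_fit(_sigmoid, ph, rfu, p0=p0, bounds=bounds, maxfev=20000)
            resid = rfu - _sigmoid(ph, *popt)
            rms = float(np.sqrt(np.mean(resid**2)))
            fitted_range = popt[1] - popt[0]
            if fitted_range > 0 and rms <= residual_ceiling_frac * fitted_range:
                return CalibrationCurve(
                    r_min=float(popt[0]),
                    r_max=float(popt[1]),
                    apparent_pka=float(popt[2]),
                    hill_slope=float(popt[3]),
                    valid_ph_range=valid_range,
                    fit_residual_rms=rms,
                )
        except RuntimeError:
            pass  # no convergence: fall through to interpolation

    # monotone fallback: isotonic regression, ties broken by a tiny ramp
    iso = isotonic_regression(rfu).x
    iso = iso + np.arange(len(iso)) * (1e-9 * max(data_range, 1.0))
    # average duplicated pH nodes so np.interp sees strictly increasing x
    uniq_ph, inverse = np.unique(ph, return_inverse=True)
    uniq_rfu = np.array([iso[inverse == i].mean() for i in range(len(uniq_ph))])
    rms = float(np.sqrt(np.mean((iso - rfu) ** 2)))
    return CalibrationCurve(
        r_min=float(uniq_rfu[0]),
        r_max=float(uniq_rfu[-1]),
        apparent_pka=float("nan"),
        hill_slope=float("nan"),
        valid_ph_range=valid_range,
        fit_residual_rms=rms,
        fallback_points=(uniq_ph, uniq_rfu),
    )


def rfu_to_ph(curve: CalibrationCurve, rfu, **kwargs):
    """Functional alias for :meth:`CalibrationCurve.rfu_to_ph`."""
    return curve.rfu_to_ph(rfu, **kwargs)


def ph_to_rfu(curve: CalibrationCurve, ph):
    """Functional alias for :meth:`CalibrationCurve.ph_to_rfu`."""
    return curve.ph_to_rfu(ph)
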