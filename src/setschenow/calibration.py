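"""Beer-Lambert calibration and quantification of UV-Vis readings.

A calibration line ``A = l*eps*m (+ intercept)`` is fitted to standards at
a fixed analytical wavelength; saturated-solution absorbances (after
dilution) are inverted through it to total solubilities.  The limit of
detection follows the usual ``3.3 * s_residual / slope`` convention with a
configurable multiplier, since real curves drift a free intercept is the
default and a strict through-origin mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateFitError, InsufficientDataError

__all__ = [
    "Spectrum",
    "CalibrationCurve",
    "QuantifiedValue",
    "pick_peak",
    "fit_calibration",
    "quantify",
    "aggregate_replicates",
]

#: Instrument absorbance resolution (the readout is quantized to this step).
ABSORBANCE_RESOLUTION = 1e-3


@dataclass(frozen=True)
class Spectrum:
    """One cuvette reading: absorbance on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise ValueError("wavelengths and absorbances must be equal-length 1-D")
        if wl.size and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted Beer-Lambert line.

    ``slope`` is ``l * eps`` in absorbance per (mol/kg); ``lod`` is the
    limit of detection on the cuvette concentration scale.
    """

    slope: float
    intercept: float
    r_squared: float
    lod: float
    range: tuple[float, float]
    residual_sd: float = 0.0
    n: int = 0
    through_origin: bool = False
    lod_factor: float = 3.3


@dataclass(frozen=True)
class QuantifiedValue:
    """Concentration from one absorbance reading, with quality flags.

    ``value`` is on the undiluted-sample scale; the flags refer to the
    cuvette-scale concentration compared with the calibration.
    """

    value: float
    below_lod: bool = False
    extrapolated: bool = False
    below_blank: bool = False

    def __float__(self) -> float:
        return float(self.value)


def pick_peak(
    spectrum: Spectrum, window: tuple[float, float]
) -> tuple[float, float]:
    """Wavelength and absorbance of the maximum inside ``window``.

    Ties are broken toward the lower wavelength.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window must satisfy lo <= hi")
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no grid points")
    wl = spectrum.wavelengths[mask]
    ab = spectrum.absorbances[mask]
    i = int(np.argmax(ab))  # argmax returns the first (lowest-nm) maximum
    return float(wl[i]), float(ab[i])


def fit_calibration(
    standards: list[tuple[float, float]],
    through_origin: bool = False,
    lod_factor: float = 3.3,
) -> CalibrationCurve:
    """Least-squares calibration line from (molality, absorbance) standards."""
    if len(standards) < 3:
        raise InsufficientDataError(
            f"need >= 3 standards, got {len(standards)}"
        )
    m = np.asarray([s[0] for s in standards], dtype=float)
    a = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(m) <= 0:
        raise DegenerateFitError("standards span a zero molality range")

    if through_origin:
        design = m[:, None]
    else:
        design = np.column_stack([np.ones_like(m), m])
    coef, _, rank, _ = np.linalg.lstsq(design, a, rcond=None)
    if rank < design.shape[1]:
        raise DegenerateFitError("singular calibration design")
    if through_origin:
        intercept, slope = 0.0, float(coef[0])
    else:
        intercept, slope = float(coef[0]), float(coef[1])
    if slope <= 0:
        raise DegenerateFitError(f"non-positive calibration slope {slope}")

    fitted = design @ coef
    rss = float(np.sum((a - fitted) ** 2))
    dof = len(m) - design.shape[1]
    residual_sd = float(np.sqrt(rss / dof)) if dof > 0 else 0.0
    tss = float(np.sum((a - a.mean()) ** 2))
    r_squared = 1.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        lod=lod_factor * residual_sd / slope,
        range=(float(m.min()), float(m.max())),
        residual_sd=residual_sd,
        n=len(m),
        through_origin=through_origin,
        lod_factor=lod_factor,
    )


def quantify(
    a: float, curve: CalibrationCurve, dilution_factor: float = 1.0
) -> QuantifiedValue:
    """Invert the calibration line for one absorbance reading.

    A negative back-calculated concentration (reading below the blank) is
    returned as-is with ``below_blank=True`` rather than raised, so that
    replicate averaging stays unbiased near zero.
    """
    if a < 0:
        raise ValueError("absorbance must be non-negative")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    c_cuvette = (a - curve.intercept) / curve.slope
    lo, hi = curve.range
    return QuantifiedValue(
        value=dilution_factor * c_cuvette,
        below_lod=c_cuvette < curve.lod,
        extrapolated=not (lo <= c_cuvette <= hi),
        below_blank=c_cuvette < 0,
    )


def aggregate_replicates(values: list[float]) -> tuple[float, float, int]:
    """Sample mean, sample sd (n-1 denominator; 0 when n=1) and count."""
    if len(values) == 0:
        raise InsufficientDataError("no replicate values")
    arr = np.asarray([float(v) for v in values])
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)
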