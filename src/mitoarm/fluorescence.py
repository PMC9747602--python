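"""Intrinsic tryptophan fluorescence and nanoDSF melt-curve analytics.

Three operations:

* :func:`emission_summary` — buffer-correct an emission spectrum and report
  the emission maximum λmax and the intensity at a chosen analysis
  wavelength (341 nm by default, where quench ratios are measured).
* :func:`stern_volmer_fit` — fit F₀/F = 1 + Ksv·[Q] to a collisional
  quenching series; the intercept is fixed at 1 by definition of F₀/F
  (a free-intercept diagnostic mode is available).  Larger Ksv means the
  fluorophore is more solvent accessible.
* :func:`melting_temperature` — extract Tm from a nanoDSF 330 nm/350 nm
  ratio melt curve as the temperature of the first-derivative maximum,
  optionally after moving-average smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoTransitionError, UndefinedMetricError, ValidationError

__all__ = [
    "EmissionSummary",
    "QuenchFit",
    "MeltFit",
    "emission_summary",
    "stern_volmer_fit",
    "melting_temperature",
    "DEFAULT_ANALYSIS_WAVELENGTH_NM",
]

DEFAULT_ANALYSIS_WAVELENGTH_NM = 341.0


@dataclass(frozen=True)
class EmissionSummary:
    corrected: np.ndarray          # buffer-corrected intensities
    wavelengths: np.ndarray        # nm grid
    lambda_max: float | None       # None when the corrected signal is flat
    intensity_at: float            # corrected intensity at analysis wavelength
    analysis_wavelength: float


@dataclass(frozen=True)
class QuenchFit:
    ksv: float           # M^-1
    ksv_err: float
    intercept: float     # 1.0 in fixed mode
    intercept_fixed: bool


@dataclass(frozen=True)
class MeltFit:
    tm: float                    # deg C
    temperatures: np.ndarray     # grid on which the derivative is defined
    derivative: np.ndarray
    smoothing_window: int
    sign: int


def emission_summary(
    wavelengths,
    intensity,
    buffer_intensity=None,
    analysis_wavelength: float = DEFAULT_ANALYSIS_WAVELENGTH_NM,
) -> EmissionSummary:
    """Buffer-correct a spectrum; report λmax and the intensity at one λ.

    The buffer spectrum (same grid) is subtracted pointwise when given.
    λmax is the wavelength of the maximum corrected intensity, lowest
    wavelength on ties; when the corrected spectrum is flat (e.g. buffer
    equals sample) λmax is reported as None.  The analysis-wavelength
    intensity is linearly interpolated on the grid.
    """
    wl = np.asarray(wavelengths, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if wl.shape != y.shape:
        raise ValidationError("wavelength and intensity grids differ in length")
    if len(wl) < 2 or not np.all(np.diff(wl) > 0):
        raise ValidationError("wavelength grid must be strictly increasing")
    if buffer_intensity is not None:
        buf = np.asarray(buffer_intensity, dtype=float)
        if buf.shape != y.shape:
            raise ValidationError("buffer spectrum grid mismatch")
        y = y - buf
    if not (wl[0] <= analysis_wavelength <= wl[-1]):
        raise ValidationError(
            f"analysis wavelength {analysis_wavelength} nm outside grid")
    lam_max = None if np.ptp(y) == 0 else float(wl[int(np.argmax(y))])
    at = float(np.interp(analysis_wavelength, wl, y))
    return EmissionSummary(corrected=y, wavelengths=wl, lambda_max=lam_max,
                           intensity_at=at,
                           analysis_wavelength=analysis_wavelength)


def stern_volmer_fit(
    concentrations_m, f0_over_f, intercept_fixed: bool = True
) -> QuenchFit:
    """Least-squares Stern–Volmer fit F₀/F = 1 + Ksv·[Q].

    With the intercept fixed at 1 (default, matching the definition of
    F₀/F) the slope is the exact least-squares solution
    Ksv = Σ c·(y−1) / Σ c²; its uncertainty comes from the residual
    variance.  Free-intercept mode performs ordinary linear regression.
    """
    c = np.asarray(concentrations_m, dtype=float)
    y = np.asarray(f0_over_f, dtype=float)
    if c.shape != y.shape:
        raise ValidationError("concentration and ratio arrays differ in length")
    if len(c) < 2:
        raise ValidationError("need >= 2 points")
    if np.ptp(c) == 0:
        raise ValidationError("all quencher concentrations are identical")
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite F0/F ratios")
    if intercept_fixed:
        ksv = float(np.sum(c * (y - 1)) / np.sum(c**2))
        resid = y - (1 + ksv * c)
        dof = len(c) - 1
        s2 = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
        ksv_err = float(np.sqrt(s2 / np.sum(c**2)))
        return QuenchFit(ksv=ksv, ksv_err=ksv_err, intercept=1.0,
                         intercept_fixed=True)
    design = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = len(c) - 2
    s2 = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(design.T @ design)
    return QuenchFit(ksv=float(coef[1]), ksv_err=float(np.sqrt(cov[1, 1])),
                     intercept=float(coef[0]), intercept_fixed=False)


def _moving_average(t: np.ndarray, y: np.ndarray, window: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average; returns the trimmed grid and smoothed signal.

    Only fully covered points are kept (``valid`` convolution): edge
    extrapolation would distort sloped baselines, and the melt midpoint is
    interior by definition."""
    if window <= 1:
        return t, y
    kernel = np.ones(window) / window
    half = window // 2
    return t[half:len(t) - half], np.convolve(y, kernel, mode="valid")


def melting_temperature(
    temperatures_c,
    signal,
    smoothing_window: int = 5,
    sign: int = 1,
) -> MeltFit:
    """Tm as the temperature of the first-derivative maximum.

    The signal (330/350 nm ratio) is optionally smoothed with a centered
    moving average (default 5 points), differentiated by central
    differences, and the maximum of ``sign * derivative`` located; ties go
    to the lowest temperature.  ``sign=-1`` handles ratio conventions where
    the transition decreases the signal.

    A curve with no transition — flat, or with its (signed) derivative
    maximal at the scan boundary, as for a pure linear baseline — raises
    :class:`NoTransitionError`: a genuine unfolding midpoint lies strictly
    inside the scanned range.
    """
    t = np.asarray(temperatures_c, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape:
        raise ValidationError("temperature and signal grids differ in length")
    if len(t) < 10:
        raise ValidationError("need >= 10 grid points spanning the transition")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("temperature grid must be strictly increasing")
    if sign not in (1, -1):
        raise ValidationError("sign must be +1 or -1")
    t_s, smoothed = _moving_average(t, y, smoothing_window)
    deriv = sign * np.gradient(smoothed, t_s)
    # a flat or purely linear curve has a constant derivative up to float
    # rounding; require genuine variation relative to the derivative scale
    if np.ptp(deriv) <= 1e-9 * max(1.0, float(np.abs(deriv).max())):
        raise NoTransitionError("derivative is constant: no transition")
    idx = int(np.argmax(deriv))
    if idx == 0 or idx == len(t_s) - 1:
        raise NoTransitionError(
            "derivative maximum at scan boundary: no transition inside range")
    return MeltFit(tm=float(t_s[idx]), temperatures=t_s, derivative=deriv,
                   smoothing_window=smoothing_window, sign=sign)
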