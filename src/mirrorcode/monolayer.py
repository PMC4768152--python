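"""Langmuir-monolayer peptide insertion analysis.

Two desk-scale analyses of surface-pressure data:

* adsorption kinetics: a mono-exponential rise
  dpi(t) = dpi_max * (1 - exp(-k t)) fitted by least squares, with the
  initial insertion velocity v0 = k * dpi_max;
* critical insertion pressure: the maximal pressure increase dpi_max induced
  by a peptide falls roughly linearly with the initial monolayer pressure
  pi0; the x-intercept of the ordinary-least-squares line
  dpi_max = a + b * pi0 is the critical pressure pi_c = -a/b, the monolayer
  density above which the peptide can no longer insert.  A high pi_c means
  high avidity of the peptide for the lipid film; the surface pressure of a
  natural plasma membrane (~30 mN/m) is the usual benchmark.

Units: time in minutes, pressures in mN/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PressureKinetics",
    "InsertionIsotherm",
    "KineticsFit",
    "PiCEstimate",
    "fit_kinetics",
    "estimate_pic",
    "EstimationError",
]


class EstimationError(ValueError):
    """The data do not admit the requested estimate."""


@dataclass(frozen=True)
class PressureKinetics:
    """A pressure-increase trace dpi(t) after peptide injection at t=0."""

    time: tuple[float, ...]  # minutes, strictly increasing
    delta_pi: tuple[float, ...]  # mN/m

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.delta_pi, dtype=float)
        if t.shape != d.shape:
            raise ValueError("time and delta_pi must have equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")


@dataclass(frozen=True)
class InsertionIsotherm:
    """(pi0, dpi_max) points measured on monolayers of varying density."""

    pi0: tuple[float, ...]  # mN/m, initial surface pressure
    delta_pi_max: tuple[float, ...]  # mN/m

    def __post_init__(self) -> None:
        p = np.asarray(self.pi0, dtype=float)
        d = np.asarray(self.delta_pi_max, dtype=float)
        if p.shape != d.shape:
            raise ValueError("pi0 and delta_pi_max must have equal length")
        if len(p) and p.min() < 0:
            raise ValueError("pi0 must be non-negative")


@dataclass(frozen=True)
class KineticsFit:
    delta_pi_max: float  # mN/m
    rate: float  # 1/min
    v0: float  # mN/m/min, = rate * delta_pi_max
    converged: bool  # False when the fallback finite-difference slope was used


@dataclass(frozen=True)
class PiCEstimate:
    pi_c: float  # mN/m, x-intercept of the fitted line
    slope: float
    intercept: float
    residual_rms: float


def fit_kinetics(data: PressureKinetics) -> KineticsFit:
    """Fit dpi(t) = dpi_max (1 - e^{-kt}) and report (dpi_max, k, v0).

    Requires >= 4 points.  An all-zero trace returns (0, 0, 0) unconverged.
    If the non-linear fit fails, the initial velocity falls back to the
    finite-difference slope over the first two points (flagged by
    ``converged=False``).
    """
    t = np.asarray(data.time, dtype=float)
    d = np.asarray(data.delta_pi, dtype=float)
    if len(t) < 4:
        raise EstimationError(f"kinetics fit needs >= 4 points, got {len(t)}")
    if np.any(d < 0):
        warnings.warn("negative delta_pi values in kinetics trace", stacklevel=2)
    if np.allclose(d, 0.0):
        return KineticsFit(0.0, 0.0, 0.0, converged=False)

    def model(t, dmax, k):
        return dmax * (1.0 - np.exp(-k * t))

    d_guess = float(d.max())
    t_scale = t[len(t) // 2] if t[len(t) // 2] > 0 else 1.0
    try:
        popt, _ = optimize.curve_fit(
            model, t, d, p0=(d_guess, 1.0 / t_scale), maxfev=10000
        )
        dmax, k = float(popt[0]), float(popt[1])
        if not (np.isfinite(dmax) and np.isfinite(k)):
            raise RuntimeError("non-finite fit")
        return KineticsFit(dmax, k, k * dmax, converged=True)
    except (RuntimeError, optimize.OptimizeWarning):
        dt = t[1] - t[0]
        v0 = float((d[1] - d[0]) / dt)
        return KineticsFit(float(d.max()), float("nan"), v0, converged=False)


def estimate_pic(isotherm: InsertionIsotherm) -> PiCEstimate:
    """Extrapolate the critical insertion pressure from an isotherm.

    Ordinary least squares of dpi_max on pi0; pi_c is the x-intercept -a/b.
    The slope must be negative (insertion decreasing with film density);
    otherwise no critical pressure exists and an :class:`EstimationError` is
    raised.  Two exact points define the line; three or more are recommended.
    """
    p = np.asarray(isotherm.pi0, dtype=float)
    d = np.asarray(isotherm.delta_pi_max, dtype=float)
    if len(p) < 2:
        raise EstimationError("pi_c estimation needs >= 2 points")
    if len(np.unique(p)) < 2:
        raise EstimationError("pi_c estimation needs >= 2 distinct pi0 values")
    if np.any(d < 0):
        warnings.warn("negative delta_pi_max values in isotherm", stacklevel=2)

    fit = stats.linregress(p, d)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope >= 0:
        raise EstimationError(
            f"slope {slope:.4g} >= 0: delta_pi_max does not decrease with pi0, "
            "no extrapolable pi_c"
        )
    resid = d - (intercept + slope * p)
    return PiCEstimate(
        pi_c=-intercept / slope,
        slope=slope,
        intercept=intercept,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def synthetic_isotherm(
    pi_c: float,
    slope: float,
    pi0_values: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> InsertionIsotherm:
    """Build a linear isotherm with given x-intercept and slope (+ noise).

    ``slope`` must be negative; the intercept is ``-slope * pi_c``.  Gaussian
    noise of standard deviation ``noise_sd`` (mN/m) emulates instrument
    accuracy.
    """
    if slope >= 0:
        raise ValueError("slope must be negative")
    rng = np.random.default_rng(seed)
    p = np.asarray(pi0_values, dtype=float)
    d = -slope * pi_c + slope * p
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, size=len(p))
    return InsertionIsotherm(pi0=tuple(p), delta_pi_max=tuple(d))
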