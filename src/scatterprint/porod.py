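"""Porod analysis: plateau, specific surface area and equivalent radius.

For a sharp interface the scattering approaches I(Q) -> K * Q^-4 at high Q
(Porod law), with K = 2 pi (delta_rho)^2 * S_v where S_v is interfacial area
per unit sample volume and delta_rho the scattering-length-density contrast
between dispersed phase and medium.  With I in absolute cm^-1 and both Q and
delta_rho in Angstrom units, Q^4 / delta_rho^2 is dimensionless, so

    S_v = K / (2 pi delta_rho^2)           [cm^-1, per sample volume]
    S   = S_v / phi                        [cm^-1, per dispersed volume]
    r   = 3 / S                            (spheres: A/V = 3/r)

phi is the dispersed-phase volume fraction, derived here from the fat mass
fraction when composition data are used (oil density 0.92 g/mL, product
density 1.0 g/mL by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ScatteringCurve

#: X-ray scattering length densities, inverse square Angstrom
SLD_OIL = 8.7e-6
SLD_WATER = 9.47e-6
DEFAULT_DELTA_RHO = SLD_WATER - SLD_OIL

OIL_DENSITY = 0.92   # g/mL
PRODUCT_DENSITY = 1.0

CM_PER_UM = 1e-4


class PorodRegimeError(ValueError):
    """Fit range does not show Porod (slope -4) behaviour."""


@dataclass(frozen=True)
class PorodResult:
    """Outcome of a Porod surface-area estimate."""

    plateau: float                     # lim I Q^4, cm^-1 (I cm^-1, Q in 1/A)
    plateau_se: float                  # standard error of the plateau
    delta_rho: float                   # contrast, 1/A^2
    dispersed_volume_fraction: float
    surface_per_sample_volume: float   # S_v, cm^-1
    specific_surface_area: float       # S = S_v / phi, cm^-1
    equivalent_radius_um: float        # r = 3/S, micrometres
    fit_range: tuple[float, float]
    slope: float                       # local log-log slope over fit range


def fat_volume_fraction(
    fat_percent: float,
    oil_density: float = OIL_DENSITY,
    product_density: float = PRODUCT_DENSITY,
) -> float:
    """Oil volume fraction from a fat mass fraction in % w/w."""
    if not 0 < fat_percent <= 100:
        raise ValueError("fat_percent must be in (0, 100]")
    return fat_percent / 100.0 * product_density / oil_density


def loglog_slope(curve: ScatteringCurve, fit_range: tuple[float, float]) -> float:
    """Least-squares log-log slope of a curve over a q-interval."""
    c = curve.masked().crop(*fit_range)
    return float(np.polyfit(np.log(c.q), np.log(c.intensity), 1)[0])


def porod_plateau(
    curve: ScatteringCurve,
    fit_range: tuple[float, float],
    *,
    slope_warn: float = 0.3,
    slope_fail: float = 1.0,
) -> tuple[float, float]:
    """Estimate the Porod plateau lim I*Q^4 over ``fit_range``.

    The local log-log slope over the range is checked against -4: beyond
    ``slope_fail`` deviation a :class:`PorodRegimeError` is raised, beyond
    ``slope_warn`` a warning is emitted.  The plateau is the inverse-variance
    weighted mean of I*Q^4 (uniform weights when sigma is absent) and its
    standard error.
    """
    if curve.smeared:
        raise ValueError("desmear the curve before Porod analysis")
    c = curve.masked().crop(*fit_range)
    if len(c) < 5:
        raise ValueError("need at least 5 usable points in fit range")
    slope = float(np.polyfit(np.log(c.q), np.log(c.intensity), 1)[0])
    if abs(slope + 4.0) > slope_fail:
        raise PorodRegimeError(
            f"log-log slope {slope:.2f} over {fit_range} is not Porod-like (-4)"
        )
    if abs(slope + 4.0) > slope_warn:
        import warnings

        warnings.warn(
            f"Porod fit range {fit_range}: slope {slope:.2f} deviates from -4"
        )
    y = c.intensity * c.q ** 4
    if c.sigma is not None and np.all(c.sigma > 0):
        w = 1.0 / (c.sigma * c.q ** 4) ** 2
    else:
        w = np.ones_like(y)
    plateau = float(np.sum(w * y) / np.sum(w))
    n = len(y)
    se = float(np.sqrt(np.sum(w * (y - plateau) ** 2) / np.sum(w) / max(n - 1, 1)))
    return plateau, se


def default_fit_range(
    curve: ScatteringCurve,
    *,
    half_decade: float = np.sqrt(10.0),
    slope_tol: float = 0.3,
    curvature_tol: float = 0.2,
) -> tuple[float, float]:
    """Lowest half-decade of the curve where the Porod test passes.

    Slides a half-decade window up from the curve minimum and returns the
    first window whose log-log slope is within -4 +/- ``slope_tol`` and
    whose log-log curvature (quadratic coefficient in ln q) is below
    ``curvature_tol``.  The curvature check rejects the knee between the
    low-Q rolloff and the true asymptotic regime, where the local slope
    sweeps through -4 without the curve being a power law.
    """
    c = curve.masked()
    qlo = c.q[0]
    while qlo * half_decade <= c.q[-1] * (1 + 1e-9):
        rng = (qlo, qlo * half_decade)
        sel = (c.q >= rng[0]) & (c.q <= rng[1])
        if sel.sum() < 5:
            break
        x = np.log(c.q[sel])
        x = x - x.mean()  # centre so the linear term is the mid-window slope
        curv, slope, _ = np.polyfit(x, np.log(c.intensity[sel]), 2)
        if abs(slope + 4.0) <= slope_tol and abs(curv) <= curvature_tol:
            return rng
        qlo *= 10 ** 0.1
    raise PorodRegimeError(
        "no half-decade window with power-law slope within -4 +/- tol"
    )


def specific_surface(
    plateau: float,
    delta_rho: float = DEFAULT_DELTA_RHO,
    dispersed_volume_fraction: float = 1.0,
    *,
    plateau_se: float = 0.0,
    fit_range: tuple[float, float] = (np.nan, np.nan),
    slope: float = np.nan,
) -> PorodResult:
    """Surface area and equivalent sphere radius from a Porod plateau.

    S_v = plateau / (2 pi delta_rho^2) is per unit sample volume; dividing
    by the dispersed volume fraction gives the specific surface area per
    unit of dispersed material, and r = 3/S the surface-weighted equivalent
    sphere radius (reported in micrometres).
    """
    if delta_rho == 0:
        raise ZeroDivisionError("delta_rho must be non-zero")
    if not 0 < dispersed_volume_fraction <= 1:
        raise ValueError("dispersed_volume_fraction must be in (0, 1]")
    if plateau <= 0:
        raise ValueError("plateau must be positive")
    sv = plateau / (2.0 * np.pi * delta_rho ** 2)
    s = sv / dispersed_volume_fraction
    return PorodResult(
        plateau=float(plateau),
        plateau_se=float(plateau_se),
        delta_rho=float(delta_rho),
        dispersed_volume_fraction=float(dispersed_volume_fraction),
        surface_per_sample_volume=float(sv),
        specific_surface_area=float(s),
        equivalent_radius_um=equivalent_radius(s),
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        slope=float(slope),
    )


def equivalent_radius(specific_surface_area: float) -> float:
    """Equivalent sphere radius r = 3/S in micrometres, S in cm^-1."""
    if specific_surface_area <= 0:
        raise ValueError("specific surface area must be positive")
    r_cm = 3.0 / specific_surface_area
    return r_cm / CM_PER_UM


def analyze(
    curve: ScatteringCurve,
    *,
    fit_range: tuple[float, float] | None = None,
    delta_rho: float = DEFAULT_DELTA_RHO,
    fat_percent: float | None = None,
    dispersed_volume_fraction: float | None = None,
) -> PorodResult:
    """Full Porod chain on a desmeared curve.

    The dispersed volume fraction may be given directly or derived from a
    fat mass fraction; default 1 (surface per sample volume only).
    """
    if fit_range is None:
        fit_range = default_fit_range(curve)
    plateau, se = porod_plateau(curve, fit_range)
    slope = loglog_slope(curve, fit_range)
    if dispersed_volume_fraction is None:
        dispersed_volume_fraction = (
            fat_volume_fraction(fat_percent) if fat_percent is not None else 1.0
        )
    return specific_surface(
        plateau,
        delta_rho,
        dispersed_volume_fraction,
        plateau_se=se,
        fit_range=fit_range,
        slope=slope,
    )
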