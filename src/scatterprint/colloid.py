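"""Dynamic light scattering and electrokinetics: cumulants, sizing, zeta.

Cumulant analysis fits the log of the field correlation function, recovered
from the measured intensity correlation via the Siegert relation
g2 = baseline + beta |g1|^2, with a quadratic

    ln|g1(t)| = -a1 t + a2 t^2,

so a1 is the mean decay rate and the polydispersity index is
PDI = 2 a2 / a1^2, which for a Gaussian distribution of decay rates equals
its relative variance sigma^2/mu^2.

Hydrodynamic radii follow from Stokes-Einstein, r = kB T / (6 pi eta D),
and zeta potentials from Henry's equation
zeta = 3 U_E eta / (2 eps f(kappa r_p)) with the Smoluchowski limit f = 1.5
for high ionic strength.  eps is the absolute permittivity (eps0 * eps_r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KB = 1.380649e-23          # J/K
M_PER_ANGSTROM = 1e-10

#: molar mass of NaCl, g/mol
NACL_MOLAR_MASS = 58.44


class FitError(ValueError):
    """Correlation function cannot be cumulant-fitted."""


@dataclass(frozen=True)
class CumulantFit:
    """Quadratic cumulant fit of ln|g1|."""

    a1: float                  # mean decay rate, 1/s
    a2: float                  # curvature (second cumulant / 2), 1/s^2
    pdi: float                 # 2 a2 / a1^2, floored at 0
    pdi_floored: bool
    fit_window: tuple[float, float]
    coherence_factor: float
    baseline: float


@dataclass(frozen=True)
class ZetaInput:
    """Inputs to Henry's equation."""

    mobility: float            # U_E, m^2 V^-1 s^-1
    viscosity: float           # eta, Pa s
    dielectric: float          # absolute permittivity, F/m
    henry_factor: float = 1.5  # f(kappa r_p), 1.0 (Hueckel) .. 1.5 (Smoluchowski)

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if not 1.0 <= self.henry_factor <= 1.5:
            raise ValueError("henry_factor must lie in [1.0, 1.5]")


def cumulant_pdi(
    lag: np.ndarray,
    g2: np.ndarray,
    *,
    baseline: float | None = None,
    coherence_factor: float | None = None,
    g1_floor: float = 0.4,
) -> CumulantFit:
    """Cumulant fit of an intensity correlation function.

    ``baseline`` defaults to the mean of the last 5% of lags; the coherence
    factor beta defaults to the extrapolated zero-lag amplitude
    g2(0) - baseline.  |g1| is recovered by the Siegert relation and the
    quadratic fitted over the lags where |g1| > ``g1_floor``, weighted by
    |g1|^2 (the inverse standard deviation of ln|g1| under additive noise
    in g2).  The cumulant expansion is a short-time expansion, so the
    default floor keeps the fit on the initial decay (mean-rate * lag of
    order one) where truncation at second order is accurate; lowering the
    floor admits long lags where higher cumulants bias a2.
    """
    lag = np.asarray(lag, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if lag.shape != g2.shape or lag.ndim != 1 or len(lag) < 10:
        raise ValueError("need matching 1D arrays with at least 10 lags")
    if baseline is None:
        ntail = max(3, len(g2) // 20)
        baseline = float(np.mean(g2[-ntail:]))
    excess = g2 - baseline
    if coherence_factor is None:
        coherence_factor = float(np.max(excess[: max(3, len(excess) // 20)]))
    if coherence_factor <= 0 or excess[0] <= 0:
        raise FitError("correlation function does not decay from a positive amplitude")
    g1sq = excess / coherence_factor
    usable = g1sq > g1_floor ** 2
    if usable.sum() < 10:
        # shrink the floor until enough early lags are usable
        import warnings

        warnings.warn("fewer than 10 lags above |g1| floor; shrinking window")
        usable = g1sq > 0
        if usable.sum() < 5:
            raise FitError("too few positive |g1| points to fit")
    t = lag[usable]
    ln_g1 = 0.5 * np.log(g1sq[usable])
    c2, c1, _ = np.polyfit(t, ln_g1, 2, w=g1sq[usable])
    a1 = -float(c1)
    a2 = float(c2)
    if a1 <= 0:
        raise FitError("non-decaying correlation function (a1 <= 0)")
    pdi = 2.0 * a2 / a1 ** 2
    floored = pdi < 0
    return CumulantFit(
        a1=a1,
        a2=a2,
        pdi=max(pdi, 0.0),
        pdi_floored=bool(floored),
        fit_window=(float(t[0]), float(t[-1])),
        coherence_factor=coherence_factor,
        baseline=baseline,
    )


def stokes_einstein_radius(D: float, T: float, viscosity: float) -> float:
    """Hydrodynamic radius r = kB T / (6 pi eta D), reported in Angstrom.

    D in m^2/s, T in kelvin, viscosity in Pa s.
    """
    if D <= 0 or T <= 0 or viscosity <= 0:
        raise ValueError("D, T and viscosity must all be positive")
    r_m = KB * T / (6.0 * np.pi * viscosity * D)
    return r_m / M_PER_ANGSTROM


def diffusion_coefficient(radius_angstrom: float, T: float, viscosity: float) -> float:
    """Stokes-Einstein diffusion coefficient (m^2/s) of a sphere."""
    if radius_angstrom <= 0 or T <= 0 or viscosity <= 0:
        raise ValueError("radius, T and viscosity must all be positive")
    return KB * T / (6.0 * np.pi * viscosity * radius_angstrom * M_PER_ANGSTROM)


def henry_zeta(inp: ZetaInput) -> float:
    """Zeta potential from Henry's equation, in millivolt.

    zeta = 3 U_E eta / (2 eps f); with the Smoluchowski factor f = 1.5 this
    reduces to U_E eta / eps.
    """
    zeta_v = 3.0 * inp.mobility * inp.viscosity / (2.0 * inp.dielectric * inp.henry_factor)
    return zeta_v * 1e3


def mass_fraction_to_molarity(
    w_percent: float,
    molar_mass: float = NACL_MOLAR_MASS,
    solution_density: float = 1.0,
) -> float:
    """Convert a solute mass fraction (% w/w) to molarity in mM.

    M = (w/100) * density [g/mL] * 1000 [mL/L] / molar_mass [g/mol].
    """
    if not 0.0 <= w_percent <= 100.0:
        raise ValueError("w_percent must lie in [0, 100]")
    if molar_mass <= 0 or solution_density <= 0:
        raise ValueError("molar_mass and solution_density must be positive")
    mol_per_l = w_percent / 100.0 * solution_density * 1000.0 / molar_mass
    return mol_per_l * 1e3  # mM
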