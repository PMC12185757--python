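"""Composition-intensity correlations: probe read-outs, Spearman, line fits.

The study-level analysis reads the scattered intensity at fixed momentum
transfers (0.0003 1/A for fat via USAXS, 0.10 1/A for carbohydrate via SAXS,
0.15 1/A for the solid-fat lamellar peak) and rank-correlates it with the
composition table.  Spearman's rho uses midranks for ties; the two-sided
p-value is exact (full permutation enumeration) for n <= 9 and the
t-approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats

from .curves import ScatteringCurve

#: default probes: q (1/A) -> composition variable
DEFAULT_PROBES = {
    0.0003: "fat",
    0.10: "carbohydrate",
    0.15: "fat",
}

EXACT_P_MAX_N = 9


class UndefinedCorrelationError(ValueError):
    """Spearman correlation is undefined (a constant input)."""


def intensity_at_q(curve: ScatteringCurve, q_probe: float) -> float:
    """Log-log interpolated intensity at a probe momentum transfer."""
    c = curve.masked()
    if not c.q[0] <= q_probe <= c.q[-1]:
        raise ValueError(
            f"q_probe {q_probe} outside curve range [{c.q[0]:g}, {c.q[-1]:g}]"
        )
    return float(c.interp_log(np.array([q_probe]))[0])


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all n! orderings of the y midranks against the fixed x
    midranks and counts |rho_perm| >= |rho_obs| (with a small numerical
    slack so ties in |rho| are counted).
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    rho_all = (ry_c[perms] @ rx_c) / denom
    count = int(np.sum(np.abs(rho_all) >= abs(rho_obs) - 1e-12))
    return count / factorial(n)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Midranks handle ties.  For n <= 9 the p-value is exact by full
    permutation enumeration under the null of no association; for larger n
    the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant input: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= EXACT_P_MAX_N:
        p = _exact_spearman_p(x, y, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def linear_fit(x, y) -> tuple[float, float, np.ndarray]:
    """Ordinary least-squares line y = slope*x + intercept.

    Returns (slope, intercept, residuals); the residual standard error is
    available as ``residuals.std(ddof=2)``-style from the residual array.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]):
        raise np.linalg.LinAlgError("constant x: singular fit")
    res = stats.linregress(x, y)
    residuals = y - (res.slope * x + res.intercept)
    return float(res.slope), float(res.intercept), residuals


@dataclass
class CorrelationReport:
    """Spearman + OLS summary of intensity at one probe vs one variable."""

    q_probe: float
    x_label: str
    x: np.ndarray
    y: np.ndarray                 # intensity read-outs
    rho: float
    p_value: float
    p_method: str                 # "exact-permutation" | "t-approximation"
    slope: float
    intercept: float
    residual_se: float


def correlate_probe(
    curves: list[ScatteringCurve],
    composition: dict[str, float] | list[float],
    q_probe: float,
    x_label: str = "",
    *,
    baseline_subtract: bool = False,
    baseline_exclude: float = 0.03,
) -> CorrelationReport:
    """Correlate intensity at ``q_probe`` with a composition variable.

    ``composition`` is either a list aligned with ``curves`` or a mapping
    sample_id -> value.  With ``baseline_subtract`` the local power-law
    baseline (fitted in log-log over the surrounding region, excluding
    +/- ``baseline_exclude`` 1/A around the probe) is removed first - used
    for the lamellar-peak probe where the crystalline excess, not the total
    intensity, tracks solid fat.
    """
    if isinstance(composition, dict):
        xs = [composition[c.sample_id] for c in curves]
    else:
        xs = list(composition)
    if len(xs) != len(curves):
        raise ValueError("composition values do not align with curves")
    ys = []
    for c in curves:
        if baseline_subtract:
            ys.append(peak_excess_at_q(c, q_probe, exclude=baseline_exclude))
        else:
            ys.append(intensity_at_q(c, q_probe))
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    rho, p = spearman(x, y)
    slope, intercept, resid = linear_fit(x, y)
    return CorrelationReport(
        q_probe=q_probe,
        x_label=x_label,
        x=x,
        y=y,
        rho=rho,
        p_value=p,
        p_method="exact-permutation" if len(x) <= EXACT_P_MAX_N else "t-approximation",
        slope=slope,
        intercept=intercept,
        residual_se=float(resid.std(ddof=min(2, len(resid) - 1))),
    )


def peak_excess_at_q(
    curve: ScatteringCurve,
    q_probe: float,
    *,
    exclude: float = 0.03,
    span: float = 4.0,
) -> float:
    """Intensity above the local power-law baseline at ``q_probe``.

    The baseline is a power law fitted over [q_probe/span, q_probe*span]
    excluding +/- ``exclude`` (1/A) around the probe.  Negative excess is
    floored at 0 (no crystalline peak present).
    """
    c = curve.masked()
    lo = max(q_probe / span, c.q[0])
    hi = min(q_probe * span, c.q[-1])
    sel = (c.q >= lo) & (c.q <= hi) & (np.abs(c.q - q_probe) > exclude)
    if sel.sum() < 3:
        raise ValueError("not enough points to fit a local baseline")
    p, lnA = np.polyfit(np.log(c.q[sel]), np.log(c.intensity[sel]), 1)
    baseline = np.exp(lnA) * q_probe ** p
    return max(intensity_at_q(curve, q_probe) - baseline, 0.0)
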