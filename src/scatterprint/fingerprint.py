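"""Structural fingerprints: log-Q resampling, log-log gradients, heat maps.

A fingerprint condenses a full merged USAXS+SAXS+WAXS curve into two rows on
a common logarithmic Q grid (100 points by default): the per-sample
min-max-normalised intensity, and the modulus of the local log-log gradient
d ln I / d ln Q between neighbouring grid points.  Rendered on a linear
temperature colour scale from 0 (black) to 4 (white), the gradient layer
makes scattering regimes directly visible:

    |g| ~ 4       sharp-interface (Porod) surface scattering
    |g| in 1..3   mass-fractal structures
    |g| ~ 0       plateau / incoherent background
    rising g >= 1 low-Q flank of a correlation peak

Values above the rendering ceiling are clipped for display only; the stored
matrices are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ScatteringCurve

DEFAULT_N_POINTS = 100
RENDER_CEILING = 4.0


class NoDataError(ValueError):
    """Curve has no usable points for resampling."""


def resample_loglog(
    curve: ScatteringCurve,
    n_points: int = DEFAULT_N_POINTS,
    *,
    q_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate ln I linearly in ln Q onto a log-spaced grid.

    The grid spans the curve's usable endpoints (or ``q_range``).  Masked
    stretches are bridged by the interpolation.  Returns (q_grid, intensity).
    """
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    try:
        c = curve.masked()
    except ValueError as exc:
        raise NoDataError(str(exc)) from None
    lo, hi = q_range if q_range is not None else (c.q[0], c.q[-1])
    if hi / lo < 10.0:
        raise ValueError("curve must span at least one decade in q")
    q_grid = np.geomspace(lo, hi, n_points)
    # guard endpoints against geomspace rounding
    q_grid[0], q_grid[-1] = lo, hi
    i_grid = np.exp(np.interp(np.log(q_grid), np.log(c.q), np.log(c.intensity)))
    return q_grid, i_grid


def loglog_gradient(
    q_grid: np.ndarray, i_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients d ln I / d ln Q between neighbouring grid points.

    Returns (q_mid, g) with the signed gradient at the geometric midpoint of
    each grid pair; the modulus is abs(g).
    """
    q_grid = np.asarray(q_grid, float)
    i_grid = np.asarray(i_grid, float)
    ok = np.isfinite(i_grid) & (i_grid > 0)
    if ok.sum() < 2:
        raise NoDataError("fewer than 2 usable gridded points")
    if not np.all(ok):
        i_grid = np.where(ok, i_grid, np.nan)
    g = np.diff(np.log(i_grid)) / np.diff(np.log(q_grid))
    q_mid = np.sqrt(q_grid[:-1] * q_grid[1:])
    return q_mid, g


def normalize_intensity(i_grid: np.ndarray) -> np.ndarray:
    """Min-max normalisation of ln I per sample onto [0, 1].

    Normalising in the log domain matches the dynamic range a log-log plot
    displays; multiplying the curve by a positive scalar leaves the result
    unchanged.
    """
    i_grid = np.asarray(i_grid, float)
    ok = np.isfinite(i_grid) & (i_grid > 0)
    if ok.sum() < 2:
        raise NoDataError("fewer than 2 usable points to normalise")
    li = np.log(i_grid)
    lo, hi = np.nanmin(li[ok]), np.nanmax(li[ok])
    if hi == lo:
        raise ValueError("constant intensity: zero normalisation range")
    out = (li - lo) / (hi - lo)
    out[~ok] = np.nan
    return out


REGIME_LABELS = (
    "porod_surface",
    "smeared_surface_or_steep",
    "mass_fractal",
    "plateau",
    "rising_peak_flank",
)


def classify_regime(gradient: float) -> str:
    """Scattering-regime label for a signed log-log gradient.

    porod_surface (g <= -3.5), smeared_surface_or_steep (-3.5 < g <= -3),
    mass_fractal (-3 < g <= -1), plateau (-1 < g < 1),
    rising_peak_flank (g >= 1).
    """
    g = float(gradient)
    if not np.isfinite(g):
        raise ValueError("gradient must be finite")
    if g <= -3.5:
        return "porod_surface"
    if g <= -3.0:
        return "smeared_surface_or_steep"
    if g <= -1.0:
        return "mass_fractal"
    if g < 1.0:
        return "plateau"
    return "rising_peak_flank"


@dataclass
class FingerprintMatrix:
    """Samples x log-Q fingerprint layers.

    ``normalized_intensity`` is (n_samples, n_points); ``gradient`` is the
    signed (n_samples, n_points - 1) gradient layer with ``q_mid`` its grid.
    ``gradient_modulus`` is its absolute value; ``render_ceiling`` is the
    display clip level (stored values are unclipped).
    """

    q_grid: np.ndarray
    q_mid: np.ndarray
    samples: list[str]
    normalized_intensity: np.ndarray
    gradient: np.ndarray
    render_ceiling: float = RENDER_CEILING

    @property
    def gradient_modulus(self) -> np.ndarray:
        return np.abs(self.gradient)

    def to_frame(self, layer: str = "gradient_modulus"):
        import pandas as pd

        if layer == "normalized_intensity":
            return pd.DataFrame(
                self.normalized_intensity, index=self.samples, columns=self.q_grid
            )
        if layer in ("gradient", "gradient_modulus"):
            return pd.DataFrame(
                getattr(self, layer), index=self.samples, columns=self.q_mid
            )
        raise ValueError(f"unknown layer {layer!r}")


def build_fingerprint(
    curves: list[ScatteringCurve],
    n_points: int = DEFAULT_N_POINTS,
    *,
    q_range: tuple[float, float] | None = None,
) -> FingerprintMatrix:
    """Stack per-sample fingerprints into a matrix ordered as given.

    All curves must cover the common grid range (the intersection of usable
    ranges when ``q_range`` is None); curves that do not span it raise a
    range error naming the offenders.
    """
    if not curves:
        raise ValueError("no curves given")
    if q_range is None:
        lo = max(c.masked().q[0] for c in curves)
        hi = min(c.masked().q[-1] for c in curves)
        if hi <= lo:
            raise ValueError("curves have no common q-range")
        q_range = (lo, hi)
    bad = [
        c.sample_id
        for c in curves
        if c.masked().q[0] > q_range[0] * (1 + 1e-9)
        or c.masked().q[-1] < q_range[1] * (1 - 1e-9)
    ]
    if bad:
        raise ValueError(f"curves do not span {q_range}: {bad}")
    norm_rows, grad_rows = [], []
    q_grid = q_mid = None
    for c in curves:
        q_grid, i_grid = resample_loglog(c, n_points, q_range=q_range)
        q_mid, g = loglog_gradient(q_grid, i_grid)
        norm_rows.append(normalize_intensity(i_grid))
        grad_rows.append(g)
    return FingerprintMatrix(
        q_grid=q_grid,
        q_mid=q_mid,
        samples=[c.sample_id for c in curves],
        normalized_intensity=np.vstack(norm_rows),
        gradient=np.vstack(grad_rows),
    )


def render_heatmap(
    matrix: FingerprintMatrix,
    layer: str = "gradient_modulus",
    *,
    ax=None,
    cmap: str = "hot",
):
    """Render a fingerprint layer as a temperature-scale heat map.

    The gradient-modulus layer is shown linearly from 0 (black) to the
    render ceiling (white); values above the ceiling are clipped for display
    only.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if layer == "normalized_intensity":
        data, vmax = matrix.normalized_intensity, 1.0
        centers = matrix.q_grid
        edges = np.concatenate(
            [
                [centers[0] ** 2 / np.sqrt(centers[0] * centers[1])],
                np.sqrt(centers[:-1] * centers[1:]),
                [centers[-1] ** 2 / np.sqrt(centers[-2] * centers[-1])],
            ]
        )
    elif layer == "gradient_modulus":
        data, vmax = matrix.gradient_modulus, matrix.render_ceiling
        edges = matrix.q_grid  # midpoint cells are bounded by the grid itself
    else:
        raise ValueError(f"unknown layer {layer!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.35 * len(matrix.samples) + 1.5))
    mesh = ax.pcolormesh(
        edges,
        np.arange(len(matrix.samples) + 1),
        data,
        cmap=cmap,
        vmin=0.0,
        vmax=vmax,
        shading="auto",
    )
    ax.set_xscale("log")
    ax.set_xlabel(r"$Q$ [$\mathrm{\AA}^{-1}$]")
    ax.set_yticks(np.arange(len(matrix.samples)) + 0.5)
    ax.set_yticklabels(matrix.samples, fontsize=7)
    ax.figure.colorbar(mesh, ax=ax, label=layer)
    return ax
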