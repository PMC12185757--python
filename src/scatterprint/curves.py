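"""Reduced 1D scattering curves: containers, file I/O, merging, backgrounds.

The central object is :class:`ScatteringCurve`, an ordered set of
(Q, I, sigma) triples with a technique label (USAXS / SAXS / WAXS / merged),
a slit-smearing flag and an intensity-unit flag.  Q is always in inverse
Angstrom; intensity is in absolute units (cm^-1) where available, otherwise
arbitrary units with ``absolute_units=False``.

Non-positive intensities are never deleted: they are kept in the arrays and
flagged in a boolean ``mask`` (True = usable point), because downstream
stages work in log space and need to treat such points as gaps.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TECHNIQUES = ("USAXS", "SAXS", "WAXS", "merged")

#: slit-smeared USAXS is scaled onto SAXS over this window (inverse Angstrom)
DEFAULT_OVERLAP = (0.0052, 0.0055)


class CurveFormatError(ValueError):
    """A curve file could not be parsed into (q, I[, sigma]) columns."""


class MergeError(ValueError):
    """Curves cannot be merged (no overlap, or unusable intensities there)."""


class CoverageError(ValueError):
    """A background curve does not cover the sample's q-range."""


class SchemaError(ValueError):
    """A composition table is missing required columns."""


@dataclass
class ScatteringCurve:
    """One reduced 1D scattering curve.

    Parameters
    ----------
    q : array
        Momentum transfer, inverse Angstrom, strictly increasing, all > 0.
    intensity : array
        Scattered intensity per q point.
    sigma : array or None
        Per-point uncertainty, same units as intensity.
    technique : str
        One of USAXS, SAXS, WAXS, merged.
    smeared : bool
        True for Bonse-Hart slit-smeared data.
    slit_length : float or None
        Slit half-length L in inverse Angstrom; required when smeared.
    absolute_units : bool
        True when intensity is on an absolute cm^-1 scale.
    sample_id : str
    mask : array of bool
        True where the point is usable (finite, positive intensity).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    technique: str = "SAXS"
    smeared: bool = False
    slit_length: float | None = None
    absolute_units: bool = True
    sample_id: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.size < 2:
            raise ValueError("curve needs at least 2 points")
        if self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must have equal length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma must match q length")
        if np.any(~np.isfinite(self.q)) or np.any(self.q <= 0):
            raise ValueError("q must be finite and positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.smeared:
            if self.slit_length is None or self.slit_length <= 0:
                raise ValueError("smeared curve requires slit_length > 0")
        if self.mask is None:
            self.mask = np.isfinite(self.intensity) & (self.intensity > 0)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.q.shape:
                raise ValueError("mask must match q length")

    def __len__(self) -> int:
        return self.q.size

    @property
    def qmin(self) -> float:
        return float(self.q[0])

    @property
    def qmax(self) -> float:
        return float(self.q[-1])

    def masked(self) -> "ScatteringCurve":
        """Return a copy restricted to usable (masked-in) points."""
        m = self.mask
        if m.sum() < 2:
            raise ValueError("fewer than 2 usable points")
        return replace(
            self,
            q=self.q[m],
            intensity=self.intensity[m],
            sigma=None if self.sigma is None else self.sigma[m],
            mask=np.ones(int(m.sum()), dtype=bool),
        )

    def crop(self, qlo: float, qhi: float) -> "ScatteringCurve":
        sel = (self.q >= qlo) & (self.q <= qhi)
        if sel.sum() < 2:
            raise ValueError(f"fewer than 2 points in [{qlo}, {qhi}]")
        return replace(
            self,
            q=self.q[sel],
            intensity=self.intensity[sel],
            sigma=None if self.sigma is None else self.sigma[sel],
            mask=self.mask[sel],
        )

    def interp_log(self, q_new: np.ndarray) -> np.ndarray:
        """Intensity at ``q_new`` by linear interpolation in (ln q, ln I).

        Only usable points are interpolated through; q_new must lie inside
        the usable range.
        """
        c = self.masked()
        q_new = np.asarray(q_new, dtype=float)
        if np.any(q_new < c.q[0]) or np.any(q_new > c.q[-1]):
            raise ValueError("q_new outside curve range")
        return np.exp(np.interp(np.log(q_new), np.log(c.q), np.log(c.intensity)))


@dataclass(frozen=True)
class SampleRecord:
    """One row of the product-composition table (mass fractions in % w/w)."""

    number: int
    sample_id: str
    category: str  # milk | yoghurt | cream
    material: str  # almond, casein, coconut, fava bean, linseed, oat, pea, rice, soy
    fat: float
    carbohydrate: float
    protein: float

    def __post_init__(self) -> None:
        for name in ("fat", "carbohydrate", "protein"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100] % w/w")
        if self.fat + self.carbohydrate + self.protein > 100.0 + 1e-9:
            raise ValueError("mass fractions sum to more than 100 % w/w")


# ---------------------------------------------------------------------------
# file I/O

def read_curve(
    path: str | Path,
    *,
    technique: str = "SAXS",
    smeared: bool = False,
    slit_length: float | None = None,
    absolute_units: bool = True,
    sample_id: str | None = None,
    columns: Sequence[int] | None = None,
) -> ScatteringCurve:
    """Read a plain-text curve file into a :class:`ScatteringCurve`.

    Accepts whitespace- or comma-separated columns with ``#`` comment lines.
    By default two columns are read as (q, I), three or more as (q, I, sigma);
    extra columns are ignored with a warning.  ``columns`` overrides the
    auto-detection with explicit 0-based column indices.

    Rows with non-finite q are dropped; the result is sorted by q.
    Non-positive intensities are retained but masked out.
    """
    path = Path(path)
    if not path.exists():
        raise CurveFormatError(f"no such file: {path}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise CurveFormatError(
                    f"{path}: non-numeric data on line {lineno}: {line.strip()!r}"
                ) from None
            if len(vals) < 2:
                raise CurveFormatError(
                    f"{path}: fewer than 2 numeric columns on line {lineno}"
                )
            rows.append(vals)
    if len(rows) < 2:
        raise CurveFormatError(f"{path}: fewer than 2 valid data rows")
    ncol = min(len(r) for r in rows)
    if columns is None:
        if ncol > 3:
            warnings.warn(
                f"{path}: {ncol} columns; using the first three as (q, I, sigma)"
            )
        columns = (0, 1, 2)[: min(ncol, 3)]
    data = np.array([[r[i] for i in columns] for r in rows], dtype=float)
    keep = np.isfinite(data[:, 0])
    data = data[keep]
    if data.shape[0] < 2:
        raise CurveFormatError(f"{path}: fewer than 2 rows with finite q")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(
        q=data[:, 0],
        intensity=data[:, 1],
        sigma=sigma,
        technique=technique,
        smeared=smeared,
        slit_length=slit_length,
        absolute_units=absolute_units,
        sample_id=sample_id if sample_id is not None else path.stem,
    )


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as '#'-commented whitespace-separated columns."""
    path = Path(path)
    cols = [curve.q, curve.intensity]
    header = "q[1/A] I" + ("[1/cm]" if curve.absolute_units else "[a.u.]")
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += " sigma"
    meta = (
        f"# sample_id: {curve.sample_id}\n# technique: {curve.technique}\n"
        f"# smeared: {curve.smeared}"
    )
    if curve.smeared:
        meta += f"\n# slit_length: {curve.slit_length}"
    np.savetxt(
        path,
        np.column_stack(cols),
        header=header + "\n" + meta.replace("# ", "", 1),
        fmt="%.9e",
    )


def read_composition_table(path: str | Path) -> list[SampleRecord]:
    """Read a product-composition CSV into :class:`SampleRecord` rows.

    Required header columns: number, sample, fat, carbohydrate, protein,
    category, material.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"number", "sample", "fat", "carbohydrate", "protein",
                "category", "material"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"composition table missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("composition table %s has no rows", path)
        return []
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                number=int(row["number"]),
                sample_id=str(row["sample"]).strip(),
                category=str(row["category"]).strip(),
                material=str(row["material"]).strip(),
                fat=float(row["fat"]),
                carbohydrate=float(row["carbohydrate"]),
                protein=float(row["protein"]),
            )
        )
    return records


def write_composition_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "number": [r.number for r in records],
            "sample": [r.sample_id for r in records],
            "fat": [r.fat for r in records],
            "carbohydrate": [r.carbohydrate for r in records],
            "protein": [r.protein for r in records],
            "category": [r.category for r in records],
            "material": [r.material for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry

def q_from_angle(theta: float | np.ndarray, wavelength: float) -> float | np.ndarray:
    """Momentum transfer Q = (4 pi / lambda) sin(theta / 2).

    ``theta`` is the full scattering angle in degrees, ``wavelength`` in
    Angstrom; the result is in inverse Angstrom.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th > 180):
        raise ValueError("theta must lie in [0, 180] degrees")
    out = (4.0 * np.pi / wavelength) * np.sin(np.radians(th) / 2.0)
    return float(out) if np.isscalar(theta) else out


# ---------------------------------------------------------------------------
# merging and background subtraction

def merge_curves(
    low_q: ScatteringCurve,
    high_q: ScatteringCurve,
    overlap: tuple[float, float] = DEFAULT_OVERLAP,
) -> tuple[ScatteringCurve, float]:
    """Scale ``low_q`` onto ``high_q`` over ``overlap`` and splice.

    The scale factor minimises the least-squares log-intensity mismatch over
    the overlap window (so every decade of intensity carries equal weight):
    ln s = mean(ln I_high(q) - ln I_low(q)) at the low-curve points inside
    the window.  The merged curve keeps the high-q curve's points inside the
    overlap and covers the union of both ranges.

    Returns (merged curve, scale factor).
    """
    if low_q.absolute_units != high_q.absolute_units:
        raise MergeError("cannot merge curves with different intensity-unit flags")
    if low_q.smeared or high_q.smeared:
        raise MergeError("desmear before merging (smeared flag set)")
    qlo, qhi = overlap
    if qhi <= qlo:
        raise MergeError("empty overlap interval")
    in_low = (low_q.q >= qlo) & (low_q.q <= qhi) & low_q.mask
    in_high = (high_q.q >= qlo) & (high_q.q <= qhi) & high_q.mask
    if in_low.sum() < 2 or in_high.sum() < 2:
        raise MergeError(
            f"need >= 2 usable points from each curve in overlap [{qlo}, {qhi}]"
        )
    q_ov = low_q.q[in_low]
    i_low = low_q.intensity[in_low]
    if np.any(i_low <= 0):
        raise MergeError("non-positive low-q intensities in overlap")
    i_high = high_q.masked().interp_log(q_ov)
    scale = float(np.exp(np.mean(np.log(i_high) - np.log(i_low))))

    keep_low = low_q.q < qlo
    q = np.concatenate([low_q.q[keep_low], high_q.q])
    i = np.concatenate([low_q.intensity[keep_low] * scale, high_q.intensity])
    sig_parts = []
    for part, sel, fac in ((low_q, keep_low, scale), (high_q, slice(None), 1.0)):
        if part.sigma is None:
            sig_parts.append(np.zeros(np.count_nonzero(sel) if isinstance(sel, np.ndarray) else len(part)))
        else:
            sig_parts.append(part.sigma[sel] * fac)
    sigma = np.concatenate(sig_parts)
    mask = np.concatenate([low_q.mask[keep_low], high_q.mask])
    source_is_low = np.concatenate(
        [np.ones(int(keep_low.sum()), bool), np.zeros(len(high_q), bool)]
    )
    order = np.argsort(q, kind="stable")
    q, i, sigma, mask = q[order], i[order], sigma[order], mask[order]
    source_is_low = source_is_low[order]
    # where both curves sampled the same q, keep the high-q curve's point
    dup = np.zeros(len(q), dtype=bool)
    close = np.isclose(q[1:], q[:-1], rtol=1e-12, atol=0.0)
    dup[:-1] |= close & source_is_low[:-1]
    dup[1:] |= close & source_is_low[1:] & ~dup[:-1]
    keep = ~dup
    merged = ScatteringCurve(
        q=q[keep],
        intensity=i[keep],
        sigma=sigma[keep] if (low_q.sigma is not None or high_q.sigma is not None) else None,
        technique="merged",
        smeared=False,
        absolute_units=high_q.absolute_units,
        sample_id=high_q.sample_id or low_q.sample_id,
        mask=mask[keep],
    )
    return merged, scale


def subtract_background(
    sample: ScatteringCurve,
    background: ScatteringCurve,
    factor: float = 1.0,
) -> ScatteringCurve:
    """Subtract ``factor``x an instrument/solvent background from a sample.

    The background is interpolated onto the sample grid linearly in ln q
    (intensity linear, so zero-crossing backgrounds are allowed).  Resulting
    non-positive intensities are masked, not deleted.  Uncertainties combine
    in quadrature when both curves carry sigma.
    """
    bg = background
    if bg.q[0] > sample.q[0] * (1 + 1e-12) or bg.q[-1] < sample.q[-1] * (1 - 1e-12):
        raise CoverageError(
            "background q-range does not cover sample "
            f"([{bg.q[0]:g}, {bg.q[-1]:g}] vs [{sample.q[0]:g}, {sample.q[-1]:g}])"
        )
    lq = np.log(sample.q)
    bgi = np.interp(lq, np.log(bg.q), bg.intensity)
    intensity = sample.intensity - factor * bgi
    sigma = None
    if sample.sigma is not None or bg.sigma is not None:
        s2 = np.zeros_like(intensity)
        if sample.sigma is not None:
            s2 += sample.sigma ** 2
        if bg.sigma is not None:
            s2 += (factor * np.interp(lq, np.log(bg.q), bg.sigma)) ** 2
        sigma = np.sqrt(s2)
    mask = sample.mask & np.isfinite(intensity) & (intensity > 0)
    return replace(sample, intensity=intensity, sigma=sigma, mask=mask)
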