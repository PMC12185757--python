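"""Bragg/lamellar peak detection and triglyceride polymorph assignment.

Triglycerides pack in three chain-packing polymorphs with characteristic
wide-angle Bragg peaks: alpha (hexagonal), beta-prime (orthorhombic, two
reported variant sets) and beta (triclinic).  A first-order lamellar peak
near Q = 0.15 1/A (d ~ 42 A) marks bilayer (2L) stacking of solid fat.
Peaks are reported with d = 2 pi / Q and matched against the catalogue
within a q tolerance; a polymorph counts as "supported" only when every
position of one of its variant sets is matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .curves import ScatteringCurve

#: catalogue positions in inverse Angstrom
DEFAULT_CATALOGUE_ENTRIES: dict[str, list[tuple[float, ...]]] = {
    "alpha_hexagonal": [(1.53,)],
    "beta_prime_orthorhombic": [(1.50, 1.65), (1.47, 1.58, 1.69)],
    "beta_triclinic": [(1.37, 1.65, 1.70)],
    "lamellar_2L": [(0.15,)],
}

DEFAULT_TOLERANCE = 0.03       # 1/A, WAXS assignment
LAMELLAR_TOLERANCE = 0.02      # 1/A, around 0.15

#: the amorphous water halo near 2 1/A is broad; baselines must span it
DEFAULT_BASELINE_WIDTH = 0.5   # 1/A


class RangeError(ValueError):
    """Requested region lies outside the curve."""


def q_to_dspacing(q: float | np.ndarray) -> float | np.ndarray:
    """Real-space repeat distance d = 2 pi / Q (Angstrom from 1/A)."""
    qa = np.asarray(q, dtype=float)
    if np.any(qa <= 0):
        raise ValueError("q must be positive")
    out = 2.0 * np.pi / qa
    return float(out) if np.isscalar(q) else out


@dataclass(frozen=True)
class PolymorphCatalogue:
    """Polymorph label -> variant sets of expected peak positions (1/A)."""

    entries: dict[str, list[tuple[float, ...]]] = field(
        default_factory=lambda: {
            k: [tuple(v) for v in vs] for k, vs in DEFAULT_CATALOGUE_ENTRIES.items()
        }
    )

    def __post_init__(self) -> None:
        for label, variants in self.entries.items():
            for variant in variants:
                if any(p <= 0 for p in variant):
                    raise ValueError(f"non-positive catalogue position in {label}")

    def positions(self) -> list[tuple[str, float]]:
        out = []
        for label, variants in self.entries.items():
            seen = set()
            for variant in variants:
                for p in variant:
                    if p not in seen:
                        out.append((label, p))
                        seen.add(p)
        return out


@dataclass
class PeakAssignment:
    """A detected peak with optional polymorph candidates.

    ``candidates`` maps polymorph label -> distance (1/A) to the nearest
    catalogue position within tolerance; empty means unassigned.
    """

    q_position: float
    d_spacing: float
    height_above_baseline: float
    width: float                       # FWHM estimate, 1/A
    candidates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.d_spacing * self.q_position - 2.0 * np.pi) > 1e-9 * 2 * np.pi:
            raise ValueError("d_spacing must equal 2 pi / q_position")


def _baseline(log_i: np.ndarray, window: int) -> np.ndarray:
    """Rolling minimum then smoothing of ln I over ``window`` points."""
    window = max(3, int(window))
    rolled = minimum_filter1d(log_i, size=window, mode="nearest")
    return uniform_filter1d(rolled, size=window, mode="nearest")


def find_peaks(
    curve: ScatteringCurve,
    region: tuple[float, float],
    *,
    min_prominence: float = 0.2,
    baseline_window: int | None = None,
) -> list[PeakAssignment]:
    """Detect peaks above a rolling-minimum baseline within a q-region.

    The baseline is a rolling minimum of ln I, smoothed over the same
    window, so broad features (the amorphous water halo) are absorbed into
    the baseline when the window spans them.  Local maxima whose intensity
    exceeds (1 + min_prominence) times the local baseline are reported with
    3-point parabolic position refinement in (q, ln I) and an FWHM estimate
    from the half-height crossings of I - baseline.  Candidates whose FWHM
    exceeds half the baseline window are discarded: a feature that broad
    cannot be separated from the baseline estimate itself (this is what
    keeps residual curvature of the amorphous halo out of the peak list).
    """
    c = curve.masked()
    qlo, qhi = region
    if qlo >= c.q[-1] or qhi <= c.q[0]:
        raise RangeError(f"region {region} outside curve range")
    sel = (c.q >= qlo) & (c.q <= qhi)
    if sel.sum() < 10:
        raise RangeError("need at least 10 points in region")
    q = c.q[sel]
    i = c.intensity[sel]
    log_i = np.log(i)
    if baseline_window is None:
        dq = np.median(np.diff(q))
        baseline_window = int(round(DEFAULT_BASELINE_WIDTH / dq))
    base = np.exp(_baseline(log_i, baseline_window))
    excess = i - base
    ratio = i / base

    peaks: list[PeakAssignment] = []
    for k in range(1, len(q) - 1):
        if not (ratio[k] - 1.0 > min_prominence):
            continue
        if not (excess[k] >= excess[k - 1] and excess[k] > excess[k + 1]):
            continue
        # 3-point parabola through (q, ln I) around the grid maximum
        y0, y1, y2 = log_i[k - 1], log_i[k], log_i[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
        else:
            shift = 0.0
        q_peak = q[k] + shift * (q[min(k + 1, len(q) - 1)] - q[k - 1]) / 2.0
        height = float(excess[k])
        half = height / 2.0
        # walk out to the half-height crossings of the excess
        left = k
        while left > 0 and excess[left] > half:
            left -= 1
        right = k
        while right < len(q) - 1 and excess[right] > half:
            right += 1

        def _cross(a: int, b: int) -> float:
            if excess[b] == excess[a]:
                return q[a]
            t = (half - excess[a]) / (excess[b] - excess[a])
            return float(q[a] + t * (q[b] - q[a]))

        q_left = _cross(left, left + 1) if left < k else q[k]
        q_right = _cross(right, right - 1) if right > k else q[k]
        width = max(float(q_right - q_left), float(np.min(np.diff(q))))
        window_q = baseline_window * float(np.median(np.diff(q)))
        if width > 0.5 * window_q:
            continue
        peaks.append(
            PeakAssignment(
                q_position=float(q_peak),
                d_spacing=float(2.0 * np.pi / q_peak),
                height_above_baseline=height,
                width=width,
            )
        )
    return peaks


def assign_polymorph(
    peaks: list[float] | list[PeakAssignment],
    catalogue: PolymorphCatalogue | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[list[PeakAssignment], list[str]]:
    """Match peak positions against the polymorph catalogue.

    Every peak is matched to all catalogue positions within ``tolerance``;
    since several positions are shared between polymorph variant sets (e.g.
    1.65 1/A appears for both beta and beta-prime), all supported polymorphs
    are reported rather than a forced unique label.

    Returns (assignments, supported_polymorphs) where a polymorph is
    supported when all positions of at least one of its variant sets are
    matched by some peak.
    """
    if catalogue is None:
        catalogue = PolymorphCatalogue()
    if tolerance <= 0:
        if tolerance < 0:
            raise ValueError("tolerance must be non-negative")
    positions = [
        p.q_position if isinstance(p, PeakAssignment) else float(p) for p in peaks
    ]
    assignments: list[PeakAssignment] = []
    for j, p in enumerate(peaks):
        if isinstance(p, PeakAssignment):
            pa = p
        else:
            qp = positions[j]
            pa = PeakAssignment(
                q_position=qp,
                d_spacing=2.0 * np.pi / qp,
                height_above_baseline=np.nan,
                width=np.nan,
            )
        cand: dict[str, float] = {}
        for label, pos in catalogue.positions():
            dist = abs(pa.q_position - pos)
            if dist <= tolerance:
                if label not in cand or dist < cand[label]:
                    cand[label] = dist
        pa.candidates = cand
        assignments.append(pa)

    supported = []
    for label, variants in catalogue.entries.items():
        for variant in variants:
            if all(
                any(abs(qp - pos) <= tolerance for qp in positions) for pos in variant
            ):
                supported.append(label)
                break
    return assignments, supported
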