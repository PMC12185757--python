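"""Synthetic emulsion scattering and DLS data with known ground truth.

Forward models for everything the analysis chain consumes:

* full-range (USAXS-SAXS-WAXS) scattering curves built from additive
  components - polydisperse sharp-interface spheres (oil droplets), power
  laws with an optional low-Q cutoff (mass-fractal biopolymer networks of
  finite cluster size), Gaussian correlation peaks (lamellar stacking of
  solid fat at 0.15 1/A, triglyceride polymorph Bragg peaks at wide angle),
  the broad amorphous water halo near 2 1/A and a flat background;
* sample sets with planted monotone composition -> amplitude links
  (fat -> droplet volume fraction and lamellar peak, carbohydrate ->
  mid-Q power law), so rank correlations have a known truth;
* DLS intensity correlation functions from planted lognormal size
  distributions via Stokes-Einstein decay rates and the Siegert relation.

All generators are deterministic given their seed, and every generated
artefact carries the planted truth needed for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colloid import diffusion_coefficient
from .curves import SampleRecord, ScatteringCurve
from .porod import DEFAULT_DELTA_RHO, fat_volume_fraction
from .smearing import SmearingGeometry, slit_smear

ANGSTROM_PER_UM = 1e4
CM_PER_ANGSTROM = 1e-8   # intensity per Angstrom -> per cm

#: plotted technique ranges, inverse Angstrom
USAXS_RANGE = (0.0003, 0.005)
SAXS_RANGE = (0.005, 1.0)
WAXS_RANGE = (1.0, 3.0)
FULL_RANGE = (0.0003, 3.0)

#: Table-style composition bounds, % w/w
FAT_RANGE = (1.0, 36.0)
CARB_RANGE = (0.0, 13.0)
PROTEIN_RANGE = (0.1, 5.0)

MATERIALS = (
    "almond", "casein", "coconut", "fava bean", "linseed",
    "oat", "pea", "rice", "soy",
)

#: wide-angle polymorph peak positions used for synthetic cream curves
BETA_TRICLINIC_PEAKS = (1.37, 1.65, 1.70)
LAMELLAR_Q = 0.15
WATER_HALO_Q = 2.0


class ModelValidationError(ValueError):
    """An emulsion model violates its field constraints."""


# ---------------------------------------------------------------------------
# components

@dataclass(frozen=True)
class PorodSphere:
    """Lognormal-polydisperse sphere population (oil droplets).

    ``mean_radius_um`` is the arithmetic mean radius, ``polydispersity`` the
    relative standard deviation of the lognormal size distribution,
    ``volume_fraction`` the dispersed-phase volume fraction and
    ``delta_rho`` the X-ray contrast in 1/A^2.
    """

    mean_radius_um: float = 0.5
    polydispersity: float = 0.2
    volume_fraction: float = 0.01
    delta_rho: float = DEFAULT_DELTA_RHO

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of ln r with r in Angstrom."""
        mean_a = self.mean_radius_um * ANGSTROM_PER_UM
        sigma = np.sqrt(np.log(1.0 + self.polydispersity ** 2))
        mu = np.log(mean_a) - 0.5 * sigma ** 2
        return float(mu), float(sigma)

    def moment(self, k: int) -> float:
        """<r^k> of the lognormal size distribution, Angstrom^k."""
        mu, sigma = self.lognormal_params()
        return float(np.exp(k * mu + 0.5 * k ** 2 * sigma ** 2))

    @property
    def surface_per_dispersed_volume_cm(self) -> float:
        """Planted specific surface 3<r^2>/<r^3>, cm^-1."""
        return 3.0 * self.moment(2) / self.moment(3) / CM_PER_ANGSTROM

    @property
    def surface_weighted_radius_um(self) -> float:
        """Planted equivalent radius <r^3>/<r^2>, micrometres."""
        return self.moment(3) / self.moment(2) / ANGSTROM_PER_UM


@dataclass(frozen=True)
class PowerLaw:
    """I = amplitude * Q^-exponent, flattening below ``q_cutoff``.

    The cutoff emulates the finite cluster size of fractal biopolymer
    networks: below it the term plateaus at amplitude * q_cutoff^-exponent
    instead of diverging into the USAXS range.
    """

    amplitude: float
    exponent: float
    q_cutoff: float | None = None


@dataclass(frozen=True)
class GaussianPeak:
    """Gaussian correlation peak at ``position`` (1/A) with std ``width``."""

    position: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class EmulsionModel:
    """Additive forward model of one emulsion scattering curve."""

    spheres: list[PorodSphere] = field(default_factory=list)
    power_laws: list[PowerLaw] = field(default_factory=list)
    peaks: list[GaussianPeak] = field(default_factory=list)
    water_halo: GaussianPeak | None = None
    flat_background: float = 0.0
    q_range: tuple[float, float] = FULL_RANGE
    n_points: int = 400
    noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for pl in self.power_laws:
            if not 0.0 <= pl.exponent <= 5.0:
                problems.append(f"power-law exponent {pl.exponent} outside [0, 5]")
            if pl.amplitude < 0:
                problems.append(f"negative power-law amplitude {pl.amplitude}")
        for pk in list(self.peaks) + ([self.water_halo] if self.water_halo else []):
            if pk.amplitude < 0:
                problems.append(f"negative peak amplitude at {pk.position}")
            if not self.q_range[0] <= pk.position <= self.q_range[1]:
                problems.append(f"peak position {pk.position} outside q_range")
            if pk.width <= 0:
                problems.append(f"non-positive peak width at {pk.position}")
        for sp in self.spheres:
            if sp.mean_radius_um <= 0 or sp.volume_fraction <= 0:
                problems.append("sphere radius and volume fraction must be positive")
            if not 0 <= sp.polydispersity < 1:
                problems.append("sphere polydispersity must lie in [0, 1)")
        if self.flat_background < 0:
            problems.append("negative flat background")
        if self.noise < 0:
            problems.append("negative noise level")
        if problems:
            raise ModelValidationError("; ".join(problems))


# ---------------------------------------------------------------------------
# forward evaluation

def _sphere_form_amplitude(x: np.ndarray) -> np.ndarray:
    """F(x) = 3 (sin x - x cos x) / x^3, orientationally averaged sphere."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    return out


def sphere_intensity(q: np.ndarray, sphere: PorodSphere, n_nodes: int = 301) -> np.ndarray:
    """Absolute intensity (cm^-1) of a polydisperse sphere population.

    I(Q) = phi / <V> * delta_rho^2 * <V(r)^2 F(Qr)^2> with the average over
    the lognormal size distribution evaluated by trapezoidal quadrature in
    ln r over +/- 5 sigma (a delta function at zero polydispersity).
    """
    q = np.asarray(q, dtype=float)
    mu, sigma = sphere.lognormal_params()
    if sigma < 1e-12:
        r = np.array([np.exp(mu)])
        w = np.array([1.0])
    else:
        lr = np.linspace(mu - 5 * sigma, mu + 5 * sigma, n_nodes)
        r = np.exp(lr)
        # lognormal pdf in ln r is a plain Gaussian
        w = np.exp(-0.5 * ((lr - mu) / sigma) ** 2)
        w /= w.sum()
    v = 4.0 / 3.0 * np.pi * r ** 3
    mean_v = float((w * v).sum())
    f2 = _sphere_form_amplitude(q[:, None] * r[None, :]) ** 2
    avg_v2p = (w[None, :] * (v ** 2)[None, :] * f2).sum(axis=1)
    i_per_a = sphere.volume_fraction / mean_v * sphere.delta_rho ** 2 * avg_v2p
    return i_per_a / CM_PER_ANGSTROM


def model_intensity(q: np.ndarray, model: EmulsionModel) -> np.ndarray:
    """Noise-free total intensity (cm^-1) of an emulsion model."""
    q = np.asarray(q, dtype=float)
    i = np.full_like(q, float(model.flat_background))
    for sp in model.spheres:
        i = i + sphere_intensity(q, sp)
    for pl in model.power_laws:
        q_eff = np.maximum(q, pl.q_cutoff) if pl.q_cutoff else q
        i = i + pl.amplitude * q_eff ** (-pl.exponent)
    for pk in list(model.peaks) + ([model.water_halo] if model.water_halo else []):
        i = i + pk.amplitude * np.exp(-0.5 * ((q - pk.position) / pk.width) ** 2)
    return i


def generate_emulsion_curve(
    model: EmulsionModel,
    *,
    smear: SmearingGeometry | None = None,
    technique: str = "merged",
    sample_id: str = "synthetic",
) -> ScatteringCurve:
    """Evaluate an emulsion model on a log-spaced grid, optionally smeared.

    Multiplicative lognormal counting noise at the model's relative level is
    applied after any smearing, with sigma set to noise * I.  Deterministic
    for a given model seed.
    """
    model.validate()
    q = np.geomspace(model.q_range[0], model.q_range[1], model.n_points)
    i = model_intensity(q, model)
    curve = ScatteringCurve(
        q=q,
        intensity=i,
        technique=technique,
        smeared=False,
        absolute_units=True,
        sample_id=sample_id,
    )
    if smear is not None:
        curve = slit_smear(curve, smear)
    if model.noise > 0:
        rng = np.random.default_rng(model.seed)
        factor = np.exp(model.noise * rng.standard_normal(len(curve)))
        curve = ScatteringCurve(
            q=curve.q,
            intensity=curve.intensity * factor,
            sigma=model.noise * curve.intensity,
            technique=curve.technique,
            smeared=curve.smeared,
            slit_length=curve.slit_length,
            absolute_units=True,
            sample_id=sample_id,
        )
    return curve


# ---------------------------------------------------------------------------
# sample sets with planted composition links

#: documented amplitude constants of the default link (not physical claims):
#: carbohydrate power law gives ~10 cm^-1 per % w/w at Q = 0.1 1/A, the
#: lamellar peak ~2 cm^-1 per % w/w solid-fat proxy above 3 % fat.
CARB_AMPLITUDE_PER_PERCENT = 0.1
CARB_EXPONENT = 2.0
CARB_CUTOFF = 0.005
LAMELLAR_AMP_PER_PERCENT = 2.0
SOLID_FAT_THRESHOLD = 3.0
#: sample-set droplets are micron-scale, so the Porod regime sits below the
#: carbohydrate-network scattering for low-carbohydrate products
LINK_DROPLET_RADIUS_UM = 1.0
WAXS_PEAK_AMPLITUDE = 0.5
HALO_AMPLITUDE = 1.0
#: the amorphous water halo is broad (FWHM about 1 1/A around 2 1/A)
HALO_WIDTH = 0.45
FLAT_BACKGROUND = 0.02


def default_link(record: SampleRecord) -> EmulsionModel:
    """Composition -> forward-model map emulating the study's correlations.

    Fat sets the droplet volume fraction (hence low-Q USAXS intensity,
    strictly monotone in fat) and, above the cream/solid-fat threshold, the
    lamellar-peak amplitude.  Carbohydrate sets a fractal power law that
    dominates the mid-Q SAXS region.  Cream-category samples additionally
    carry beta-triclinic wide-angle peaks.
    """
    peaks = []
    if record.fat > SOLID_FAT_THRESHOLD and record.category in ("cream", "yoghurt"):
        peaks.append(
            GaussianPeak(LAMELLAR_Q, 0.012,
                         LAMELLAR_AMP_PER_PERCENT * (record.fat - SOLID_FAT_THRESHOLD))
        )
    if record.category == "cream":
        for pos in BETA_TRICLINIC_PEAKS:
            peaks.append(GaussianPeak(pos, 0.02, WAXS_PEAK_AMPLITUDE))
    power_laws = []
    if record.carbohydrate > 0:
        power_laws.append(
            PowerLaw(
                amplitude=CARB_AMPLITUDE_PER_PERCENT * record.carbohydrate,
                exponent=CARB_EXPONENT,
                q_cutoff=CARB_CUTOFF,
            )
        )
    return EmulsionModel(
        spheres=[PorodSphere(mean_radius_um=LINK_DROPLET_RADIUS_UM,
                             volume_fraction=fat_volume_fraction(record.fat))],
        power_laws=power_laws,
        peaks=peaks,
        water_halo=GaussianPeak(WATER_HALO_Q, HALO_WIDTH, HALO_AMPLITUDE),
        flat_background=FLAT_BACKGROUND,
    )


def generate_composition_table(n_samples: int = 29, seed: int = 0) -> list[SampleRecord]:
    """Synthetic composition table emulating the study's 29 products.

    Fat values are placed on a jittered grid over 1-36 % w/w (so they are
    distinct and well separated, as in the real table), assigned so that
    milk products get the low-fat end and cream the high-fat end.
    Carbohydrate is bimodal, as in commercial products: about one sample in
    five is a nut/legume-style product with almost no carbohydrate
    (uniform 0-0.5 % w/w), the rest carry 0.5-13 % w/w; protein is uniform
    within its range.  Categories split roughly as
    milk : yoghurt : cream = 12 : 8 : 9.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    grid = np.linspace(FAT_RANGE[0], FAT_RANGE[1], n_samples)
    step = grid[1] - grid[0]
    fat = np.sort(np.clip(grid + rng.uniform(-0.3, 0.3, n_samples) * step,
                          FAT_RANGE[0], FAT_RANGE[1]))
    low_carb = rng.random(n_samples) < 0.2
    carb = np.where(
        low_carb,
        rng.uniform(0.0, 0.5, n_samples),
        rng.uniform(0.5, CARB_RANGE[1], n_samples),
    )
    protein = rng.uniform(*PROTEIN_RANGE, n_samples)
    n_milk = max(1, round(n_samples * 12 / 29))
    n_yog = max(1, round(n_samples * 8 / 29))
    records = []
    for k in range(n_samples):
        category = "milk" if k < n_milk else ("yoghurt" if k < n_milk + n_yog else "cream")
        material = MATERIALS[k % len(MATERIALS)]
        records.append(
            SampleRecord(
                number=k + 1,
                sample_id=f"{material} {category} - {k + 1}",
                category=category,
                material=material,
                fat=round(float(fat[k]), 2),
                carbohydrate=round(float(carb[k]), 2),
                protein=round(float(protein[k]), 2),
            )
        )
    return records


def generate_sample_set(
    n_samples: int = 29,
    link=default_link,
    noise: float = 0.0,
    seed: int = 0,
    *,
    n_points: int = 2000,
) -> tuple[list[ScatteringCurve], list[SampleRecord], dict]:
    """Generate a full synthetic study: curves + composition table + truth.

    Each sample's curve is built by :func:`generate_emulsion_curve` from the
    model the ``link`` assigns to its composition record.  Returns
    (curves, records, truth) where ``truth`` records the planted link and
    per-sample models for recovery assertions.
    """
    records = generate_composition_table(n_samples, seed)
    curves = []
    models = {}
    for k, rec in enumerate(records):
        base = link(rec)
        model = EmulsionModel(
            spheres=base.spheres,
            power_laws=base.power_laws,
            peaks=base.peaks,
            water_halo=base.water_halo,
            flat_background=base.flat_background,
            q_range=base.q_range,
            n_points=n_points,
            noise=noise,
            seed=seed * 100003 + k,
        )
        models[rec.sample_id] = model
        curves.append(
            generate_emulsion_curve(model, sample_id=rec.sample_id)
        )
    truth = {"link": link, "models": models, "noise": noise, "seed": seed}
    return curves, records, truth


# ---------------------------------------------------------------------------
# DLS correlation functions

#: study-style optics and bath defaults
DLS_WAVELENGTH_NM = 633.0
DLS_ANGLE_DEG = 173.0
DLS_TEMPERATURE_K = 298.15
DLS_VISCOSITY = 0.89e-3       # Pa s, water at 25 C
DLS_N_MEDIUM = 1.33


def scattering_vector(
    wavelength_nm: float = DLS_WAVELENGTH_NM,
    angle_deg: float = DLS_ANGLE_DEG,
    n_medium: float = DLS_N_MEDIUM,
) -> float:
    """Light-scattering vector q = 4 pi n sin(theta/2) / lambda, in 1/m."""
    if wavelength_nm <= 0 or n_medium <= 0 or not 0 < angle_deg <= 180:
        raise ValueError("invalid optics parameters")
    return 4.0 * np.pi * n_medium * np.sin(np.radians(angle_deg) / 2.0) / (
        wavelength_nm * 1e-9
    )


def dls_rate_distribution(
    median_radius_a: float,
    spread: float,
    *,
    T: float = DLS_TEMPERATURE_K,
    viscosity: float = DLS_VISCOSITY,
    wavelength_nm: float = DLS_WAVELENGTH_NM,
    angle_deg: float = DLS_ANGLE_DEG,
    n_medium: float = DLS_N_MEDIUM,
    n_nodes: int = 201,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted decay rates of a lognormal size distribution.

    Sizes are lognormal with the given median (Angstrom) and ``spread`` the
    standard deviation of ln r.  Scattering weights are Rayleigh-like
    (proportional to r^6 times the number density), decay rates
    Gamma = D(r) q^2 with Stokes-Einstein D.  Returns (rates [1/s],
    normalised weights).
    """
    if median_radius_a <= 0 or spread < 0:
        raise ValueError("distribution parameters must be positive")
    qv = scattering_vector(wavelength_nm, angle_deg, n_medium)
    mu = np.log(median_radius_a)
    if spread < 1e-12:
        r = np.array([median_radius_a])
        w = np.array([1.0])
    else:
        lr = np.linspace(mu - 5 * spread, mu + 5 * spread, n_nodes)
        r = np.exp(lr)
        w = np.exp(-0.5 * ((lr - mu) / spread) ** 2) * r ** 6
        w /= w.sum()
    rates = np.array([diffusion_coefficient(ri, T, viscosity) for ri in r]) * qv ** 2
    return rates, w


def generate_dls_correlation(
    median_radius_a: float = 1500.0,
    spread: float = 0.0,
    *,
    T: float = DLS_TEMPERATURE_K,
    viscosity: float = DLS_VISCOSITY,
    wavelength_nm: float = DLS_WAVELENGTH_NM,
    angle_deg: float = DLS_ANGLE_DEG,
    n_medium: float = DLS_N_MEDIUM,
    coherence_factor: float = 1.0,
    baseline: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
    n_lags: int = 200,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Intensity correlation function g2(tau) of a lognormal dispersion.

    g1 is the intensity-weighted sum of exponentials over the planted decay
    rates; g2 follows from the Siegert relation
    g2 = baseline + beta |g1|^2, with additive Gaussian noise of the given
    absolute level.  Lag times span 1e-3 .. 20 mean decay times,
    log-spaced.  Returns (lag, g2, truth) with the planted decay-rate
    moments in ``truth``.
    """
    rates, w = dls_rate_distribution(
        median_radius_a, spread, T=T, viscosity=viscosity,
        wavelength_nm=wavelength_nm, angle_deg=angle_deg, n_medium=n_medium,
    )
    mean_rate = float((w * rates).sum())
    var_rate = float((w * (rates - mean_rate) ** 2).sum())
    lag = np.geomspace(1e-3 / mean_rate, 20.0 / mean_rate, n_lags)
    g1 = (w[None, :] * np.exp(-np.outer(lag, rates))).sum(axis=1)
    g2 = baseline + coherence_factor * g1 ** 2
    if noise > 0:
        rng = np.random.default_rng(seed)
        g2 = g2 + noise * rng.standard_normal(n_lags)
    truth = {
        "mean_rate": mean_rate,
        "rate_relative_variance": var_rate / mean_rate ** 2,
        "scattering_vector": scattering_vector(wavelength_nm, angle_deg, n_medium),
        "coherence_factor": coherence_factor,
        "baseline": baseline,
    }
    return lag, g2, truth
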