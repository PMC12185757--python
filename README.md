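# scatterprint

Multi-scale scattering analysis for dairy and plant-based emulsions
(milk, yoghurt and cream products), combining ultra-small-, small- and
wide-angle X-ray scattering (USAXS/SAXS/WAXS) with dynamic light
scattering and electrokinetics.

Commercial food emulsions are too heterogeneous for single-model fits, but
a lot of structure can be read off reduced 1D curves directly: droplet
interfaces, biopolymer networks, solid-fat lamellae and triglyceride
crystal packing all leave characteristic marks between Q = 0.0003 and
3 Å⁻¹ (length scales from ~2 µm down to ~2 Å).  This package implements
that model-light workflow end to end:

* **Curve handling** — plain-text (Q, I, σ) readers/writers, Kapton-style
  background subtraction, and scaling/merging of slit-smeared USAXS onto
  SAXS over a configurable overlap window (default 0.0052–0.0055 Å⁻¹).
* **Slit smearing and desmearing** — forward Bonse–Hart infinite-slit
  smearing with a uniform slit of half-length L (default 0.015 Å⁻¹), which
  turns a Porod Q⁻⁴ tail into Q⁻³, and its inversion by Lake iteration
  (multiplicative by default, with residual-based early stopping and an
  optional regularised variant).
* **Porod analysis** — from a desmeared curve, the plateau K = lim I·Q⁴
  gives the interfacial area per unit sample volume
  S_v = K / (2π(Δρ)²), the specific surface area S = S_v/φ of the
  dispersed oil (volume fraction φ from the fat content), and the
  equivalent droplet radius r = 3/S.  Default contrast: oil SLD
  8.7 × 10⁻⁶ Å⁻² against water 9.47 × 10⁻⁶ Å⁻².
* **Peak analysis** — baseline-aware peak detection (the broad amorphous
  water halo near 2 Å⁻¹ is treated as baseline), d = 2π/Q spacings, and
  triglyceride polymorph assignment against the α (hexagonal),
  β′ (orthorhombic) and β (triclinic) catalogues, plus the 2L lamellar
  repeat (~42 Å) at 0.15 Å⁻¹.
* **Structural fingerprints** — per-sample rows of normalised intensity
  and |d ln I/d ln Q| on a 100-point log-Q grid, rendered as temperature
  heat maps (0 = black to 4 = white), so surface scattering (|g| ≈ 4),
  mass fractals (1–3) and correlation peaks stand out across dozens of
  samples at once.
* **Correlations** — intensity read-outs at fixed probes (0.0003 Å⁻¹ for
  fat, 0.10 Å⁻¹ for carbohydrate, 0.15 Å⁻¹ for solid fat) rank-correlated
  with a composition table; Spearman ρ with exact permutation p-values for
  n ≤ 9.
* **Colloid properties** — DLS cumulant analysis
  (ln|g₁| = −a₁t + a₂t², PDI = 2a₂/a₁²), Stokes–Einstein sizing, Henry's
  equation ζ = 3U_Eη / (2εf(κr_p)) with the Smoluchowski limit f = 1.5,
  and % w/w → molarity conversion.
* **Synthetic data** — seeded generators for full-range emulsion curves
  (polydisperse sphere form factors, fractal power laws, lamellar/crystal
  peaks, water halo), 29-sample study sets with planted
  composition→intensity links, and DLS correlation functions from planted
  size distributions, so every stage is testable without any download.

## Worked example

```python
import numpy as np
from scatterprint import (PorodSphere, EmulsionModel, SmearingGeometry,
                          generate_emulsion_curve, slit_smear, desmear,
                          porod_plateau, specific_surface)

# a 0.5 um (20% lognormal) oil-in-water emulsion, 1.5% oil by volume
sphere = PorodSphere(mean_radius_um=0.5, polydispersity=0.2, volume_fraction=0.015)
model = EmulsionModel(spheres=[sphere], q_range=(0.0003, 0.005), n_points=200)
ideal = generate_emulsion_curve(model)

geom = SmearingGeometry(slit_length=0.015)          # Bonse-Hart slit, 1/A
measured = slit_smear(ideal, geom)                  # what the camera records
recovered, info = desmear(measured, geom)           # Lake inversion

plateau, se = porod_plateau(recovered, fit_range=(0.002, 0.005))
result = specific_surface(plateau, sphere.delta_rho, sphere.volume_fraction)
print(f"desmeared in {info['iterations']} iterations")
print(f"specific surface area S = {result.specific_surface_area:.0f} 1/cm")
print(f"equivalent droplet radius r = 3/S = {result.equivalent_radius_um:.2f} um")
print(f"planted surface-weighted radius  = {sphere.surface_weighted_radius_um:.2f} um")
```

prints

```
desmeared in 29 iterations
specific surface area S = 55702 1/cm
equivalent droplet radius r = 3/S = 0.54 um
planted surface-weighted radius  = 0.54 um
```

i.e. the full smear → desmear → Porod chain recovers the planted
surface-weighted droplet radius to about 1 %.  For reference, a product
with S = 3600 cm⁻¹ has r = 3/S ≈ 8.3 µm, and one with 5900 cm⁻¹ has
≈ 5.1 µm.

## The synthetic study

`analysis/` holds numbered drivers that run the whole workflow on a
29-product synthetic study (deterministic seed), writing tables under
`results/` and figures/curves under `scratch/`:

```bash
python analysis/01_simulate_products.py   # composition table + curves
python analysis/02_desmear_usaxs.py       # smearing demo, round-trip checks
python analysis/03_porod_surface_areas.py # which samples show Porod windows
python analysis/04_polymorph_peaks.py     # lamellar peak + polymorphs
python analysis/05_fingerprints.py        # fingerprint matrices + heat maps
python analysis/06_correlations.py        # composition-intensity Spearman
python analysis/07_dls_zeta.py            # DLS cumulants, zeta, molarity
```

A thin CLI mirrors the library for shell use, e.g.
`scatterprint merge --low usaxs.dat --high saxs.dat -o merged.dat`,
`scatterprint desmear in.dat --slit 0.015 -o out.dat`,
`scatterprint peaks in.dat --region 1.0:3.0`, `scatterprint zeta --mobility -2e-8`.

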