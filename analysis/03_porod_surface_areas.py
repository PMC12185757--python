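"""Porod surface areas and equivalent droplet radii across the product set.

For every synthetic product: crop to the USAXS range, slit-smear and
desmear (the full measurement chain), look for a half-decade window with
Porod (-4) behaviour and, where one exists, convert the I*Q^4 plateau into
a specific surface area and an equivalent droplet radius using the oil
volume fraction implied by the fat content.  Samples whose low-Q scattering
is dominated by carbohydrate structures show no Porod window - exactly the
behaviour reported for carbohydrate-rich products - and are listed as such.
"""

from pathlib import Path

import pandas as pd

from scatterprint.curves import ScatteringCurve
from scatterprint.fingerprint import resample_loglog
from scatterprint.porod import PorodRegimeError, analyze
from scatterprint.smearing import SmearingGeometry, desmear, slit_smear
from scatterprint.synth import USAXS_RANGE, generate_sample_set

SEED = 20250929
RESULTS = Path(__file__).resolve().parents[1] / "results"
GEOM = SmearingGeometry(0.015)
N_USAXS = 150  # slit-camera-like point density over the USAXS range


def usaxs_segment(curve) -> ScatteringCurve:
    q, i = resample_loglog(curve.crop(*USAXS_RANGE), N_USAXS)
    return ScatteringCurve(q=q, intensity=i, technique="USAXS",
                           sample_id=curve.sample_id)


def main() -> None:
    curves, records, truth = generate_sample_set(29, noise=0.0, seed=SEED)
    rows = []
    for curve, record in zip(curves, records):
        usaxs = usaxs_segment(curve)
        desmeared, _ = desmear(slit_smear(usaxs, GEOM), GEOM,
                               smooth_iterates=True, max_iter=100)
        planted = truth["models"][record.sample_id].spheres[0]
        row = {
            "number": record.number,
            "sample": record.sample_id,
            "fat": record.fat,
            "carbohydrate": record.carbohydrate,
            "planted_radius_um": planted.surface_weighted_radius_um,
        }
        try:
            res = analyze(desmeared, fat_percent=record.fat)
            row.update(
                specific_surface_cm=res.specific_surface_area,
                radius_um=res.equivalent_radius_um,
                fit_lo=res.fit_range[0],
                fit_hi=res.fit_range[1],
                porod=True,
            )
        except PorodRegimeError:
            row.update(specific_surface_cm=float("nan"),
                       radius_um=float("nan"), porod=False)
        rows.append(row)
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "porod.csv", index=False, float_format="%.5g")

    shown = df[df.porod]
    print(df.to_string(index=False))
    print(
        f"\n{len(shown)} of {len(df)} samples show a Porod window; their "
        "recovered radii vs the planted surface-weighted radii:"
    )
    if len(shown):
        rel = (shown.radius_um / shown.planted_radius_um - 1.0).abs()
        print(f"median |relative error| = {rel.median():.2%}")
        print(
            "carbohydrate-rich samples hide the droplet interface "
            f"(no-Porod median carb = {df[~df.porod].carbohydrate.median():.1f}"
            f" vs {shown.carbohydrate.median():.1f} % w/w for Porod samples)"
        )


if __name__ == "__main__":
    main()
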