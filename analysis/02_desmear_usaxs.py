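"""Demonstrate slit smearing and Lake desmearing on the USAXS segment.

Takes the lowest-fat and highest-fat synthetic products, crops their curves
to the USAXS range (0.0003-0.005 1/A), applies Bonse-Hart slit smearing
(half-length 0.015 1/A) and inverts it again.  Reports the log-log slopes
before/after (the characteristic -4 -> -3 power change under smearing) and
the round-trip error of the inversion.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scatterprint.curves import ScatteringCurve
from scatterprint.fingerprint import resample_loglog
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


def loglog_slope(curve, qlo, qhi):
    sel = (curve.q >= qlo) & (curve.q <= qhi)
    return float(np.polyfit(np.log(curve.q[sel]),
                            np.log(curve.intensity[sel]), 1)[0])


def main() -> None:
    curves, records, _ = generate_sample_set(29, noise=0.0, seed=SEED)
    by_fat = sorted(zip(curves, records), key=lambda cr: cr[1].fat)
    rows = []
    for curve, record in (by_fat[0], by_fat[-1]):
        usaxs = usaxs_segment(curve)
        smeared = slit_smear(usaxs, GEOM)
        recovered, info = desmear(smeared, GEOM, smooth_iterates=True,
                                  max_iter=100)
        err = np.log(recovered.intensity) - np.log(usaxs.intensity)
        n = len(err)
        rows.append(
            {
                "sample": record.sample_id,
                "fat": record.fat,
                "slope_ideal": loglog_slope(usaxs, 0.001, 0.005),
                "slope_smeared": loglog_slope(smeared, 0.001, 0.005),
                "roundtrip_rms_log": float(
                    np.sqrt(np.mean(err[n // 10: -n // 10] ** 2))
                ),
                "iterations": info["iterations"],
                "residual": info["residual"],
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "desmearing.csv", index=False, float_format="%.5g")
    print(df.to_string(index=False))
    print(
        "\nslit smearing raises the high-Q slope by one power of Q "
        "(about -4 to -3); the Lake inversion reproduces the ideal curve to "
        f"{df['roundtrip_rms_log'].max():.2%} RMS in log intensity"
    )


if __name__ == "__main__":
    main()
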