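"""Generate the synthetic product set the downstream analyses run on.

Builds 29 synthetic milk/yoghurt/cream products with compositions spanning
fat 1-36, carbohydrate 0-13 and protein 0.1-5 % w/w, and a full-range
(0.0003-3 1/A) scattering curve for each: polydisperse oil droplets whose
volume fraction tracks fat, a carbohydrate-linked mass-fractal power law,
a lamellar peak for solid-fat samples, beta-triclinic WAXS peaks for
creams, and the amorphous water halo.  Writes the composition table and a
per-sample summary of intensity read-outs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scatterprint.correlations import intensity_at_q
from scatterprint.curves import write_composition_table, write_curve
from scatterprint.synth import generate_sample_set

SEED = 20250929
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
NOISE = 0.02  # 2 % relative counting noise, matching the SAXS resolution scale


def main() -> None:
    curves, records, _ = generate_sample_set(29, noise=NOISE, seed=SEED)
    RESULTS.mkdir(exist_ok=True)
    write_composition_table(records, RESULTS / "composition.csv")

    curve_dir = SCRATCH / "curves"
    curve_dir.mkdir(parents=True, exist_ok=True)
    for curve, record in zip(curves, records):
        write_curve(curve, curve_dir / f"sample_{record.number:02d}.dat")

    summary = pd.DataFrame(
        {
            "number": [r.number for r in records],
            "sample": [r.sample_id for r in records],
            "category": [r.category for r in records],
            "fat": [r.fat for r in records],
            "carbohydrate": [r.carbohydrate for r in records],
            "I_at_0.0003": [intensity_at_q(c, 0.0003) for c in curves],
            "I_at_0.10": [intensity_at_q(c, 0.10) for c in curves],
            "I_at_0.15": [intensity_at_q(c, 0.15) for c in curves],
        }
    )
    summary.to_csv(RESULTS / "sample_summary.csv", index=False,
                   float_format="%.6g")
    print(f"wrote {len(records)} samples to {curve_dir}")
    print(summary.head(8).to_string(index=False))
    lo = summary["I_at_0.0003"]
    print(f"\nlow-Q intensity spans {lo.min():.3g} to {lo.max():.3g} 1/cm, "
          "rising with fat content as planted")


if __name__ == "__main__":
    main()
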