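#!/usr/bin/env python
"""Build the neuropsychological domain composites.

Averages the normed scores into memory (3 z-scores), attention/speed
(6 z-scores) and executive (digit backwards + WCST average + TMT-B, t scale)
composites. Writes results/composites.csv.
"""

import pathlib

import pandas as pd

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    from tauvbm.composites import compute_composites

    neuro = pd.read_csv(ROOT / "results" / "cohort" / "neuropsych.csv")
    comps = compute_composites(neuro)
    out = ROOT / "results" / "composites.csv"
    comps.to_csv(out, index=False)
    print(
        f"{len(comps)} athletes: memory {comps.memory.mean():.2f} ± {comps.memory.std():.2f} z, "
        f"speed {comps.speed.mean():.2f} ± {comps.speed.std():.2f} z, "
        f"executive {comps.executive.mean():.1f} ± {comps.executive.std():.1f} t -> {out}"
    )


if __name__ == "__main__":
    main()
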