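#!/usr/bin/env python
"""Simulate the study cohort.

Generates 54 healthy controls (grey-matter maps with linear age and TIV
effects) and 52 screened retired athletes (GM + tau SUVR maps with a
frontotemporal-weighted tau excess coupled to atrophy), plus biofluid panels
straddling the screening thresholds and a neuropsych battery whose memory
composite is negatively coupled to tau burden. Writes NIfTI volumes and the
subject/biofluid/neuropsych tables under results/cohort/.
"""

import pathlib
import sys

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    from tauvbm.pipeline import export_cohort, simulate_cohort
    from tauvbm.simulate import SimulationConfig

    cfg = SimulationConfig(seed=SEED)
    cohort = simulate_cohort(cfg)
    export_cohort(cohort, OUT)
    n_pos = int(cohort.biofluids["true_positive"].sum())
    print(
        f"simulated {len(cohort.control_records)} controls and "
        f"{len(cohort.athlete_records)} athletes (seed {SEED}) -> {OUT}"
    )
    print(
        f"ground truth: {n_pos} biofluid-positive athletes, "
        f"{len(cohort.truth['pet_flagged'])} PET-pattern flag(s), "
        f"coupling_beta={cfg.coupling_beta}, memory_slope={cfg.memory_slope}"
    )


if __name__ == "__main__":
    main()
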