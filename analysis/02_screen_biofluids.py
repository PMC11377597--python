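#!/usr/bin/env python
"""Screen the athletes for Alzheimer-type pathology and apply the cohort gate.

Reads the biofluid panels and subject table written by 01_simulate_cohort.py,
classifies each athlete (plasma p-tau181 with age-dependent in-house / V2
thresholds, CSF p-tau + Aβ42/t-tau index) and excludes anyone positive on any
modality or flagged for an AD-like tau-PET pattern. Writes
results/gate_report.csv.
"""

import pathlib

import pandas as pd

ROOT = pathlib.Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"


def main() -> None:
    from tauvbm.biofluids import apply_gate

    subjects = pd.read_csv(COHORT / "subjects.csv")
    athletes = subjects[subjects["group"] == "athlete"]
    panels = pd.read_csv(COHORT / "biofluids.csv")
    res = apply_gate(
        panels,
        ages=dict(zip(athletes["subject_id"], athletes["age"])),
        pet_ad_flags=dict(zip(athletes["subject_id"], athletes["pet_ad_flag"].astype(bool))),
    )
    rows = [{"subject_id": s, "decision": "included", "reason": ""} for s in res.included]
    rows += [
        {"subject_id": s, "decision": "excluded", "reason": res.reasons[s]}
        for s in res.excluded
    ]
    out = ROOT / "results" / "gate_report.csv"
    pd.DataFrame(rows).sort_values("subject_id").to_csv(out, index=False)
    print(
        f"screened {res.n_screened} athletes: {len(res.excluded)} excluded "
        f"({sum('plasma' in r for r in res.reasons.values())} plasma, "
        f"{sum('CSF' in r for r in res.reasons.values())} CSF, "
        f"{sum('tau-PET' in r for r in res.reasons.values())} PET pattern), "
        f"{len(res.included)} included -> {out}"
    )


if __name__ == "__main__":
    main()
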