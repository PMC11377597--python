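#!/usr/bin/env python
"""Normative w-score maps and tau-mask means.

Fits the voxelwise age+TIV regression on the healthy controls, converts every
included athlete's grey-matter map into a w-score map (deviation from the
age/TIV-expected volume in control-residual-SD units), and extracts the mean
w inside each athlete's tau-positive and tau-negative masks. Writes
results/wscore_summary.csv.
"""

import pathlib
import warnings

import pandas as pd

ROOT = pathlib.Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
MASKS = ROOT / "results" / "tau_masks"


def main() -> None:
    from tauvbm.volume_io import load_subject_table, load_volume
    from tauvbm.wscore import extract_mask_means, fit_normative, wscore_map

    records = load_subject_table(COHORT / "subjects.csv")
    controls = [r for r in records if r.group == "control"]
    athletes = {r.subject_id: r for r in records if r.group == "athlete"}
    gm_mask = load_volume(COHORT / "gm_mask.nii.gz").data > 0.5
    vols = [load_volume(COHORT / f"{r.subject_id}_gm.nii.gz") for r in controls]
    model = fit_normative(vols, controls, gm_mask)
    print(f"normative model fit on {model.n_controls} controls "
          f"(ages {model.age_range[0]:.0f}-{model.age_range[1]:.0f})")

    gate = pd.read_csv(ROOT / "results" / "gate_report.csv")
    included = gate.loc[gate["decision"] == "included", "subject_id"].tolist()
    rows = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*outside control range.*")
        for sid in included:
            r = athletes[sid]
            w = wscore_map(model, load_volume(COHORT / f"{sid}_gm.nii.gz"), r.age, r.tiv)
            pos = load_volume(MASKS / f"{sid}_tau_pos.nii.gz").data > 0.5
            neg = load_volume(MASKS / f"{sid}_tau_neg.nii.gz").data > 0.5
            s = extract_mask_means(w, pos, neg, subject_id=sid)
            rows.append(
                {
                    "subject_id": sid,
                    "mean_w_pos": s.mean_w_pos,
                    "mean_w_neg": s.mean_w_neg,
                    "n_vox_pos": s.n_vox_pos,
                    "n_vox_neg": s.n_vox_neg,
                }
            )
    out = ROOT / "results" / "wscore_summary.csv"
    df = pd.DataFrame(rows)
    df.to_csv(out, index=False)
    print(
        f"{len(df)} athletes: mean w in tau+ voxels {df.mean_w_pos.mean():.3f} "
        f"± {df.mean_w_pos.std():.3f}, in tau- voxels {df.mean_w_neg.mean():.3f} "
        f"± {df.mean_w_neg.std():.3f} -> {out}"
    )


if __name__ == "__main__":
    main()
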