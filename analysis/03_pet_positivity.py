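#!/usr/bin/env python
"""Tau-PET positivity for every included athlete.

For each athlete that survived the biofluid gate: smooth the SUVR image with
the scanner-matched anisotropic Gaussian kernel, threshold at SUVR >= 1.30
within the grey-matter mask, and record global and per-region % positivity
plus positive-voxel counts. Writes results/positivity.csv,
results/region_extent.csv and per-subject tau+/- masks.
"""

import json
import pathlib

import numpy as np
import pandas as pd

ROOT = pathlib.Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
MASKS = ROOT / "results" / "tau_masks"


def main() -> None:
    from tauvbm.pet import SCANNER_KERNELS, percent_positivity, smooth, threshold_positivity
    from tauvbm.volume_io import ImageVolume, LabelAtlas, load_volume, save_volume

    gate = pd.read_csv(ROOT / "results" / "gate_report.csv")
    included = gate.loc[gate["decision"] == "included", "subject_id"].tolist()
    subjects = pd.read_csv(COHORT / "subjects.csv").set_index("subject_id")
    gm = load_volume(COHORT / "gm_mask.nii.gz").data > 0.5
    labels = load_volume(COHORT / "atlas.nii.gz").data.astype(np.int32)
    names = {int(k): v for k, v in json.load(open(COHORT / "atlas_names.json")).items()}
    atlas = LabelAtlas(labels, names)

    MASKS.mkdir(parents=True, exist_ok=True)
    pos_rows, extent_rows = [], []
    for sid in included:
        suvr = load_volume(COHORT / f"{sid}_suvr.nii.gz")
        kern = SCANNER_KERNELS[subjects.loc[sid, "scanner"]]
        sm = smooth(suvr, kern, mask=gm)
        res = threshold_positivity(sm, gm)
        pct, _ = percent_positivity(res, atlas)
        pos_rows.append(
            {
                "subject_id": sid,
                "pct_positive": pct,
                "suvr_gm_mean": float(np.nanmean(sm.data[gm])),
            }
        )
        extent_rows.append(
            {
                "subject_id": sid,
                **{
                    names[lab]: int((res.positive_mask & (labels == lab)).sum())
                    for lab in atlas.regions()
                },
            }
        )
        for tag, mask in (("pos", res.positive_mask), ("neg", res.negative_mask)):
            save_volume(
                ImageVolume(mask.astype(float), suvr.voxel_size_mm),
                MASKS / f"{sid}_tau_{tag}.nii.gz",
            )
    pos = pd.DataFrame(pos_rows)
    pos.to_csv(ROOT / "results" / "positivity.csv", index=False)
    pd.DataFrame(extent_rows).to_csv(ROOT / "results" / "region_extent.csv", index=False)
    print(
        f"{len(included)} athletes: global % positivity "
        f"mean {pos.pct_positive.mean():.1f}%, SD {pos.pct_positive.std():.1f}%, "
        f"range {pos.pct_positive.min():.1f}-{pos.pct_positive.max():.1f}%"
    )


if __name__ == "__main__":
    main()
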