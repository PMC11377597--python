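"""End-to-end orchestration: simulate → gate → PET → composites → w-scores → stats.

``run_pipeline`` executes the full chain on a synthetic cohort and returns an
analysis report (paired w-score contrast, Table-2-shaped partial-correlation
block, quartile/region table) plus a reproducibility manifest (config
snapshot, seeds, per-stage effective n, output checksums). Everything is
deterministic given the seed; rerunning a manifest's config+seed reproduces
the report bit-identically.

Stage functions are exposed individually so the CLI subcommands and the
numbered analysis drivers can run the chain piecewise on files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .biofluids import GateResult, apply_gate
from .composites import compute_composites
from .pet import SCANNER_KERNELS, percent_positivity, smooth, threshold_positivity
from .quartiles import QuartileAssignment, assign_quartiles, mean_suvr_by_quartile, region_extent_regression
from .simulate import (
    SimulationConfig,
    generate_athletes,
    generate_biofluids,
    generate_controls,
    generate_neuropsych,
    gm_mask,
    make_atlas,
)
from .stats import bonferroni, paired_t, partial_pearson
from .volume_io import ImageVolume, LabelAtlas, SubjectRecord, subjects_to_frame
from .wscore import extract_mask_means, fit_normative, wscore_map

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "gate": {"fraction_positive": 4 / 52, "n_pet_flagged": 1},
    "pet": {"threshold": 1.30, "comparator": "ge", "smooth_mode": "renormalized"},
    "wscore": {"sd_floor": 1e-6, "guard_band": 0.10},
    "quartiles": {
        "enabled": True,
        "n_boot": 2000,
        "acquisition_covariates": True,
        "min_subjects": 8,
    },
    "stats": {"n_boot_paired": 2000, "n_boot_partial": 1000, "bonferroni_m": 6},
    "simulation": {},  # overrides for SimulationConfig fields
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


@dataclass
class Cohort:
    """Everything the generator knows about one synthetic study."""

    cfg: SimulationConfig
    control_records: list[SubjectRecord]
    control_gm: list[ImageVolume]
    athlete_records: list[SubjectRecord]
    athlete_gm: dict[str, ImageVolume]
    athlete_suvr: dict[str, ImageVolume]
    biofluids: pd.DataFrame
    pet_ad_flags: dict[str, bool]
    truth: dict
    gm_mask: np.ndarray
    atlas: LabelAtlas


def simulate_cohort(cfg: SimulationConfig, gate_cfg: dict | None = None) -> Cohort:
    """Generate the full synthetic study (volumes, biofluids, PET flags)."""
    gate_cfg = {**DEFAULT_CONFIG["gate"], **(gate_cfg or {})}
    ctl_recs, ctl_gm = generate_controls(cfg)
    ath_recs, ath_gm, ath_suvr, truth = generate_athletes(cfg)
    biofluids = generate_biofluids(ath_recs, gate_cfg["fraction_positive"], cfg)
    fluid_pos = set(biofluids.loc[biofluids["true_positive"], "subject_id"])
    # PET-pattern AD flags: the highest-severity athletes not already
    # biofluid-positive (mirrors an AD-like retention pattern call)
    severity = truth["severity"]
    candidates = [r.subject_id for r in ath_recs if r.subject_id not in fluid_pos]
    candidates.sort(key=lambda s: (-severity[s], s))
    flagged = set(candidates[: int(gate_cfg["n_pet_flagged"])])
    flags = {r.subject_id: (r.subject_id in flagged) for r in ath_recs}
    truth = {**truth, "biofluid_positive": sorted(fluid_pos), "pet_flagged": sorted(flagged)}
    return Cohort(
        cfg=cfg,
        control_records=ctl_recs,
        control_gm=ctl_gm,
        athlete_records=ath_recs,
        athlete_gm={r.subject_id: v for r, v in zip(ath_recs, ath_gm)},
        athlete_suvr={r.subject_id: v for r, v in zip(ath_recs, ath_suvr)},
        biofluids=biofluids,
        pet_ad_flags=flags,
        truth=truth,
        gm_mask=gm_mask(cfg),
        atlas=make_atlas(cfg),
    )


def export_cohort(cohort: Cohort, outdir, pet_cfg: dict | None = None) -> None:
    """Write the simulated study to disk (volumes, tables, ground truth).

    The neuropsych table needs each athlete's measured % positivity, so the
    PET measurement chain is run on all athletes here before generation.
    """
    import os

    from .volume_io import save_volume

    os.makedirs(outdir, exist_ok=True)
    cfg = cohort.cfg
    for rec, vol in zip(cohort.control_records, cohort.control_gm):
        save_volume(vol, os.path.join(outdir, f"{rec.subject_id}_gm.nii.gz"))
    for sid, vol in cohort.athlete_gm.items():
        save_volume(vol, os.path.join(outdir, f"{sid}_gm.nii.gz"))
    for sid, vol in cohort.athlete_suvr.items():
        save_volume(vol, os.path.join(outdir, f"{sid}_suvr.nii.gz"))
    save_volume(
        ImageVolume(cohort.gm_mask.astype(float), cfg.voxel_size_mm),
        os.path.join(outdir, "gm_mask.nii.gz"),
    )
    save_volume(
        ImageVolume(cohort.atlas.labels.astype(float), cfg.voxel_size_mm),
        os.path.join(outdir, "atlas.nii.gz"),
    )
    with open(os.path.join(outdir, "atlas_names.json"), "w") as fh:
        json.dump({str(k): v for k, v in cohort.atlas.name_table.items()}, fh, indent=2)
    df = subjects_to_frame(cohort.control_records + cohort.athlete_records)
    df["pet_ad_flag"] = [cohort.pet_ad_flags.get(s, False) for s in df["subject_id"]]
    df.to_csv(os.path.join(outdir, "subjects.csv"), index=False)
    cohort.biofluids.to_csv(os.path.join(outdir, "biofluids.csv"), index=False)
    pet_stage = pet_positivity_stage(cohort, sorted(cohort.athlete_gm), pet_cfg)
    generate_neuropsych(cohort.athlete_records, pet_stage.pct_global, cfg).to_csv(
        os.path.join(outdir, "neuropsych.csv"), index=False
    )
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)


def gate_cohort(cohort: Cohort) -> GateResult:
    ages = {r.subject_id: r.age for r in cohort.athlete_records}
    return apply_gate(cohort.biofluids, ages=ages, pet_ad_flags=cohort.pet_ad_flags)


@dataclass
class PetStage:
    smoothed_suvr: dict[str, ImageVolume]
    positivity: dict[str, object]
    pct_global: pd.Series
    suvr_gm_mean: pd.Series
    region_extent: pd.DataFrame  # subjects x region names, positive-voxel counts
    region_pct: pd.DataFrame


def pet_positivity_stage(
    cohort: Cohort, included: list[str], pet_cfg: dict | None = None
) -> PetStage:
    """Scanner-matched smoothing, thresholding and % positivity per athlete."""
    pet_cfg = {**DEFAULT_CONFIG["pet"], **(pet_cfg or {})}
    recs = {r.subject_id: r for r in cohort.athlete_records}
    smoothed, posres = {}, {}
    pct, suvr_mean = {}, {}
    extent_rows, pct_rows = {}, {}
    names = cohort.atlas.name_table
    for sid in included:
        kern = SCANNER_KERNELS[recs[sid].scanner]
        sm = smooth(
            cohort.athlete_suvr[sid], kern, mask=cohort.gm_mask, mode=pet_cfg["smooth_mode"]
        )
        res = threshold_positivity(
            sm, cohort.gm_mask, threshold=pet_cfg["threshold"], comparator=pet_cfg["comparator"]
        )
        g, by_region = percent_positivity(res, cohort.atlas)
        smoothed[sid] = sm
        posres[sid] = res
        pct[sid] = g
        suvr_mean[sid] = float(np.nanmean(sm.data[cohort.gm_mask]))
        labels = cohort.atlas.labels
        extent_rows[sid] = {
            names[lab]: int((res.positive_mask & (labels == lab)).sum())
            for lab in cohort.atlas.regions()
        }
        pct_rows[sid] = {names[lab]: by_region[lab] for lab in cohort.atlas.regions()}
    return PetStage(
        smoothed_suvr=smoothed,
        positivity=posres,
        pct_global=pd.Series(pct, name="pct_positive"),
        suvr_gm_mean=pd.Series(suvr_mean, name="suvr_gm_mean"),
        region_extent=pd.DataFrame.from_dict(extent_rows, orient="index").sort_index(),
        region_pct=pd.DataFrame.from_dict(pct_rows, orient="index").sort_index(),
    )


def wscore_stage(
    cohort: Cohort,
    included: list[str],
    pet_stage: PetStage,
    wcfg: dict | None = None,
) -> tuple[pd.DataFrame, object]:
    """Fit the normative model on controls, score athletes, extract mask means."""
    wcfg = {**DEFAULT_CONFIG["wscore"], **(wcfg or {})}
    model = fit_normative(
        cohort.control_gm, cohort.control_records, cohort.gm_mask, sd_floor=wcfg["sd_floor"]
    )
    recs = {r.subject_id: r for r in cohort.athlete_records}
    rows = []
    for sid in included:
        r = recs[sid]
        w = wscore_map(model, cohort.athlete_gm[sid], r.age, r.tiv, guard_band=wcfg["guard_band"])
        res = pet_stage.positivity[sid]
        summ = extract_mask_means(w, res.positive_mask, res.negative_mask, subject_id=sid)
        rows.append(asdict(summ))
    return pd.DataFrame(rows).set_index("subject_id").sort_index(), model


def athlete_covariates(cohort: Cohort, included: list[str]) -> pd.DataFrame:
    """Covariate block for partial correlations: age, education, scanner, duration."""
    recs = {r.subject_id: r for r in cohort.athlete_records}
    rows = {
        sid: {
            "age": recs[sid].age,
            "education": recs[sid].education,
            "scanner_hrrt": 1.0 if recs[sid].scanner == "HRRT" else 0.0,
            "short_window": 1.0 if recs[sid].scan_window == "W80_90" else 0.0,
        }
        for sid in included
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def neuropsych_correlations(
    composites: pd.DataFrame,
    tau_measures: pd.DataFrame,
    covariates: pd.DataFrame,
    n_boot: int = 1000,
    bonferroni_m: int = 6,
    seed: int | None = None,
) -> pd.DataFrame:
    """Table-2-shaped block: composites x tau measures, partial r with BCa CIs."""
    comp = composites.set_index("subject_id") if "subject_id" in composites else composites
    rows = []
    k = 0
    for measure in tau_measures.columns:
        for domain in ("memory", "speed", "executive"):
            df = pd.concat(
                [comp[domain], tau_measures[measure], covariates], axis=1, join="inner"
            ).dropna()
            pc = partial_pearson(
                df[measure].to_numpy(),
                df[domain].to_numpy(),
                df[covariates.columns].to_numpy(),
                n_boot=n_boot or None,
                seed=None if seed is None else [seed, 50 + k],
            )
            rows.append(
                {
                    "tau_measure": measure,
                    "composite": domain,
                    "r": pc.r,
                    "n": pc.n,
                    "p_unadjusted": pc.p_two_sided,
                    "bca_lo": None if pc.bca_ci is None else pc.bca_ci[0],
                    "bca_hi": None if pc.bca_ci is None else pc.bca_ci[1],
                }
            )
            k += 1
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = bonferroni(table["p_unadjusted"].to_numpy(), m=bonferroni_m)
    return table


def run_pipeline(
    config: dict | None = None, seed: int = 0, outdir=None
) -> tuple[dict, dict]:
    """Execute the full chain; returns (report, manifest).

    ``config`` deep-merges over :data:`DEFAULT_CONFIG`; ``config["simulation"]``
    holds SimulationConfig overrides. When ``outdir`` is given, volumes and
    tables are also written there (NIfTI / CSV / JSON).
    """
    cfg_all = _merge(DEFAULT_CONFIG, config)
    sim_cfg = SimulationConfig(seed=seed, **cfg_all["simulation"])
    stats_cfg = cfg_all["stats"]

    cohort = simulate_cohort(sim_cfg, cfg_all["gate"])
    gate = gate_cohort(cohort)
    included = gate.included
    log.info("gate: %d screened, %d included, %d excluded", gate.n_screened, len(included), len(gate.excluded))

    pet_stage = pet_positivity_stage(cohort, included, cfg_all["pet"])
    neuro = generate_neuropsych(
        [r for r in cohort.athlete_records if r.subject_id in set(included)],
        pet_stage.pct_global,
        sim_cfg,
    )
    comps = compute_composites(neuro)

    wsummary, model = wscore_stage(cohort, included, pet_stage, cfg_all["wscore"])
    paired = paired_t(
        wsummary["mean_w_pos"].to_numpy(),
        wsummary["mean_w_neg"].to_numpy(),
        n_boot=stats_cfg["n_boot_paired"] or None,
        seed=[seed, 2],
    )

    covs = athlete_covariates(cohort, included)
    tau_measures = pd.concat([pet_stage.pct_global, pet_stage.suvr_gm_mean], axis=1)
    corr = neuropsych_correlations(
        comps,
        tau_measures,
        covs,
        n_boot=stats_cfg["n_boot_partial"],
        bonferroni_m=stats_cfg["bonferroni_m"],
        seed=seed,
    )

    report: dict = {
        "gate": {
            "n_screened": gate.n_screened,
            "n_included": len(included),
            "n_excluded": len(gate.excluded),
            "reasons": gate.reasons,
        },
        "positivity": {
            "pct_mean": float(pet_stage.pct_global.mean()),
            "pct_sd": float(pet_stage.pct_global.std(ddof=1)),
        },
        "paired_wscore": {
            "n_pairs": paired.n_pairs,
            "mean_w_pos": paired.mean_a,
            "mean_w_neg": paired.mean_b,
            "sd_w_pos": paired.sd_a,
            "sd_w_neg": paired.sd_b,
            "mean_diff": paired.mean_diff,
            "t": paired.t_stat,
            "p": paired.p_two_sided,
            "bca_ci_diff": paired.bca_ci_diff,
        },
        "neuropsych_correlations": corr.to_dict(orient="records"),
    }

    quart_cfg = cfg_all["quartiles"]
    assignment: QuartileAssignment | None = None
    if quart_cfg["enabled"]:
        assignment = assign_quartiles(pet_stage.pct_global)
        qmeans = mean_suvr_by_quartile(pet_stage.smoothed_suvr, assignment)
        ages = pd.Series({r.subject_id: r.age for r in cohort.athlete_records})
        extra = (
            covs[["scanner_hrrt", "short_window"]]
            if quart_cfg["acquisition_covariates"]
            else None
        )
        region_table = region_extent_regression(
            pet_stage.region_extent,
            assignment,
            ages,
            covariates=extra,
            n_boot=quart_cfg["n_boot"],
            seed=[seed, 3],
            min_subjects=quart_cfg["min_subjects"],
        )
        report["quartiles"] = {
            "group_sizes": list(assignment.group_sizes),
            "cut_values": list(assignment.cut_values),
            "region_table": region_table.to_dict(orient="records"),
        }
    else:
        qmeans = None

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": _config_snapshot(cfg_all, sim_cfg),
        "effective_n": {
            "controls": len(cohort.control_records),
            "athletes_screened": len(cohort.athlete_records),
            "athletes_included": len(included),
            "paired_pairs": paired.n_pairs,
        },
        "checksums": {"report": _sha256_json(report)},
    }

    if outdir is not None:
        _write_outputs(outdir, cohort, gate, pet_stage, wsummary, comps, report, manifest, qmeans)
    return report, manifest


def _config_snapshot(cfg_all: dict, sim_cfg: SimulationConfig) -> dict:
    snap = {k: v for k, v in cfg_all.items() if k != "simulation"}
    sim = asdict(sim_cfg)
    sim["tau_hotspots"] = [
        {"center": list(h["center"]), "radius": h["radius"], "peak": h["peak"]}
        for h in sim["tau_hotspots"]
    ]
    snap["simulation"] = sim
    return snap


def _sha256_json(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _write_outputs(outdir, cohort, gate, pet_stage, wsummary, comps, report, manifest, qmeans):
    import os

    from .volume_io import save_volume

    os.makedirs(outdir, exist_ok=True)
    subjects_to_frame(cohort.control_records + cohort.athlete_records).to_csv(
        os.path.join(outdir, "subjects.csv"), index=False
    )
    cohort.biofluids.to_csv(os.path.join(outdir, "biofluids.csv"), index=False)
    pd.DataFrame(
        {"subject_id": gate.excluded, "reason": [gate.reasons[s] for s in gate.excluded]}
    ).to_csv(os.path.join(outdir, "gate_exclusions.csv"), index=False)
    pet_stage.pct_global.rename_axis("subject_id").to_frame().join(
        pet_stage.suvr_gm_mean
    ).to_csv(os.path.join(outdir, "positivity.csv"))
    pet_stage.region_extent.rename_axis("subject_id").to_csv(
        os.path.join(outdir, "region_extent.csv")
    )
    wsummary.to_csv(os.path.join(outdir, "wscore_summary.csv"))
    comps.to_csv(os.path.join(outdir, "composites.csv"), index=False)
    if qmeans is not None:
        for q, vol in qmeans.items():
            save_volume(vol, os.path.join(outdir, f"quartile_mean_q{q}.nii.gz"))
    with open(os.path.join(outdir, "analysis_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
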