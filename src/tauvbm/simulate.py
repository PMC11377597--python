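"""Synthetic cohort generator: the ground-truth test bed for the pipeline.

Emulates the statistical structure the analysis assumes, not anatomy:

* control grey-matter (GM) maps = a fixed smooth baseline template (sum of
  low-frequency cosines — no real brain template, so nothing to download)
  plus linear age and TIV effects plus voxelwise Gaussian noise;
* athlete SUVR maps = 1.0 baseline + a spatially structured tau excess field
  (anterior/lateral-weighted diffuse component plus compact radial-cosine
  hotspots), scaled by a per-subject severity factor, plus Gaussian noise;
* athlete GM maps = the control-model prediction for the athlete's age/TIV
  plus ``coupling_beta * max(SUVR - 1, 0)`` (atrophy proportional to tau
  excess; coupling_beta <= 0 for the positive-coupling scenario) plus noise;
* memory composite inputs drawn so that the composite equals
  ``memory_slope * (global % positivity)`` plus noise, while the speed and
  executive domains are tau-independent (null domains);
* biofluid panels whose values straddle the screening thresholds, with the
  generator's own positive labels recorded for gate verification.

Everything is deterministic given ``SimulationConfig.seed``; independent
substreams keep the stages decoupled (changing only the seed changes noise,
never structural parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volume_io import ImageVolume, LabelAtlas, SubjectRecord

__all__ = [
    "Hotspot",
    "SimulationConfig",
    "gm_mask",
    "reference_mask",
    "make_atlas",
    "baseline_template",
    "tau_excess_field",
    "generate_controls",
    "generate_athletes",
    "generate_neuropsych",
    "generate_biofluids",
]


@dataclass(frozen=True)
class Hotspot:
    """Isotropic radial-cosine bump: compact support, smooth, peak at centre."""

    center: tuple[int, int, int]
    radius: float
    peak: float


# default hotspots: anterior (high j) and lateral (i near the edges) placement
# echoing a frontotemporal-weighted pattern; mid-to-upper axial position.
_DEFAULT_HOTSPOTS = (
    Hotspot((4, 11, 9), 3.2, 0.50),
    Hotspot((11, 11, 9), 3.2, 0.50),
    Hotspot((3, 8, 7), 2.8, 0.375),
    Hotspot((12, 8, 7), 2.8, 0.375),
)


@dataclass
class SimulationConfig:
    """All structural parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 54 controls aged 26-71 (used
    only to fit the normative model), 52 screened athletes of whom 5 are
    AD-biomarker/PET-pattern positive leaving 47, scanner mix 66% PET/CT,
    78.7% with the 80-100 min window. ``coupling_beta`` and the tau-field
    amplitudes are calibrated once so the athlete paired w-score contrast
    lands near -0.37 (tau-positive voxels) vs -0.31 (tau-negative voxels);
    see docs/methods.md.
    """

    seed: int
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_controls: int = 54
    n_athletes: int = 52
    control_age_range: tuple[float, float] = (26.0, 71.0)
    athlete_age_mean: float = 51.0
    athlete_age_sd: float = 14.0
    athlete_age_range: tuple[float, float] = (24.0, 85.0)
    tiv_mean: float = 1500.0  # mL
    tiv_sd: float = 120.0
    education_mean: float = 15.0  # years
    education_sd: float = 2.0
    # grey matter model (GM probability-like units)
    beta_age: float = -0.002  # per year
    beta_tiv: float = 2.0e-4  # per mL
    sigma_gm: float = 0.04
    # tau signal
    tau_baseline: float = 1.0  # SUVR
    tau_diffuse: float = 0.38  # amplitude of the anterior/lateral diffuse excess
    tau_hotspots: tuple[Hotspot, ...] = _DEFAULT_HOTSPOTS
    tau_noise_sd: float = 0.08
    severity_range: tuple[float, float] = (0.7, 1.3)
    # tau -> atrophy coupling (GM units per unit SUVR excess; <= 0 couples
    # higher tau to lower GM)
    coupling_beta: float = -0.040
    # neuropsych coupling (memory composite z per % positivity; <= 0)
    memory_slope: float = -0.018
    memory_sigma: float = 0.8
    memory_jitter: float = 0.3
    domain_factor_sd: float = 0.6
    domain_noise_sd: float = 0.4
    # acquisition mix
    p_petct: float = 0.66
    p_w80_100: float = 0.787

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(d < 8 for d in self.grid_dims):
            raise ValueError(f"grid dims must be >= 8 per axis, got {self.grid_dims}")
        for name in ("sigma_gm", "tau_noise_sd", "memory_sigma", "memory_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for h in self.tau_hotspots:
            if any(not (0 <= c < d) for c, d in zip(h.center, self.grid_dims)):
                raise ValueError(f"hotspot centre {h.center} outside grid {self.grid_dims}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substream per stage; offset keeps streams disjoint across
    # stage indices and alternate control samples
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def _coords(dims: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(*(np.arange(d, dtype=float) for d in dims), indexing="ij")


def gm_mask(cfg: SimulationConfig) -> np.ndarray:
    """Ellipsoidal grey-matter analysis mask inscribed in the grid."""
    i, j, k = _coords(cfg.grid_dims)
    c = [(d - 1) / 2.0 for d in cfg.grid_dims]
    a = [0.46 * d for d in cfg.grid_dims]
    r2 = ((i - c[0]) / a[0]) ** 2 + ((j - c[1]) / a[1]) ** 2 + ((k - c[2]) / a[2]) ** 2
    return r2 <= 1.0


def reference_mask(cfg: SimulationConfig) -> np.ndarray:
    """Synthetic inferior reference slab (outside the GM analysis mask)."""
    i, j, k = _coords(cfg.grid_dims)
    return (k <= 1) & ~gm_mask(cfg)


def make_atlas(cfg: SimulationConfig) -> LabelAtlas:
    """Generic integer-label parcellation of the GM mask.

    Eight cortical octants named by position (anterior/posterior x left/right
    x superior/inferior) plus four small deep-grey spheres placed centrally,
    away from the tau hotspots ("hippocampus-like", "putamen-like",
    "caudate-like" stand-ins used as negative-control regions).
    """
    dims = cfg.grid_dims
    gm = gm_mask(cfg)
    i, j, k = _coords(dims)
    c = [(d - 1) / 2.0 for d in dims]
    labels = np.zeros(dims, dtype=np.int32)
    names: dict[int, str] = {}
    lab = 0
    for jo, ap in ((1, "anterior"), (0, "posterior")):
        for io, lr in ((0, "left"), (1, "right")):
            for ko, si in ((1, "superior"), (0, "inferior")):
                lab += 1
                names[lab] = f"{ap}_{lr}_{si}"
                sel = (
                    gm
                    & ((j > c[1]) == bool(jo))
                    & ((i > c[0]) == bool(io))
                    & ((k > c[2]) == bool(ko))
                )
                labels[sel] = lab
    deep = [
        ("hippocampus_like_left", (c[0] - 2.0, c[1] - 1.0, c[2] - 1.2)),
        ("hippocampus_like_right", (c[0] + 2.0, c[1] - 1.0, c[2] - 1.2)),
        ("putamen_like", (c[0] - 1.2, c[1] + 0.5, c[2])),
        ("caudate_like", (c[0] + 1.2, c[1] + 0.5, c[2])),
    ]
    for name, (ci, cj, ck) in deep:
        lab += 1
        names[lab] = name
        sel = gm & (((i - ci) ** 2 + (j - cj) ** 2 + (k - ck) ** 2) <= 1.5**2)
        labels[sel] = lab
    return LabelAtlas(labels, names)


def baseline_template(cfg: SimulationConfig) -> np.ndarray:
    """Fixed smooth GM baseline: mean level plus low-frequency cosines."""
    i, j, k = _coords(cfg.grid_dims)
    ni = [x / (d - 1) for x, d in zip((i, j, k), cfg.grid_dims)]
    return (
        0.55
        + 0.06 * np.cos(np.pi * ni[0])
        + 0.05 * np.cos(2 * np.pi * ni[1])
        + 0.04 * np.cos(np.pi * ni[2]) * np.cos(np.pi * ni[1])
    )


def tau_excess_field(cfg: SimulationConfig) -> np.ndarray:
    """Noise-free tau excess E(v) at severity 1 (SUVR units above baseline).

    Diffuse component: amplitude * a smooth anterior/lateral-weighted profile
    (low centrally, where the deep negative-control regions sit). Hotspots:
    compact radial-cosine bumps. Zero outside the GM mask.
    """
    dims = cfg.grid_dims
    gm = gm_mask(cfg)
    i, j, k = _coords(dims)
    c = [(d - 1) / 2.0 for d in dims]
    anterior = j / (dims[1] - 1)  # 0 posterior -> 1 anterior
    lateral = np.abs(i - c[0]) / c[0]  # 0 medial -> 1 lateral
    profile = np.clip(0.55 + 0.35 * anterior + 0.25 * lateral, 0.0, 1.0)
    # central depression keeps the deep negative-control regions sub-threshold
    r_c2 = (i - c[0]) ** 2 + (j - c[1]) ** 2 + (k - c[2]) ** 2
    profile = profile * (1.0 - 0.85 * np.exp(-r_c2 / (2.0 * 3.6**2)))
    field = cfg.tau_diffuse * profile
    for h in cfg.tau_hotspots:
        r = np.sqrt(
            (i - h.center[0]) ** 2 + (j - h.center[1]) ** 2 + (k - h.center[2]) ** 2
        )
        bump = np.where(r <= h.radius, np.cos(0.5 * np.pi * r / h.radius) ** 2, 0.0)
        field = field + h.peak * bump
    return np.where(gm, field, 0.0)


def _volume(cfg: SimulationConfig, data: np.ndarray) -> ImageVolume:
    return ImageVolume(data, cfg.voxel_size_mm, "synthetic-common")


def generate_controls(
    cfg: SimulationConfig, sample: int = 0
) -> tuple[list[SubjectRecord], list[ImageVolume]]:
    """Healthy-control records and GM maps.

    ``sample`` selects an independent substream (sample=1 gives a held-out
    control cohort from the same model family, for calibration checks).
    """
    rng = _rng(cfg, 10 + sample)
    n = cfg.n_controls
    lo, hi = cfg.control_age_range
    age = rng.uniform(lo, hi, size=n)
    tiv = rng.normal(cfg.tiv_mean, cfg.tiv_sd, size=n)
    tiv = np.clip(tiv, 1000.0, 2200.0)
    template = baseline_template(cfg)
    age_c, tiv_c = np.mean(cfg.control_age_range), cfg.tiv_mean
    records, vols = [], []
    for s in range(n):
        noise = rng.normal(0.0, cfg.sigma_gm, size=cfg.grid_dims)
        data = (
            template
            + cfg.beta_age * (age[s] - age_c)
            + cfg.beta_tiv * (tiv[s] - tiv_c)
            + noise
        )
        records.append(
            SubjectRecord(
                subject_id=f"ctl{sample}{s:03d}",
                age=float(age[s]),
                tiv=float(tiv[s]),
                group="control",
            )
        )
        vols.append(_volume(cfg, data))
    return records, vols


def generate_athletes(
    cfg: SimulationConfig,
) -> tuple[list[SubjectRecord], list[ImageVolume], list[ImageVolume], dict]:
    """Athlete records, GM maps, (unsmoothed) SUVR maps, and ground truth.

    SUVR = baseline + severity * excess field + noise; GM = control-model
    prediction for the athlete's covariates + coupling_beta * max(SUVR - 1, 0)
    + noise. Returns a truth dict with the per-subject severity factors.
    """
    rng = _rng(cfg, 20)
    n = cfg.n_athletes
    lo, hi = cfg.athlete_age_range
    ages = []
    while len(ages) < n:
        a = rng.normal(cfg.athlete_age_mean, cfg.athlete_age_sd)
        if lo <= a <= hi:
            ages.append(a)
    age = np.array(ages)
    tiv = np.clip(rng.normal(cfg.tiv_mean, cfg.tiv_sd, size=n), 1000.0, 2200.0)
    education = np.clip(rng.normal(cfg.education_mean, cfg.education_sd, size=n), 8.0, 22.0)
    severity = rng.uniform(*cfg.severity_range, size=n)
    scanner = np.where(rng.uniform(size=n) < cfg.p_petct, "PETCT", "HRRT")
    window = np.where(rng.uniform(size=n) < cfg.p_w80_100, "W80_100", "W80_90")

    template = baseline_template(cfg)
    excess = tau_excess_field(cfg)
    age_c, tiv_c = np.mean(cfg.control_age_range), cfg.tiv_mean
    records, gm_vols, suvr_vols = [], [], []
    for s in range(n):
        suvr = (
            cfg.tau_baseline
            + severity[s] * excess
            + rng.normal(0.0, cfg.tau_noise_sd, size=cfg.grid_dims)
        )
        gm_pred = (
            template + cfg.beta_age * (age[s] - age_c) + cfg.beta_tiv * (tiv[s] - tiv_c)
        )
        gm = (
            gm_pred
            + cfg.coupling_beta * np.maximum(suvr - 1.0, 0.0)
            + rng.normal(0.0, cfg.sigma_gm, size=cfg.grid_dims)
        )
        records.append(
            SubjectRecord(
                subject_id=f"ath{s:03d}",
                age=float(age[s]),
                tiv=float(tiv[s]),
                group="athlete",
                education=float(education[s]),
                scanner=str(scanner[s]),
                scan_window=str(window[s]),
            )
        )
        gm_vols.append(_volume(cfg, gm))
        suvr_vols.append(_volume(cfg, suvr))
    truth = {
        "severity": {r.subject_id: float(v) for r, v in zip(records, severity)},
        "coupling_beta": cfg.coupling_beta,
        "memory_slope": cfg.memory_slope,
    }
    return records, gm_vols, suvr_vols, truth


def generate_neuropsych(
    records: list[SubjectRecord],
    pct_positivity,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Normed neuropsych scores with the memory composite coupled to tau.

    The three memory z-scores average *exactly* to
    memory_slope * pct + N(0, memory_sigma) (within-subject jitter sums to
    zero), so the generated composite has the stated linear model. Speed and
    executive inputs are drawn independently of tau (null domains).
    """
    pct = pd.Series(dict(pct_positivity), dtype=float)
    missing = [r.subject_id for r in records if r.subject_id not in pct.index]
    if missing:
        raise ValueError(f"no %% positivity for subjects: {missing}")
    rng = _rng(cfg, 30)
    rows = []
    for r in records:
        m = cfg.memory_slope * pct[r.subject_id] + rng.normal(0.0, cfg.memory_sigma)
        d = rng.normal(0.0, cfg.memory_jitter, size=2)
        mem = [m + d[0], m + d[1], m - d[0] - d[1]]
        f_speed = rng.normal(0.0, cfg.domain_factor_sd)
        speed = f_speed + rng.normal(0.0, cfg.domain_noise_sd, size=6)
        f_exec = rng.normal(0.0, cfg.domain_factor_sd)
        execz = f_exec + rng.normal(0.0, cfg.domain_noise_sd, size=6)
        exec_t = 50.0 + 10.0 * execz
        rows.append(
            {
                "subject_id": r.subject_id,
                "ravlt_trials_z": mem[0],
                "ravlt_delay_z": mem[1],
                "rvdlt_trials_z": mem[2],
                "tmt_a_z": speed[0],
                "digit_fwd_z": speed[1],
                "stroop_color_z": speed[2],
                "stroop_word_z": speed[3],
                "sdmt_written_z": speed[4],
                "sdmt_oral_z": speed[5],
                "digit_bwd_t": exec_t[0],
                "wcst_err_t": exec_t[1],
                "wcst_persev_err_t": exec_t[2],
                "wcst_nonpersev_err_t": exec_t[3],
                "wcst_conceptual_t": exec_t[4],
                "tmt_b_t": exec_t[5],
            }
        )
    return pd.DataFrame(rows)


def generate_biofluids(
    records: list[SubjectRecord],
    fraction_positive: float,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Plasma/CSF panels straddling the screening thresholds.

    Exactly ``round(fraction_positive * n)`` subjects get values above their
    assay's threshold; the rest sit below with a stated margin. The
    ``true_positive`` column records the generator's own labels so the gate
    can be verified against ground truth.
    """
    if not 0.0 <= fraction_positive <= 1.0:
        raise ValueError(f"fraction_positive must be in [0, 1], got {fraction_positive}")
    rng = _rng(cfg, 40)
    n = len(records)
    n_pos = int(round(fraction_positive * n))
    pos_idx = set(rng.choice(n, size=n_pos, replace=False).tolist()) if n_pos else set()
    assays = rng.choice(["in_house", "commercial_v2", "csf"], size=n, p=[0.30, 0.38, 0.32])
    rows = []
    for s, r in enumerate(records):
        positive = s in pos_idx
        row = {
            "subject_id": r.subject_id,
            "visit": 1,
            "plasma_ptau181": np.nan,
            "plasma_assay": None,
            "csf_ptau181": np.nan,
            "csf_abeta42": np.nan,
            "csf_ttau": np.nan,
            "true_positive": positive,
        }
        assay = assays[s]
        if assay == "in_house":
            thr = 10.5 if r.age < 60 else 13.3
            row["plasma_assay"] = "in_house"
            row["plasma_ptau181"] = thr * (
                rng.uniform(1.05, 1.6) if positive else rng.uniform(0.55, 0.95)
            )
        elif assay == "commercial_v2":
            row["plasma_assay"] = "commercial_v2"
            row["plasma_ptau181"] = 2.2 * (
                rng.uniform(1.05, 2.0) if positive else rng.uniform(0.2, 0.9)
            )
        else:
            if positive:
                ttau = rng.uniform(250.0, 500.0)
                row["csf_ptau181"] = rng.uniform(75.0, 130.0)
                row["csf_ttau"] = ttau
                row["csf_abeta42"] = (240.0 + 1.18 * ttau) * rng.uniform(0.3, 0.7)
            else:
                row["csf_ptau181"] = rng.uniform(20.0, 60.0)
                row["csf_ttau"] = max(50.0, rng.normal(256.0, 100.0))
                row["csf_abeta42"] = max(150.0, rng.normal(926.0, 300.0))
        rows.append(row)
    return pd.DataFrame(rows)
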