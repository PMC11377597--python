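"""Voxelwise normative modelling: w-score maps from a healthy-control fit.

For each voxel inside the fit mask, grey-matter volume in healthy controls is
regressed on age and total intracranial volume (ordinary least squares on
[1, age, TIV]). A subject's w-score at a voxel is then

    w = (observed - predicted(age, TIV)) / SD(control residuals)

so w is a covariate-adjusted z-score: negative w means less grey matter than
expected for that age and head size. Residual SD uses the unbiased n - 3
denominator. Covariates are z-scaled internally for conditioning; w-scores
are invariant to any affine covariate rescaling, so this is a numerical
choice only.

Voxels whose control residual SD falls below a configurable floor are
excluded from maps and summaries (division blow-up at near-deterministic
voxels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import ImageVolume, SubjectRecord, assert_same_grid

__all__ = ["NormativeModel", "WScoreSummary", "fit_normative", "wscore_map", "extract_mask_means"]

log = logging.getLogger(__name__)

#: minimum control residual SD (GM units) for a voxel to stay in the analysis
SD_FLOOR = 1e-6


@dataclass
class NormativeModel:
    """Per-voxel OLS coefficients and residual SD over the fit mask.

    Coefficients are stored on the z-scaled covariate basis recorded in
    ``covariate_scaling``; ``beta_age_per_year`` / ``beta_tiv_per_ml``
    expose them in raw units.
    """

    beta0: np.ndarray
    beta_age: np.ndarray
    beta_tiv: np.ndarray
    resid_sd: np.ndarray
    fit_mask: np.ndarray
    n_controls: int
    covariate_scaling: dict
    voxel_size_mm: tuple[float, float, float]
    age_range: tuple[float, float]
    tiv_range: tuple[float, float]
    sd_floor: float = SD_FLOOR

    @property
    def usable_mask(self) -> np.ndarray:
        return self.fit_mask & (self.resid_sd >= self.sd_floor)

    @property
    def beta_age_per_year(self) -> np.ndarray:
        return self.beta_age / self.covariate_scaling["age_sd"]

    @property
    def beta_tiv_per_ml(self) -> np.ndarray:
        return self.beta_tiv / self.covariate_scaling["tiv_sd"]

    def _scale(self, age: float, tiv: float) -> tuple[float, float]:
        s = self.covariate_scaling
        return (age - s["age_mean"]) / s["age_sd"], (tiv - s["tiv_mean"]) / s["tiv_sd"]

    def predict(self, age: float, tiv: float) -> np.ndarray:
        za, zt = self._scale(age, tiv)
        return self.beta0 + self.beta_age * za + self.beta_tiv * zt


@dataclass
class WScoreSummary:
    subject_id: str
    mean_w_pos: float
    mean_w_neg: float
    n_vox_pos: int
    n_vox_neg: int


def fit_normative(
    volumes: list[ImageVolume],
    records: list[SubjectRecord],
    fit_mask: np.ndarray,
    sd_floor: float = SD_FLOOR,
) -> NormativeModel:
    """Fit the voxelwise age+TIV normative model on control volumes."""
    if len(volumes) != len(records):
        raise ValueError("one volume per subject record required")
    n = len(volumes)
    if n < 10:
        raise ValueError(f"need >= 10 controls to fit the normative model, got {n}")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != n:
        raise ValueError("duplicate subject ids in control set")
    base = volumes[0]
    for v in volumes[1:]:
        assert_same_grid(base, v)
    mask = np.asarray(fit_mask) > 0.5
    if mask.shape != base.shape:
        raise ValueError("fit mask grid does not match volumes")

    age = np.array([r.age for r in records], dtype=float)
    tiv = np.array([r.tiv for r in records], dtype=float)
    for name, v in (("age", age), ("tiv", tiv)):
        if np.std(v) == 0:
            raise ValueError(f"degenerate covariate '{name}': constant across controls")
    scaling = {
        "age_mean": float(age.mean()),
        "age_sd": float(age.std(ddof=0)),
        "tiv_mean": float(tiv.mean()),
        "tiv_sd": float(tiv.std(ddof=0)),
    }
    za = (age - scaling["age_mean"]) / scaling["age_sd"]
    zt = (tiv - scaling["tiv_mean"]) / scaling["tiv_sd"]
    X = np.column_stack([np.ones(n), za, zt])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (age and TIV collinear)")

    Y = np.stack([v.data[mask] for v in volumes])  # n x V
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)  # 3 x V
    resid = Y - X @ coef
    sd = np.sqrt((resid**2).sum(axis=0) / (n - 3))

    def grid(vals: np.ndarray) -> np.ndarray:
        g = np.full(base.shape, np.nan)
        g[mask] = vals
        return g

    n_floored = int((sd < sd_floor).sum())
    if n_floored:
        log.info("normative fit: %d voxels below residual-SD floor excluded", n_floored)
    return NormativeModel(
        beta0=grid(coef[0]),
        beta_age=grid(coef[1]),
        beta_tiv=grid(coef[2]),
        resid_sd=grid(sd),
        fit_mask=mask,
        n_controls=n,
        covariate_scaling=scaling,
        voxel_size_mm=base.voxel_size_mm,
        age_range=(float(age.min()), float(age.max())),
        tiv_range=(float(tiv.min()), float(tiv.max())),
        sd_floor=sd_floor,
    )


def wscore_map(
    model: NormativeModel,
    gm: ImageVolume,
    age: float,
    tiv: float,
    guard_band: float = 0.10,
) -> ImageVolume:
    """W-score map for one subject: (observed - predicted) / control residual SD.

    Warns (never silently) when the subject's age or TIV falls outside the
    control range extended by ``guard_band`` (fraction of the range) — the
    normative prediction is then an extrapolation.
    """
    if gm.shape != model.fit_mask.shape:
        raise ValueError(f"grid mismatch: subject {gm.shape} vs model {model.fit_mask.shape}")
    for name, value, (lo, hi) in (
        ("age", age, model.age_range),
        ("tiv", tiv, model.tiv_range),
    ):
        pad = guard_band * (hi - lo)
        if not (lo - pad <= value <= hi + pad):
            warnings.warn(
                f"{name}={value} outside control range [{lo}, {hi}] (+/- {pad:.3g}); "
                "w-scores are extrapolated",
                stacklevel=2,
            )
    pred = model.predict(age, tiv)
    w = np.full(gm.shape, np.nan)
    ok = model.usable_mask & np.isfinite(gm.data)
    w[ok] = (gm.data[ok] - pred[ok]) / model.resid_sd[ok]
    return ImageVolume(w, model.voxel_size_mm, gm.space_tag)


def extract_mask_means(
    w: ImageVolume,
    positive_mask: np.ndarray,
    negative_mask: np.ndarray,
    subject_id: str = "",
) -> WScoreSummary:
    """Mean w inside the tau-positive and tau-negative masks.

    Masks must be disjoint. An empty positive mask yields a missing
    ``mean_w_pos`` (the subject then contributes no paired observation);
    counts are of non-missing w voxels in each mask.
    """
    pos = np.asarray(positive_mask) > 0.5
    neg = np.asarray(negative_mask) > 0.5
    if pos.shape != w.shape or neg.shape != w.shape:
        raise ValueError("mask grids do not match the w-score map")
    if np.any(pos & neg):
        raise ValueError("positive and negative masks overlap")

    def mean_in(m: np.ndarray) -> tuple[float, int]:
        vals = w.data[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan"), 0
        return float(vals.mean()), int(vals.size)

    mp, np_ = mean_in(pos)
    mn, nn = mean_in(neg)
    if np_ == 0:
        log.info("subject %s: empty tau-positive mask, no paired observation", subject_id)
    return WScoreSummary(
        subject_id=subject_id, mean_w_pos=mp, mean_w_neg=mn, n_vox_pos=np_, n_vox_neg=nn
    )
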