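"""Quartile analysis of tau-PET burden and region-wise extent regressions.

Subjects are split into four groups by their global grey-matter % positivity
(quartile 1 = lowest burden). Mean SUVR images per quartile visualise the
spatial spread of signal; per-region regressions of positive-voxel extent on
quartile group (entered as the number 1-4) and age, with BCa confidence
intervals stratified by quartile and Bonferroni correction over regions,
identify where the signal grows across quartiles.

Deterministic conventions the split needs (ties and n mod 4 are inevitable
at n = 47): subjects are ordered by (% positivity, subject_id) and the
remainder goes to the *lower* quartiles, so n = 47 gives sizes 12/12/12/11.
The assignment depends only on ranks, hence is invariant to any strictly
monotone transform of the % values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bca_ci, bonferroni
from .volume_io import ImageVolume, assert_same_grid

__all__ = ["QuartileAssignment", "assign_quartiles", "mean_suvr_by_quartile", "region_extent_regression"]

log = logging.getLogger(__name__)


@dataclass
class QuartileAssignment:
    quartile: dict[str, int]
    cut_values: tuple[float, float, float]
    tie_warning: bool = False
    group_sizes: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))

    def as_series(self) -> pd.Series:
        return pd.Series(self.quartile, name="quartile").sort_index()


def assign_quartiles(pct: pd.Series | dict[str, float]) -> QuartileAssignment:
    """Rank-split subjects into 4 quartile groups by % positivity.

    ``pct`` maps subject_id -> global % positivity. Ties are broken by
    subject id (stable); with n not divisible by 4 the larger groups are the
    lower quartiles. Interior cut values are midpoints between the boundary
    subjects' values.
    """
    s = pd.Series(dict(pct), dtype=float)
    n = len(s)
    if n < 4:
        raise ValueError(f"need at least 4 subjects to form quartiles, got {n}")
    if s.isna().any():
        raise ValueError(f"missing % positivity for: {sorted(s[s.isna()].index)}")
    order = sorted(s.index, key=lambda sid: (s[sid], str(sid)))
    base, rem = divmod(n, 4)
    sizes = tuple(base + (1 if q < rem else 0) for q in range(4))
    quartile: dict[str, int] = {}
    bounds = []
    i = 0
    for q, size in enumerate(sizes, start=1):
        for sid in order[i : i + size]:
            quartile[sid] = q
        if q < 4:
            bounds.append(0.5 * (s[order[i + size - 1]] + s[order[i + size]]))
        i += size
    tie = s.duplicated().any()
    if tie:
        log.warning("tied % positivity values; tie-break by subject id is in effect")
    return QuartileAssignment(
        quartile=quartile,
        cut_values=tuple(float(b) for b in bounds),  # type: ignore[arg-type]
        tie_warning=bool(tie),
        group_sizes=sizes,
    )


def mean_suvr_by_quartile(
    suvr_maps: dict[str, ImageVolume],
    assignment: QuartileAssignment,
) -> dict[int, ImageVolume]:
    """Voxelwise mean SUVR image within each quartile group."""
    by_group: dict[int, list[ImageVolume]] = {1: [], 2: [], 3: [], 4: []}
    for sid, q in assignment.quartile.items():
        if sid not in suvr_maps:
            raise ValueError(f"no SUVR map for subject {sid}")
        by_group[q].append(suvr_maps[sid])
    out = {}
    ref = next(iter(suvr_maps.values()))
    for q, vols in by_group.items():
        if not vols:
            raise ValueError(f"quartile {q} is empty")
        for v in vols:
            assert_same_grid(ref, v)
        out[q] = ref.with_data(np.mean([v.data for v in vols], axis=0))
    return out


def _ols_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and two-sided p-values (closed form)."""
    n, p = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - p
    s2 = (resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df=dof)
    pvals = np.where(se == 0, np.where(coef == 0, 1.0, 0.0), pvals)
    return coef, pvals


def region_extent_regression(
    extent: pd.DataFrame,
    assignment: QuartileAssignment,
    ages: pd.Series | dict[str, float],
    covariates: pd.DataFrame | None = None,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
    min_subjects: int = 8,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Per-region OLS of positive-voxel extent on quartile group and age.

    ``extent`` is subjects x regions (index = subject_id, one column per
    region label or name). Quartile enters as a numeric 1-4 predictor;
    optional extra ``covariates`` (e.g. scanner, scan duration; index =
    subject_id) are appended to the design. The quartile coefficient gets a
    BCa CI with resampling stratified by quartile group, p-values are
    Bonferroni-corrected over the regions tested, and rows come back sorted
    by the unstandardized quartile coefficient, descending. Regions observed
    in fewer than ``min_subjects`` subjects are skipped with a warning.
    """
    ages = pd.Series(dict(ages), dtype=float)
    q = assignment.as_series().astype(float)
    rows = []
    for region in extent.columns:
        y_all = extent[region]
        sub = y_all.dropna().index.intersection(q.index).intersection(ages.dropna().index)
        if covariates is not None:
            sub = sub.intersection(covariates.dropna().index)
        sub = sorted(sub)
        if len(sub) < min_subjects:
            log.warning("region %s: only %d subjects, skipped", region, len(sub))
            continue
        y = y_all.loc[sub].to_numpy(dtype=float)
        cols = [np.ones(len(sub)), q.loc[sub].to_numpy(), ages.loc[sub].to_numpy()]
        if covariates is not None:
            cov = covariates.loc[sub]
            cols.extend(cov[c].to_numpy(dtype=float) for c in cov.columns)
        X = np.column_stack(cols)
        coef, pvals = _ols_with_p(X, y)
        strata = q.loc[sub].to_numpy()
        rows_idx = np.arange(len(sub))

        def stat(idx: np.ndarray) -> float:
            c, *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            return float(c[1])

        ci = bca_ci(
            stat,
            rows_idx,
            n_boot=n_boot,
            alpha=alpha,
            strata=strata,
            seed=seed,
            indices=True,
        )
        rows.append(
            {
                "region": region,
                "n": len(sub),
                "coef_quartile": float(coef[1]),
                "coef_age": float(coef[2]),
                "p_raw": float(pvals[1]),
                "bca_lo": ci[0],
                "bca_hi": ci[1],
            }
        )
    if not rows:
        raise ValueError("no region had enough subjects for regression")
    table = pd.DataFrame(rows)
    m = bonferroni_m if bonferroni_m is not None else len(table)
    table["p_bonferroni"] = bonferroni(table["p_raw"].to_numpy(), m=m)
    return table.sort_values("coef_quartile", ascending=False, kind="stable").reset_index(
        drop=True
    )
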