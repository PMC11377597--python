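"""Inferential toolkit: paired t, partial Pearson correlation, BCa bootstrap CIs,
Bonferroni adjustment.

These four primitives carry all the hypothesis tests in the analysis:

* within-subject comparison of mean grey-matter w-scores in tau-positive vs
  tau-negative voxels (paired t with a BCa CI on the mean difference);
* associations between tau-PET measures and neuropsychological composites
  (Pearson partial correlations controlling for age, education, scanner, and
  scan duration, with BCa CIs);
* region-wise quartile regressions (BCa CIs stratified by quartile group,
  Bonferroni-corrected over regions).

The bias-corrected accelerated (BCa) interval adjusts bootstrap percentile
endpoints for median bias (z0, from the fraction of bootstrap statistics below
the point estimate) and for skewness (acceleration a, from the jackknife).
Every bootstrap call takes an explicit seed; there is no hidden global RNG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "PartialCorrelation",
    "paired_t",
    "partial_pearson",
    "bca_ci",
    "bonferroni",
]


@dataclass
class PairedComparison:
    n_pairs: int
    mean_a: float
    mean_b: float
    mean_diff: float
    sd_a: float
    sd_b: float
    sd_diff: float
    t_stat: float
    p_two_sided: float
    bca_ci_diff: tuple[float, float] | None = None
    degenerate: bool = False


@dataclass
class PartialCorrelation:
    r: float
    n: int
    k_covariates: int
    p_two_sided: float
    bca_ci: tuple[float, float] | None = None
    degenerate: bool = False

    @property
    def df(self) -> int:
        return self.n - 2 - self.k_covariates


def paired_t(
    a,
    b,
    n_boot: int | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PairedComparison:
    """Two-sided paired t-test on ``a - b`` with complete-case pairing.

    Pairs where either element is missing (NaN) are dropped. The standard
    deviation uses the n-1 denominator; p comes from the t distribution with
    n-1 df. If ``n_boot`` is given, a BCa CI for the mean difference is
    attached (resampling pairs).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.shape} vs {b.shape}")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    degenerate = False
    if sd_d == 0.0:
        if mean_d == 0.0:
            t, p = 0.0, 1.0
        else:
            # all differences identical and nonzero: t undefined (infinite)
            t, p, degenerate = np.inf * np.sign(mean_d), 0.0, True
    else:
        t = mean_d / (sd_d / np.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    ci = None
    if n_boot:
        ci = bca_ci(lambda x: float(np.mean(x)), d, n_boot=n_boot, alpha=alpha, seed=seed)
    return PairedComparison(
        n_pairs=n,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=mean_d,
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        sd_diff=sd_d,
        t_stat=float(t),
        p_two_sided=float(p),
        bca_ci_diff=ci,
        degenerate=degenerate,
    )


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_pearson(
    x,
    y,
    covariates=None,
    n_boot: int | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PartialCorrelation:
    """Pearson partial correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares; r is
    the Pearson correlation of the residuals, with a two-sided p from
    t = r * sqrt(df / (1 - r^2)), df = n - 2 - k. With no covariates this is
    the plain Pearson correlation. Rows with any missing value are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((x.size, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    if not (x.shape[0] == y.shape[0] == C.shape[0]):
        raise ValueError("x, y and covariates must have equal length")
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[keep], y[keep], C[keep]
    n, k = x.size, C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear columns)")

    def _r(xi: np.ndarray, yi: np.ndarray, Ci: np.ndarray) -> float:
        di = np.column_stack([np.ones(len(xi)), Ci])
        rx = _residualize(xi, di)
        ry = _residualize(yi, di)
        # a variable explained (numerically) exactly by the covariates has no
        # residual signal left to correlate: r = 0, not the ratio of rounding noise
        for resid, orig in ((rx, xi), (ry, yi)):
            ss, oss = resid @ resid, orig @ orig
            if ss == 0:
                raise ZeroDivisionError("zero residual variance")
            if ss <= 1e-20 * max(oss, 1.0):
                return 0.0
        return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))

    r = _r(x, y, C)
    df = n - 2 - k
    degenerate = False
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.clip(r, -1.0, 1.0))
        p = 0.0
        degenerate = True
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=df))
    ci = None
    if n_boot:
        rows = np.arange(n)

        def stat(idx_rows: np.ndarray) -> float:
            return _r(x[idx_rows], y[idx_rows], C[idx_rows])

        ci = bca_ci(stat, rows, n_boot=n_boot, alpha=alpha, seed=seed, indices=True)
    return PartialCorrelation(
        r=r, n=n, k_covariates=k, p_two_sided=p, bca_ci=ci, degenerate=degenerate
    )


def _bca_percentiles(z0: float, a: float, alpha: float) -> tuple[float, float]:
    zlo, zhi = sps.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    lo = sps.norm.cdf(z0 + (z0 + zlo) / (1.0 - a * (z0 + zlo)))
    hi = sps.norm.cdf(z0 + (z0 + zhi) / (1.0 - a * (z0 + zhi)))
    return float(lo), float(hi)


def bca_ci(
    stat_fn,
    data,
    n_boot: int = 2000,
    alpha: float = 0.05,
    strata=None,
    seed: int | None = None,
    indices: bool = False,
    force_z0: float | None = None,
    force_accel: float | None = None,
    vectorized: bool = False,
) -> tuple[float, float]:
    """Bias-corrected accelerated bootstrap CI for ``stat_fn`` over ``data``.

    ``data`` is an array of records (resampled along axis 0). With
    ``indices=True`` the statistic receives resampled *row indices* instead,
    which lets callers close over several aligned arrays. ``strata`` (labels
    per row) makes resampling stratified: rows are drawn with replacement
    within each stratum, preserving stratum sizes. A statistic that raises or
    returns NaN on a resample causes that draw to be redrawn; more than 10%
    redraws is an error.

    ``force_z0`` / ``force_accel`` pin the bias-correction and acceleration
    (e.g. both 0 reduces BCa to the plain percentile interval; used for
    self-checks). ``vectorized=True`` promises that ``stat_fn`` accepts a 2-D
    (n_boot, n) resample matrix and returns one statistic per row.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 records to bootstrap")
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    rng = np.random.default_rng(seed)
    rows = np.arange(n)

    def evaluate(idx: np.ndarray) -> float:
        sample = idx if indices else data[idx]
        return float(stat_fn(sample))

    theta_hat = evaluate(rows)

    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape[0] != n:
            raise ValueError("strata labels must align with data rows")
        groups = [rows[strata == s] for s in np.unique(strata)]
    else:
        groups = [rows]

    def draw_indices(size: int) -> np.ndarray:
        # one resample per row of the output; stratified within groups
        out = np.empty((size, n), dtype=int)
        for g in groups:
            out[:, g] = g[rng.integers(0, len(g), size=(size, len(g)))]
        return out

    if vectorized and not indices:
        idx = draw_indices(n_boot)
        boot = np.asarray(stat_fn(data[idx]), dtype=float)
        bad = ~np.isfinite(boot)
        n_redraw = 0
        while bad.any():
            n_redraw += int(bad.sum())
            if n_redraw > 0.1 * n_boot:
                raise RuntimeError("statistic undefined on > 10% of bootstrap resamples")
            idx2 = draw_indices(int(bad.sum()))
            boot[bad] = np.asarray(stat_fn(data[idx2]), dtype=float)
            bad = ~np.isfinite(boot)
    else:
        boot = np.empty(n_boot)
        n_redraw = 0
        all_idx = draw_indices(n_boot)
        for b in range(n_boot):
            idx = all_idx[b]
            while True:
                try:
                    val = evaluate(idx)
                except Exception:
                    val = np.nan
                if np.isfinite(val):
                    break
                n_redraw += 1
                if n_redraw > 0.1 * n_boot:
                    raise RuntimeError("statistic undefined on > 10% of bootstrap resamples")
                idx = draw_indices(1)[0]
            boot[b] = val

    if np.ptp(boot) == 0.0:
        c = float(boot[0])
        return (c, c)

    if force_z0 is not None:
        z0 = float(force_z0)
    else:
        prop = (np.sum(boot < theta_hat) + 0.5 * np.sum(boot == theta_hat)) / n_boot
        prop = float(np.clip(prop, 1.0 / (n_boot + 1), n_boot / (n_boot + 1.0)))
        z0 = float(sps.norm.ppf(prop))

    if force_accel is not None:
        a = float(force_accel)
    else:
        # jackknife acceleration
        if vectorized and not indices:
            jk_idx = np.stack([np.delete(rows, i) for i in range(n)])
            jack = np.asarray(stat_fn(data[jk_idx]), dtype=float)
        else:
            jack = np.empty(n)
            for i in range(n):
                jack[i] = evaluate(np.delete(rows, i))
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
        a = float(num / den) if den > 0 else 0.0

    lo_q, hi_q = _bca_percentiles(z0, a, alpha)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return (float(lo), float(hi))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m); m defaults to the vector length."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, p * m)
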