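"""Tau-PET SUVR construction, scanner-matched smoothing, and positivity masks.

Processing order is fixed: (frame averaging →) SUVR → smoothing → thresholding.
Smoothing before thresholding matters — a smoothed-then-thresholded map is not
the thresholded-then-smoothed one — and the pipeline pins the former.

Scanner-specific anisotropic Gaussian kernels equalise the effective spatial
resolution of the two tomographs:

* PET/CT (Biograph HiRez XVI): FWHM 6.55 x 6.55 x 7.75 mm (x, y, z)
* HRRT: FWHM 7.37 x 7.37 x 7.91 mm

A voxel is tau-positive when its smoothed SUVR is >= 1.30 (comparator
configurable to strict '>'); % positivity of a region is
100 * (positive voxels) / (grey-matter voxels in the region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import ImageVolume, LabelAtlas, assert_same_grid

__all__ = [
    "SmoothingKernel",
    "PETCT_KERNEL",
    "HRRT_KERNEL",
    "SCANNER_KERNELS",
    "PositivityResult",
    "average_frames",
    "compute_suvr",
    "smooth",
    "threshold_positivity",
    "percent_positivity",
    "SUVR_THRESHOLD",
]

SUVR_THRESHOLD = 1.30
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class SmoothingKernel:
    fwhm_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.fwhm_mm) != 3 or any(f <= 0 for f in self.fwhm_mm):
            raise ValueError(f"FWHM must be three positive reals, got {self.fwhm_mm}")

    def sigma_voxels(self, voxel_size_mm: tuple[float, float, float]) -> tuple[float, ...]:
        return tuple(
            f * FWHM_TO_SIGMA / v for f, v in zip(self.fwhm_mm, voxel_size_mm)
        )


PETCT_KERNEL = SmoothingKernel((6.55, 6.55, 7.75))
HRRT_KERNEL = SmoothingKernel((7.37, 7.37, 7.91))
SCANNER_KERNELS = {"PETCT": PETCT_KERNEL, "HRRT": HRRT_KERNEL}


@dataclass
class PositivityResult:
    positive_mask: np.ndarray
    negative_mask: np.ndarray
    threshold: float
    comparator: str
    pct_positive_global: float
    pct_positive_by_region: dict[int, float] = field(default_factory=dict)
    n_missing: int = 0

    def __post_init__(self) -> None:
        if np.any(self.positive_mask & self.negative_mask):
            raise ValueError("positive and negative masks overlap")


def average_frames(
    frames: list[tuple[ImageVolume, float, float]],
    window: tuple[float, float],
    weighted: bool = True,
) -> ImageVolume:
    """Duration-weighted mean of the PET frames overlapping ``window`` (minutes).

    Frames must be sorted and non-overlapping, and must jointly cover the
    window; a gap is a fatal error naming the uncovered interval. With
    ``weighted=False`` the overlapping frames are averaged without duration
    weights.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    if not frames:
        raise ValueError("no frames given")
    prev_end = -np.inf
    for _, s, e in frames:
        if e <= s:
            raise ValueError(f"frame with non-positive duration: [{s}, {e}]")
        if s < prev_end:
            raise ValueError("frames must be sorted and non-overlapping")
        prev_end = e
    # coverage check
    cursor = t0
    for _, s, e in frames:
        if s > cursor and cursor < t1:
            gap_end = min(s, t1)
            if gap_end > cursor:
                raise ValueError(f"window [{t0}, {t1}] not covered: gap [{cursor}, {gap_end}]")
        cursor = max(cursor, min(e, t1))
    if cursor < t1:
        raise ValueError(f"window [{t0}, {t1}] not covered: gap [{cursor}, {t1}]")

    base = frames[0][0]
    contributing: list[tuple[ImageVolume, float]] = []
    for vol, s, e in frames:
        assert_same_grid(base, vol)
        overlap = min(e, t1) - max(s, t0)
        if overlap > 0:
            contributing.append((vol, overlap if weighted else 1.0))
    if len(contributing) == 1:
        return base.with_data(contributing[0][0].data.copy())
    total_w = sum(w for _, w in contributing)
    acc = np.zeros_like(base.data)
    for vol, w in contributing:
        acc += (w / total_w) * vol.data
    return base.with_data(acc)


def compute_suvr(activity: ImageVolume, reference_mask: ImageVolume) -> ImageVolume:
    """Divide every voxel by the mean activity over the reference region."""
    assert_same_grid(activity, reference_mask)
    ref = reference_mask.data > 0.5
    vals = activity.data[ref]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("reference mask is empty (or all-missing)")
    ref_mean = float(vals.mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean activity: {ref_mean}")
    return activity.with_data(activity.data / ref_mean)


def smooth(
    vol: ImageVolume,
    kernel: SmoothingKernel,
    mask: np.ndarray | None = None,
    mode: str = "renormalized",
) -> ImageVolume:
    """Separable Gaussian smoothing with per-axis sigma = FWHM / (vox * sqrt(8 ln 2)).

    ``mode="renormalized"`` (default) renormalises the truncated kernel over
    the in-support voxels (support = finite voxels, intersected with ``mask``
    when given), which avoids edge attenuation near the brain boundary and
    leaves constants exactly constant; voxels outside the support come back
    NaN. ``mode="zero"`` is plain zero-padded convolution (SPM-style).
    """
    sigma = kernel.sigma_voxels(vol.voxel_size_mm)
    data = vol.data
    if mode == "zero":
        filled = np.where(np.isfinite(data), data, 0.0)
        return vol.with_data(ndimage.gaussian_filter(filled, sigma=sigma, mode="constant"))
    if mode != "renormalized":
        raise ValueError(f"unknown smoothing mode {mode!r}")
    support = np.isfinite(data)
    if mask is not None:
        support &= mask > 0.5
    filled = np.where(support, data, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(support.astype(float), sigma=sigma, mode="constant")
    out = np.full_like(filled, np.nan)
    ok = support & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return vol.with_data(out)


def threshold_positivity(
    suvr: ImageVolume,
    gm_mask: np.ndarray,
    threshold: float = SUVR_THRESHOLD,
    comparator: str = "ge",
) -> PositivityResult:
    """Split grey-matter voxels into tau-positive / tau-negative at the threshold.

    Missing (NaN) SUVR voxels inside the grey-matter mask belong to neither
    mask and are counted in ``n_missing``; the two masks partition the finite
    grey-matter voxels.
    """
    gm = np.asarray(gm_mask) > 0.5
    if gm.shape != suvr.shape:
        raise ValueError(f"grid mismatch: suvr {suvr.shape} vs mask {gm.shape}")
    if not gm.any():
        raise ValueError("empty grey-matter mask")
    finite = np.isfinite(suvr.data)
    if comparator == "ge":
        pos = gm & finite & (suvr.data >= threshold)
    elif comparator == "gt":
        pos = gm & finite & (suvr.data > threshold)
    else:
        raise ValueError(f"comparator must be 'ge' or 'gt', got {comparator!r}")
    neg = gm & finite & ~pos
    n_gm_finite = int((gm & finite).sum())
    pct = 100.0 * pos.sum() / n_gm_finite if n_gm_finite else np.nan
    return PositivityResult(
        positive_mask=pos,
        negative_mask=neg,
        threshold=threshold,
        comparator=comparator,
        pct_positive_global=float(pct),
        n_missing=int((gm & ~finite).sum()),
    )


def percent_positivity(
    result: PositivityResult,
    atlas: LabelAtlas | np.ndarray | None = None,
) -> tuple[float, dict[int, float]]:
    """Global and per-region % positivity: 100 * |pos ∩ region| / |GM ∩ region|.

    Regions with no grey-matter voxels get NaN. Also fills
    ``result.pct_positive_by_region`` as a side effect for reporting.
    """
    gm = result.positive_mask | result.negative_mask
    by_region: dict[int, float] = {}
    if atlas is not None:
        labels = atlas.labels if isinstance(atlas, LabelAtlas) else np.asarray(atlas)
        if labels.shape != gm.shape:
            raise ValueError("atlas grid does not match masks")
        for lab in np.unique(labels):
            if lab == 0:
                continue
            region = labels == lab
            denom = int((gm & region).sum())
            by_region[int(lab)] = (
                100.0 * int((result.positive_mask & region).sum()) / denom
                if denom
                else float("nan")
            )
    result.pct_positive_by_region = by_region
    return result.pct_positive_global, by_region
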