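"""Evaluation statistics for the attenuation-correction comparison.

Smoothing, grey-matter masking, global-mean scaling, ROI summary tables,
percent-relative-difference tables, paired t-tests, voxelwise Pearson
correlation within ROIs, and voxelwise two-sample t-maps thresholded by
Benjamini-Hochberg FDR with a cluster-extent criterion (26-connectivity,
clusters strictly greater than the extent threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .image import Image3D, require_same_grid

__all__ = [
    "ClusterRecord", "gaussian_smooth", "gm_mask", "scale_to_global_mean",
    "roi_table", "percent_rd_table", "paired_ttest", "voxelwise_pearson",
    "voxelwise_ttest_clusters",
]

_CONN26 = np.ones((3, 3, 3))


@dataclass(frozen=True)
class ClusterRecord:
    """One suprathreshold cluster from the voxelwise comparison."""

    cluster_size: int
    peak_voxel: tuple
    peak_world_mm: tuple
    peak_t: float
    direction: str              # 'A>B' or 'A<B'


def gaussian_smooth(image: Image3D, fwhm_mm: float = 6.0) -> Image3D:
    """Separable Gaussian smoothing; FWHM in mm is converted per axis to
    sigma = FWHM / 2.355 honoring anisotropic spacing.  fwhm=0 is the
    identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return image.with_data(image.data.copy())
    sigma = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / image.spacing
    return image.with_data(ndimage.gaussian_filter(
        np.asarray(image.data, float), sigma=sigma))


def gm_mask(gm_prob: Image3D, threshold: float = 0.80) -> Image3D:
    """Binary grey-matter mask at strictly > ``threshold`` probability."""
    p = np.asarray(gm_prob.data, float)
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    mask = (p > threshold).astype(np.uint8)
    if not mask.any():
        import warnings
        warnings.warn("grey-matter mask is empty")
    return gm_prob.with_data(mask)


def scale_to_global_mean(image: Image3D, mask: Image3D) -> Image3D:
    """Divide by the mean over the mask; the masked mean of the output is
    exactly 1 (the 'relative image' used for intermodal comparison)."""
    require_same_grid(image, mask)
    m = mask.data > 0
    if not m.any():
        raise ValueError("empty mask")
    mean = float(image.data[m].mean())
    if mean <= 0:
        raise ValueError("nonpositive global mean")
    return image.with_data(np.asarray(image.data, float) / mean)


def roi_table(image: Image3D, atlas: Image3D, code_names: dict) -> pd.DataFrame:
    """Per-ROI mean, SD and voxel count of ``image``.

    Empty ROIs are kept with n = 0 and NaN summaries (flagged, not
    dropped).  Atlas codes without a name are rejected.
    """
    require_same_grid(image, atlas)
    codes = np.unique(atlas.data)
    codes = codes[codes != 0]
    unknown = set(codes.tolist()) - set(code_names)
    if unknown:
        raise ValueError(f"atlas codes without names: {sorted(unknown)}")
    rows = []
    for code, name in sorted(code_names.items()):
        vox = np.asarray(image.data, float)[atlas.data == code]
        rows.append({
            "roi": name,
            "code": code,
            "n": int(vox.size),
            "mean": float(vox.mean()) if vox.size else np.nan,
            "sd": float(vox.std(ddof=1)) if vox.size > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("roi")


def percent_rd_table(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI percent relative difference 100 (mean_a - mean_b) / mean_b.

    Rows whose denominator mean is zero (or missing) carry NaN and are
    flagged in the 'valid' column.
    """
    if not table_a.index.equals(table_b.index):
        raise ValueError("ROI keys do not match")
    a = table_a["mean"]
    b = table_b["mean"]
    valid = b.notna() & (b != 0) & a.notna()
    rd = pd.Series(np.nan, index=table_a.index)
    rd[valid] = 100.0 * (a[valid] - b[valid]) / b[valid]
    return pd.DataFrame({"percent_rd": rd, "valid": valid,
                         "n": table_a["n"]})


def paired_ttest(x, y):
    """Classical paired t-test (two-sided, df = n - 1).

    Rejects zero-variance differences rather than reporting an infinite
    statistic.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def voxelwise_pearson(image_a: Image3D, image_b: Image3D,
                      roi_mask: Image3D):
    """Pearson correlation across masked voxels of two images.

    Returns (r, two-sided p, n_voxels).  Requires >= 3 voxels and nonzero
    variance in both images.
    """
    require_same_grid(image_a, image_b, roi_mask)
    m = roi_mask.data > 0
    a = np.asarray(image_a.data, float)[m]
    b = np.asarray(image_b.data, float)[m]
    if a.size < 3:
        raise ValueError("need at least 3 voxels in the ROI mask")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance within the ROI mask")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p), int(a.size)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at level q (independence
    variant)."""
    reject, _, _, _ = multipletests(np.asarray(pvals, float),
                                    alpha=q, method="fdr_bh")
    return reject


def _two_sample_t(a_stack: np.ndarray, b_stack: np.ndarray):
    """Pooled-variance two-sample t per voxel; returns (t, p, df)."""
    na, nb = a_stack.shape[0], b_stack.shape[0]
    ma, mb = a_stack.mean(axis=0), b_stack.mean(axis=0)
    va = a_stack.var(axis=0, ddof=1)
    vb = b_stack.var(axis=0, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    t[~np.isfinite(t)] = 0.0
    p = 2.0 * sps.t.sf(np.abs(t), df=df)
    return t, p, df


def voxelwise_ttest_clusters(
    group_a,
    group_b,
    mask: Image3D,
    q: float = 0.05,
    min_cluster: int = 50,
):
    """Voxelwise two-sample comparison with FDR and cluster extent.

    Pooled-variance t per masked voxel, Benjamini-Hochberg over the
    masked p-values at level ``q``, 26-connected clustering of the
    surviving voxels, and reporting of clusters strictly larger than
    ``min_cluster`` voxels, separately for each sign of the effect.

    Returns (t_map as Image3D with NaN outside the mask, list of
    :class:`ClusterRecord` sorted by decreasing size).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 images")
    ref = group_a[0]
    for im in list(group_a) + list(group_b) + [mask]:
        require_same_grid(ref, im)
    m = mask.data > 0
    a_stack = np.stack([im.data for im in group_a])
    b_stack = np.stack([im.data for im in group_b])
    t, p, _ = _two_sample_t(a_stack, b_stack)

    t_map = np.full(ref.shape, np.nan)
    t_map[m] = t[m]
    reject = np.zeros(ref.shape, bool)
    reject[m] = bh_fdr(p[m], q=q)

    records = []
    for direction, sel in (("A>B", reject & (t > 0)), ("A<B", reject & (t < 0))):
        labels, ncl = ndimage.label(sel, structure=_CONN26)
        for lbl in range(1, ncl + 1):
            where = labels == lbl
            size = int(where.sum())
            if size <= min_cluster:
                continue
            tt = np.where(where, np.abs(t), -np.inf)
            peak = np.unravel_index(np.argmax(tt), tt.shape)
            records.append(ClusterRecord(
                cluster_size=size,
                peak_voxel=tuple(int(i) for i in peak),
                peak_world_mm=tuple(float(v)
                                    for v in ref.voxel_to_world(peak)[0]),
                peak_t=float(t[peak]),
                direction=direction,
            ))
    records.sort(key=lambda r: -r.cluster_size)
    return ref.with_data(t_map), records
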