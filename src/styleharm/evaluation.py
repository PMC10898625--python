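"""Quantitative evaluation of harmonization quality.

Covers the four families of measures used to validate harmonization:

* paired-image fidelity -- MAE, PSNR and a multi-scale structural similarity
  score, computed against ground-truth target renderings of the same anatomy
  (the synthetic traveling-phantom protocol);
* distributional quality -- FID (Frechet distance between Gaussian fits of
  feature embeddings) and KID (unbiased polynomial-kernel MMD^2), computed at
  the slice level with a pluggable embedding whose default is a fixed, seeded,
  untrained convolutional feature extractor (deterministic and download-free;
  relative comparisons are what matters here);
* segmentation consistency -- Dice overlap of tissue classes from an internal
  phantom segmenter (background by Otsu threshold + largest connected
  component, tissues by deterministic quantile-initialized 3-means on
  foreground intensities, labels in ascending mean-intensity order);
* tissue-volume distributions across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure
from skimage.metrics import structural_similarity
from skimage.transform import downscale_local_mean

from ._autodiff import conv2d_forward
from .errors import (InvalidArgumentError, SegmentationDegenerateError,
                     ShapeError)

__all__ = [
    "MetricReport", "EmbeddingModel", "mae", "psnr", "ms_ssim", "dsc",
    "segment_phantom", "fid", "kid", "volumetric_distributions",
    "edge_transition_width",
]

# MS-SSIM per-scale exponents (standard 5-scale weights, truncated and
# renormalized when the image only supports fewer dyadic scales).
_MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class MetricReport:
    """A flat collection of metric rows with grouping keys."""

    rows: list[dict] = field(default_factory=list)

    def add(self, metric: str, value: float, n_samples: int,
            dispersion: float = float("nan"), **keys) -> None:
        if n_samples < 1:
            raise InvalidArgumentError("n_samples must be >= 1")
        self.rows.append({"metric": metric, "value": float(value),
                          "n_samples": int(n_samples),
                          "dispersion": float(dispersion), **keys})

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def _check_pair(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch {x.shape} vs {y.shape}")
    return x, y


def mae(x, y) -> float:
    """Mean absolute error."""
    x, y = _check_pair(x, y)
    return float(np.mean(np.abs(x - y)))


def psnr(x, y, peak: float = 2.0, cap: float = 100.0) -> float:
    """Peak signal-to-noise ratio in dB (capped when MSE = 0)."""
    x, y = _check_pair(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float(cap)
    return float(min(cap, 10.0 * np.log10(peak * peak / mse)))


def ms_ssim(x, y, data_range: float = 2.0) -> float:
    """Multi-scale structural similarity in [0, 1].

    Computed as a weighted geometric mean of single-scale SSIM over dyadic
    scales (2x average-pool between scales); the number of scales adapts to
    the image size so the 7x7 SSIM window always fits.  Negative per-scale
    values are clipped at 0.
    """
    x, y = _check_pair(x, y)
    if x.ndim != 2:
        raise ShapeError("ms_ssim expects 2-D images")
    n_scales = 1
    m = min(x.shape)
    # the Gaussian SSIM window is 11 px; keep every scale at least that big
    while n_scales < len(_MSSSIM_WEIGHTS) and m // 2 >= 11:
        n_scales += 1
        m //= 2
    w = np.array(_MSSSIM_WEIGHTS[:n_scales])
    w = w / w.sum()
    vals = []
    cx, cy = x, y
    for s in range(n_scales):
        v = structural_similarity(cx, cy, data_range=data_range,
                                  gaussian_weights=True, sigma=1.5,
                                  use_sample_covariance=False)
        vals.append(max(0.0, float(v)))
        if s + 1 < n_scales:
            cx = downscale_local_mean(cx, (2, 2))
            cy = downscale_local_mean(cy, (2, 2))
    return float(np.prod(np.asarray(vals) ** w))


def dsc(mask_a, mask_b, class_id: int) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|); 1.0 when both sets are empty."""
    a = np.asarray(mask_a) == class_id
    b = np.asarray(mask_b) == class_id
    if a.shape != b.shape:
        raise ShapeError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


# -- internal phantom segmenter ----------------------------------------------

def _kmeans_1d(values: np.ndarray, k: int, iters: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means: quantile init, Lloyd iterations.

    Scale- and shift-equivariant, so label order is invariant to positive
    rescaling of the image.
    """
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(values, qs)
    for _ in range(iters):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array([values[assign == c].mean() if np.any(assign == c)
                        else centers[c] for c in range(k)])
        if np.allclose(new, centers, rtol=0, atol=1e-12):
            break
        centers = new
    return np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)


def segment_phantom(image: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Tissue segmentation of a rendered phantom (stand-in for external
    brain-extraction + tissue-segmentation tools).

    Background is split off by Otsu threshold and restricted to the largest
    foreground connected component; foreground intensities are clustered into
    ``n_classes`` tissue classes relabeled in ascending mean-intensity order
    (1 = darkest tissue).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ShapeError("segment_phantom expects a single-channel 2-D image")
    if np.ptp(img) == 0:
        raise SegmentationDegenerateError("constant image cannot be segmented")
    # intensity floor: lowest of (n_classes + 1) intensity clusters is
    # background (scale/shift invariant, unlike a fixed threshold)
    assign_all = _kmeans_1d(img.ravel(), n_classes + 1)
    centers = [img.ravel()[assign_all == c].mean()
               if np.any(assign_all == c) else np.inf
               for c in range(n_classes + 1)]
    bg_cluster = int(np.argmin(centers))
    fg = (assign_all != bg_cluster).reshape(img.shape)
    if not fg.any() or fg.all():
        raise SegmentationDegenerateError("no background/foreground split")
    lab = measure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    fg = lab == largest
    out = np.zeros(img.shape, dtype=np.uint8)
    vals = img[fg]
    assign = _kmeans_1d(vals, n_classes)
    order = np.argsort([vals[assign == c].mean() for c in range(n_classes)])
    relabel = np.empty(n_classes, dtype=np.uint8)
    relabel[order] = np.arange(1, n_classes + 1)
    out[fg] = relabel[assign]
    return out


# -- distributional metrics ---------------------------------------------------

class EmbeddingModel:
    """A fixed, seeded, untrained convolutional image embedding.

    Three stride-2 random convolutions with ReLU, followed by global average
    and standard-deviation pooling of the last feature maps.  Identical
    inputs map to identical features; construction is deterministic in
    ``seed``.  A pretrained feature extractor can be substituted anywhere a
    callable ``(N, H, W) -> (N, d_f)`` is accepted.
    """

    def __init__(self, seed: int = 0, widths: tuple[int, ...] = (8, 16, 32)):
        rng = np.random.default_rng(seed)
        self.weights = []
        c = 1
        for f in widths:
            w = rng.standard_normal((f, c, 3, 3)) * np.sqrt(2.0 / (c * 9))
            self.weights.append(w.astype(np.float32))
            c = f
        self.d_f = 2 * widths[-1]

    def __call__(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ShapeError("embedding expects (N, H, W) images")
        h = x[:, None]
        for w in self.weights:
            h, _, _ = conv2d_forward(h, w, None, stride=2, pad=1)
            h = np.maximum(h, 0.0)
        return np.concatenate([h.mean(axis=(2, 3)), h.std(axis=(2, 3))],
                              axis=1)


def _sqrtm_psd(m: np.ndarray) -> np.ndarray:
    """Symmetric PSD matrix square root via eigendecomposition, clipping
    negative eigenvalues at zero (stabilizes near-singular covariances)."""
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Frechet distance between Gaussian fits of two feature sets."""
    a = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("fid needs >= 2 feature vectors per set")
    mu_a, mu_b = a.mean(0), b.mean(0)
    ca = np.cov(a, rowvar=False)
    cb = np.cov(b, rowvar=False)
    ca = np.atleast_2d(ca)
    cb = np.atleast_2d(cb)
    sa = _sqrtm_psd(ca)
    cross = _sqrtm_psd(sa @ cb @ sa)
    d2 = float(np.sum((mu_a - mu_b) ** 2)
               + np.trace(ca) + np.trace(cb) - 2.0 * np.trace(cross))
    return max(0.0, d2)


def kid(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Unbiased MMD^2 with the degree-3 polynomial kernel (x.y/d + 1)^3."""
    a = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("kid needs >= 2 feature vectors per set")
    d = a.shape[1]

    def k(x, y):
        return (x @ y.T / d + 1.0) ** 3

    m, n = len(a), len(b)
    kaa = k(a, a)
    kbb = k(b, b)
    kab = k(a, b)
    term_a = (kaa.sum() - np.trace(kaa)) / (m * (m - 1))
    term_b = (kbb.sum() - np.trace(kbb)) / (n * (n - 1))
    return float(term_a + term_b - 2.0 * kab.mean())


def volumetric_distributions(masks_by_group: dict[object, list[np.ndarray]],
                             voxel_volume: float = 1.0,
                             classes: tuple[int, ...] = (1, 2, 3)
                             ) -> MetricReport:
    """Per-class tissue volumes per group, plus pairwise two-sample
    Kolmogorov-Smirnov statistics between groups."""
    if any(len(v) == 0 for v in masks_by_group.values()) or not masks_by_group:
        raise InvalidArgumentError("every group needs at least one mask")
    report = MetricReport()
    vols: dict[object, dict[int, np.ndarray]] = {}
    for g, masks in masks_by_group.items():
        vols[g] = {}
        for c in classes:
            v = np.array([float((np.asarray(m) == c).sum()) * voxel_volume
                          for m in masks])
            vols[g][c] = v
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            report.add("volume_median", med, len(v), dispersion=q3 - q1,
                       group=g, class_id=c)
    groups = list(masks_by_group)
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            for c in classes:
                va, vb = vols[groups[gi]][c], vols[groups[gj]][c]
                if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
                    stat, p = 0.0, 1.0
                else:
                    res = stats.ks_2samp(va, vb)
                    stat, p = float(res.statistic), float(res.pvalue)
                report.add("volume_ks", stat, len(va) + len(vb), dispersion=p,
                           group=f"{groups[gi]}|{groups[gj]}", class_id=c)
    return report


# -- sharpness ----------------------------------------------------------------

def edge_transition_width(image: np.ndarray, n_profiles: int = 4) -> float:
    """Mean 10-90% transition width (pixels) of the object's outer edge.

    Profiles are taken through the image center along both axes; for each,
    the steepest edge on each side is located and the distance between the
    10% and 90% crossing points of the local level swing is measured by
    linear interpolation.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ShapeError("edge_transition_width expects a 2-D image")
    h, w = img.shape
    profiles = [img[h // 2, :], img[:, w // 2]][:max(1, n_profiles // 2)]
    widths = []
    for prof in profiles:
        grad = np.abs(np.diff(prof))
        half = len(grad) // 2
        for lo, hi in ((0, half), (half, len(grad))):
            if np.all(grad[lo:hi] == 0):
                continue
            e = lo + int(np.argmax(grad[lo:hi]))
            width = _edge_width_at(prof, e)
            if width is not None:
                widths.append(width)
    if not widths:
        raise InvalidArgumentError("no measurable edge found")
    return float(np.mean(widths))


def _edge_width_at(prof: np.ndarray, e: int, win: int = 6) -> float | None:
    """10-90% equivalent width of the transition at gradient index e.

    Estimated as ``0.8 * swing / max_slope``: exact (0.8 px) for an ideal
    step and proportional to the blur scale for smoothed edges, while being
    robust to short plateaus between neighbouring tissue transitions.
    """
    lo_win = prof[max(0, e - win):e + 1]
    hi_win = prof[e + 1:e + 2 + win]
    if len(lo_win) < 2 or len(hi_win) < 2:
        return None
    seg_lo, seg_hi = (lo_win, hi_win) if prof[e + 1] >= prof[e] else \
        (-lo_win, -hi_win)
    lo = np.percentile(seg_lo, 15)
    hi = np.percentile(seg_hi, 85)
    swing = hi - lo
    slope = abs(prof[e + 1] - prof[e])
    if swing <= 0 or slope == 0:
        return None
    return float(0.8 * swing / slope)
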