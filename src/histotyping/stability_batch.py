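"""Cross-site feature-stability filtering, image-quality metrics and the
UMAP batch-effect audit.

Stability filtering runs on features extracted from *benign* (non-
cancerous) regions of each contributing site: a feature whose benign
distribution differs between any two sites reflects pre-analytic batch
variation (stain, scanner) rather than biology and is dropped before
model training.  The divergence statistic is the two-sample
Kolmogorov-Smirnov distance, which is rank-based (invariant to monotone
per-feature rescaling) and sample-size robust; the default threshold is
tau = 0.4 on the maximum pairwise-site KS.

The 29 image-quality metrics summarize brightness, contrast, color
distribution and stain intensities of an RGB region image and serve as
the "how the image looks" feature space of the UMAP audit: if sites
cluster in the embedding of these metrics but not in the embedding of the
model's features, the model features are robust to the batch effects that
are plainly present in the pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from skimage.color import rgb2gray, rgb2hed, rgb2hsv
from skimage.filters import laplace, sobel

from .io_core import RegionImage, ValidationError

logger = logging.getLogger("histotyping")

IMAGE_METRIC_NAMES: tuple[str, ...] = (
    # brightness / contrast (5)
    "gray_mean",
    "gray_sd",
    "rms_contrast",
    "michelson_contrast",
    "gray_entropy",
    # RGB channels (6)
    "red_mean",
    "red_sd",
    "green_mean",
    "green_sd",
    "blue_mean",
    "blue_sd",
    # HSV color distribution (6)
    "hue_circ_mean",
    "hue_circ_sd",
    "saturation_mean",
    "saturation_sd",
    "value_mean",
    "value_sd",
    # stain deconvolution (7)
    "hematoxylin_mean",
    "hematoxylin_sd",
    "hematoxylin_fraction",
    "eosin_mean",
    "eosin_sd",
    "eosin_fraction",
    "residual_mean",
    # structure / quality (5)
    "edge_density",
    "laplacian_variance",
    "tissue_fraction",
    "background_fraction",
    "saturated_white_fraction",
)

_STAIN_POSITIVE_THRESHOLD = 0.05  # optical-density units after deconvolution
_EDGE_THRESHOLD = 0.05
_BACKGROUND_LUMINANCE = 0.9
_SATURATED_WHITE = 250 / 255


def image_metrics(img: RegionImage) -> dict[str, float]:
    """The 29 image-quality metrics of an RGB region image (deterministic)."""
    pixels = np.asarray(img.pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValidationError("image_metrics requires an RGB image")
    rgb = pixels.astype(float) / 255.0
    gray = rgb2gray(rgb)

    out: dict[str, float] = {}
    out["gray_mean"] = float(gray.mean())
    out["gray_sd"] = float(gray.std())
    out["rms_contrast"] = float(gray.std())
    gmin, gmax = float(gray.min()), float(gray.max())
    out["michelson_contrast"] = (
        (gmax - gmin) / (gmax + gmin) if gmax + gmin > 0 else 0.0
    )
    hist, _ = np.histogram(gray, bins=64, range=(0, 1))
    p = hist / hist.sum()
    out["gray_entropy"] = float(-np.sum(np.where(p > 0, p * np.log2(p), 0.0)))

    for c, name in enumerate(("red", "green", "blue")):
        out[f"{name}_mean"] = float(rgb[..., c].mean())
        out[f"{name}_sd"] = float(rgb[..., c].std())

    hsv = rgb2hsv(rgb)
    ang = hsv[..., 0] * 2 * np.pi
    C = np.mean(np.cos(ang))
    S = np.mean(np.sin(ang))
    R = float(np.hypot(C, S))
    out["hue_circ_mean"] = float(np.arctan2(S, C) % (2 * np.pi) / (2 * np.pi))
    out["hue_circ_sd"] = float(np.sqrt(max(0.0, -2.0 * np.log(max(R, 1e-12)))))
    out["saturation_mean"] = float(hsv[..., 1].mean())
    out["saturation_sd"] = float(hsv[..., 1].std())
    out["value_mean"] = float(hsv[..., 2].mean())
    out["value_sd"] = float(hsv[..., 2].std())

    hed = rgb2hed(rgb)
    for c, name in enumerate(("hematoxylin", "eosin")):
        ch = hed[..., c]
        out[f"{name}_mean"] = float(ch.mean())
        out[f"{name}_sd"] = float(ch.std())
        out[f"{name}_fraction"] = float(np.mean(ch > _STAIN_POSITIVE_THRESHOLD))
    out["residual_mean"] = float(hed[..., 2].mean())

    out["edge_density"] = float(np.mean(sobel(gray) > _EDGE_THRESHOLD))
    out["laplacian_variance"] = float(laplace(gray).var())
    tissue = (hsv[..., 1] > 0.1) & (hsv[..., 2] < 0.95)
    out["tissue_fraction"] = float(tissue.mean())
    out["background_fraction"] = float(np.mean(gray >= _BACKGROUND_LUMINANCE))
    out["saturated_white_fraction"] = float(np.mean(np.all(rgb >= _SATURATED_WHITE, axis=-1)))
    assert len(out) == 29
    return out


# ---------------------------------------------------------------------------
# Stability filtering
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Per-feature stability decisions across contributing sites."""

    statistics: pd.DataFrame  # index: feature, column: max_pairwise_ks
    keep: list[str]
    drop: list[str]
    sites: list[str]
    threshold: float

    def kept_mask(self) -> pd.Series:
        return pd.Series(
            [f in set(self.keep) for f in self.statistics.index],
            index=self.statistics.index,
        )


def stability_filter(
    benign_features: pd.DataFrame,
    site_labels: pd.Series | np.ndarray,
    threshold: float = 0.4,
    min_regions_per_site: int = 10,
) -> StabilityReport:
    """Drop features whose benign-region distributions differ across sites.

    For each feature the two-sample KS statistic is computed for every
    pair of usable sites (those with >= ``min_regions_per_site`` regions);
    a feature is dropped when the maximum pairwise KS exceeds
    ``threshold``.  NaN feature values are excluded pairwise.
    """
    site_labels = pd.Series(np.asarray(site_labels), index=benign_features.index)
    counts = site_labels.value_counts()
    usable = [s for s in counts.index if counts[s] >= min_regions_per_site]
    for s in counts.index:
        if s not in usable:
            logger.warning(
                "site %r has %d < %d regions; excluded from stability filtering",
                s, int(counts[s]), min_regions_per_site,
            )
    if len(usable) < 2:
        raise ValidationError("stability filtering requires >= 2 usable sites")

    max_ks = {}
    for feat in benign_features.columns:
        worst = 0.0
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                a = benign_features.loc[site_labels == usable[i], feat].dropna()
                b = benign_features.loc[site_labels == usable[j], feat].dropna()
                if len(a) == 0 or len(b) == 0:
                    continue
                worst = max(worst, float(ks_2samp(a, b).statistic))
        max_ks[feat] = worst
    stats = pd.DataFrame({"max_pairwise_ks": pd.Series(max_ks)})
    drop = [f for f, v in max_ks.items() if v > threshold]
    keep = [f for f in benign_features.columns if f not in set(drop)]
    if not keep:
        raise ValidationError("stability filtering dropped every feature")
    return StabilityReport(
        statistics=stats, keep=keep, drop=drop, sites=list(usable),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# UMAP batch-effect audit
# ---------------------------------------------------------------------------

def umap_audit(
    matrix: pd.DataFrame | np.ndarray,
    site_labels: pd.Series | np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> tuple[np.ndarray, float]:
    """2-D UMAP embedding plus a site-mixing score.

    The mixing score is the mean silhouette of the site labels in the
    embedding: high values mean the sites form separate clusters (batch
    effect); values near zero or negative mean good mixing.  The
    embedding is deterministic for a fixed seed.
    """
    from sklearn.metrics import silhouette_score
    from sklearn.preprocessing import StandardScaler
    from umap import UMAP

    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(site_labels)
    if X.shape[0] < 20:
        raise ValidationError("umap_audit requires n >= 20")
    if np.allclose(X.std(axis=0), 0):
        raise ValidationError("constant feature matrix")
    keep = X.std(axis=0) > 0
    Xz = StandardScaler().fit_transform(X[:, keep])
    emb = UMAP(
        n_components=2, n_neighbors=min(n_neighbors, X.shape[0] - 1),
        min_dist=min_dist, metric="euclidean", random_state=seed,
    ).fit_transform(Xz)
    score = float(silhouette_score(emb, labels)) if len(set(labels.tolist())) > 1 else 0.0
    return np.asarray(emb), score
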