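"""Stage-2 classification: canopy pixels into green, yellow and brown.

A second k-means runs on the RGB triples of the masked canopy (optionally on
HSV coordinates) and the resulting clusters are recoded to the three
agronomic color classes.  The recoding is automated by centroid hue: a green
cluster sits around 120 deg, a chlorotic (yellow) cluster around 60 deg, and
necrotic/brown material at low hue and value.  An explicit cluster->label
mapping can override the hue rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv

from idcpheno.io import GeoTransform, RgbRaster
from idcpheno.segmentation import CanopyMask, KMeansModel, kmeans_cluster

logger = logging.getLogger(__name__)

NON_PLANT, GREEN, YELLOW, BROWN = 0, 1, 2, 3
LABEL_NAMES = {NON_PLANT: "non_plant", GREEN: "green", YELLOW: "yellow", BROWN: "brown"}

# hue boundaries (degrees): [40, 75) yellow, [75, 170) green, else brown
HUE_YELLOW_MIN = 40.0
HUE_GREEN_MIN = 75.0
HUE_GREEN_MAX = 170.0


@dataclass
class ColorClassRaster:
    """Integer grid {0 non-plant, 1 green, 2 yellow, 3 brown} + provenance."""

    labels: np.ndarray  # uint8 (rows, cols)
    transform: GeoTransform
    crs: str | None = None
    provenance: dict = field(default_factory=dict)


def centroid_hue_value(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hue (degrees, [0, 360)) and value (max channel / 255) per RGB centroid."""
    c = np.atleast_2d(np.asarray(centroids, dtype=np.float64))
    hsv = rgb_to_hsv(np.clip(c / 255.0, 0.0, 1.0))
    return hsv[:, 0] * 360.0, hsv[:, 2]


def label_clusters_by_hue(centroids: np.ndarray) -> list[int]:
    """Assign green/yellow/brown to RGB centroids by hue.

    Green for hue in [75, 170); yellow for hue in [40, 75); brown otherwise,
    which captures low-hue reds/oranges and dark necrotic material.
    """
    hue, _value = centroid_hue_value(centroids)
    out = []
    for h in hue:
        if HUE_GREEN_MIN <= h < HUE_GREEN_MAX:
            out.append(GREEN)
        elif HUE_YELLOW_MIN <= h < HUE_GREEN_MIN:
            out.append(YELLOW)
        else:
            out.append(BROWN)
    return out


def classify_canopy_colors(
    raster: RgbRaster,
    mask: CanopyMask,
    k: int = 3,
    seed: int = 0,
    mapping: dict[int, int] | None = None,
    feature_space: str = "rgb",
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[ColorClassRaster, KMeansModel]:
    """Cluster canopy pixels and recode clusters to green/yellow/brown.

    Parameters
    ----------
    raster, mask
        The orthomosaic and its plant/soil mask (must be aligned).
    k
        Number of clusters, >= 3.  With k > 3, clusters sharing a hue label
        are merged, which is more robust when lighting varies within a class.
    mapping
        Optional explicit cluster-id -> label (1 green, 2 yellow, 3 brown)
        override of the hue rule.
    feature_space
        "rgb" (default) clusters raw triples; "hsv" clusters HSV coordinates
        scaled to comparable ranges.
    """
    if mask.mask.shape != raster.shape:
        raise ValueError("mask and raster shapes differ")
    if k < 3:
        raise ValueError(f"k must be >= 3 for three color classes, got {k}")
    canopy = mask.mask.astype(bool)
    n_canopy = int(canopy.sum())
    if n_canopy == 0:
        raise ValueError("canopy empty: mask contains no plant pixels")
    rgb = raster.pixels[canopy].astype(np.float64)
    if feature_space == "rgb":
        feats = rgb
    elif feature_space == "hsv":
        hsv = rgb_to_hsv(rgb / 255.0)
        feats = hsv * np.array([360.0, 100.0, 100.0])
    else:
        raise ValueError(f"unknown feature_space {feature_space!r}")

    model, clusters = kmeans_cluster(feats, k=k, seed=seed, max_iter=max_iter,
                                     tol=tol, n_init=3)
    if feature_space == "rgb":
        rgb_centroids = np.asarray(model.centroids)
    else:
        # recover mean RGB per cluster for the hue rule
        rgb_centroids = np.vstack(
            [rgb[clusters == j].mean(axis=0) if (clusters == j).any()
             else np.zeros(3) for j in range(k)]
        )

    if mapping is not None:
        missing = [j for j in range(k) if j not in mapping]
        if missing:
            raise ValueError(f"explicit mapping missing cluster ids {missing}")
        cluster_labels = [int(mapping[j]) for j in range(k)]
        if any(l not in (GREEN, YELLOW, BROWN) for l in cluster_labels):
            raise ValueError("mapping values must be 1 (green), 2 (yellow) or 3 (brown)")
        rule = "explicit"
    else:
        cluster_labels = label_clusters_by_hue(rgb_centroids)
        rule = "hue"

    labels = np.zeros(raster.shape, dtype=np.uint8)
    flat = np.asarray(cluster_labels, dtype=np.uint8)[clusters]
    labels[canopy] = flat
    prov = {
        "rule": rule,
        "k": k,
        "feature_space": feature_space,
        "centroids_rgb": rgb_centroids.tolist(),
        "cluster_labels": {int(j): LABEL_NAMES[cluster_labels[j]] for j in range(k)},
        "hue_bounds_deg": [HUE_YELLOW_MIN, HUE_GREEN_MIN, HUE_GREEN_MAX],
        "n_canopy": n_canopy,
    }
    return ColorClassRaster(labels=labels, transform=raster.transform,
                            crs=raster.crs, provenance=prov), model
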