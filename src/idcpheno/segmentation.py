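"""Stage-1 canopy segmentation: red/green index, k-means, plant/soil recode.

The segmentation mirrors the classical unsupervised workflow: a single-band
index image of (R-G)/(R+G) is clustered into ``k`` spectral classes with
k-means, and the classes are then recoded into a binary plant/soil mask —
either by an explicit user-supplied mapping (the field-practice analogue of
grouping classes by eye) or automatically by thresholding the cluster
centroids at index 0 (green vegetation has G > R, hence a negative index).

The k-means here is a deterministic Lloyd's algorithm: the first centroid is
a seed-selected data point and the remaining centroids are placed by
farthest-point traversal, so a fixed seed yields a fixed model.  An empty
cluster arising during iteration is re-seeded at the point farthest from its
currently assigned centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from idcpheno.io import GeoTransform, RgbRaster

logger = logging.getLogger(__name__)

#: Centroid-index level above which an automatic "plant" assignment is
#: considered spectrally suspicious (chlorotic/necrotic canopy resembles soil).
_PLANT_CENTROID_WARN = -0.02


@dataclass
class IndexRaster:
    """Single-band (R-G)/(R+G) index grid sharing the source georeferencing."""

    values: np.ndarray  # float64 (rows, cols)
    transform: GeoTransform
    crs: str | None = None
    n_degenerate: int = 0  # pixels with R+G == 0, set to 0 by convention


@dataclass
class KMeansModel:
    """Fitted k-means clustering (1-D index values or RGB triples)."""

    k: int
    centroids: np.ndarray  # (k,) or (k, d)
    inertia: float  # within-cluster sum of squares
    n_iter: int
    seed: int


@dataclass
class CanopyMask:
    """Binary plant(1)/soil(0) grid with the cluster->class mapping used."""

    mask: np.ndarray  # uint8 (rows, cols)
    transform: GeoTransform
    crs: str | None = None
    provenance: dict = field(default_factory=dict)


def compute_rg_index(raster: RgbRaster) -> IndexRaster:
    """Per-pixel (R - G) / (R + G) on 8-bit digital numbers.

    Pixels with R + G = 0 are set to 0 and tallied in ``n_degenerate``.
    Finite values lie in [-1, 1]; the index is negative for green vegetation.
    """
    r = raster.pixels[:, :, 0].astype(np.float64)
    g = raster.pixels[:, :, 1].astype(np.float64)
    denom = r + g
    degenerate = denom == 0
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info("compute_rg_index: %d pixels with R+G=0 set to 0", n_degenerate)
    denom[degenerate] = 1.0
    values = (r - g) / denom
    values[degenerate] = 0.0
    return IndexRaster(
        values=values,
        transform=raster.transform,
        crs=raster.crs,
        n_degenerate=n_degenerate,
    )


def _farthest_point_init(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    """First centroid: seed-selected point; then greedy farthest-point picks."""
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]), dtype=np.float64)
    centroids[0] = x[rng.integers(n)]
    d2 = ((x - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        centroids[j] = x[int(np.argmax(d2))]
        d2 = np.minimum(d2, ((x - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _lloyd(x: np.ndarray, k: int, init_seed: int, max_iter: int, tol: float):
    centroids = _farthest_point_init(x, k, init_seed)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        new_centroids = centroids.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centroids[j] = x[members].mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its
                # currently assigned centroid
                per_point = d2[np.arange(len(x)), labels]
                new_centroids[j] = x[int(np.argmax(per_point))]
        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(len(x)), labels].sum())
    return centroids, labels, inertia, n_iter


def kmeans_cluster(
    values: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 10,
) -> tuple[KMeansModel, np.ndarray]:
    """Lloyd's k-means on scalar values or d-dimensional points.

    Parameters
    ----------
    values
        Array of shape (n,) or (n, d).
    k
        Number of clusters, >= 2; requires at least ``k`` distinct points.
    seed
        Selects the initial centroid of each restart; the rest of the
        initialisation is the deterministic farthest-point rule, so a fixed
        seed yields a fixed model.
    max_iter, tol
        Iterate until the largest centroid movement drops below ``tol`` or
        ``max_iter`` sweeps have run.
    n_init
        Number of deterministic restarts (sub-seeds ``seed .. seed+n_init-1``);
        the run with the lowest within-cluster sum of squares wins, which
        guards against poor local optima of a single Lloyd descent.

    Returns
    -------
    (model, labels) where ``labels`` assigns each input point to a cluster
    ordered by ascending centroid (first coordinate), so cluster ids are
    stable across runs.
    """
    x = np.asarray(values, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("values must be (n,) or (n, d)")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    n_distinct = np.unique(x, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"need at least k={k} distinct values, found {n_distinct}"
        )

    best = None
    for i in range(n_init):
        result = _lloyd(x, k, seed + i, max_iter, tol)
        if best is None or result[2] < best[2] - 1e-12:
            best = result
    centroids, labels, _, n_iter = best
    # canonical ordering: ascending first coordinate of the centroid
    order = np.argsort(centroids[:, 0], kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    centroids = centroids[order]
    labels = remap[labels]
    inertia = float(((x - centroids[labels]) ** 2).sum())
    model = KMeansModel(
        k=k,
        centroids=centroids[:, 0] if squeeze else centroids,
        inertia=inertia,
        n_iter=n_iter,
        seed=seed,
    )
    return model, labels


def recode_to_plant_soil(
    model: KMeansModel,
    labels: np.ndarray,
    transform: GeoTransform,
    crs: str | None = None,
    mapping: dict[int, str] | None = None,
    threshold: float = 0.0,
) -> CanopyMask:
    """Recode index clusters into a binary plant/soil mask.

    ``mapping`` maps every cluster id to ``"plant"`` or ``"soil"`` explicitly
    (the analogue of grouping the classes by human observation).  Without a
    mapping, clusters whose centroid index is below ``threshold`` (default 0)
    become plant.  A warning is logged when an automatic plant assignment
    has a centroid above -0.02, since stressed canopy and soil overlap
    spectrally there.
    """
    centroids = np.atleast_1d(np.asarray(model.centroids, dtype=float))
    if centroids.ndim > 1:
        centroids = centroids[:, 0]
    if mapping is not None:
        missing = [j for j in range(model.k) if j not in mapping]
        if missing:
            raise ValueError(f"explicit mapping missing cluster ids {missing}")
        bad = {j: v for j, v in mapping.items() if v not in ("plant", "soil")}
        if bad:
            raise ValueError(f"mapping values must be 'plant' or 'soil': {bad}")
        plant_clusters = [j for j in range(model.k) if mapping[j] == "plant"]
        rule = {"rule": "explicit", "mapping": {int(j): mapping[j] for j in mapping}}
    else:
        plant_clusters = [j for j in range(model.k) if centroids[j] < threshold]
        rule = {
            "rule": "centroid-threshold",
            "threshold": threshold,
            "mapping": {
                int(j): ("plant" if j in plant_clusters else "soil")
                for j in range(model.k)
            },
        }
        for j in plant_clusters:
            if centroids[j] > _PLANT_CENTROID_WARN:
                logger.warning(
                    "cluster %d assigned to plant with centroid index %.4f "
                    "close to the soil boundary; consider an explicit mapping",
                    j,
                    centroids[j],
                )
    mask = np.isin(labels, plant_clusters).astype(np.uint8)
    rule["centroids"] = [float(c) for c in centroids]
    return CanopyMask(mask=mask, transform=transform, crs=crs, provenance=rule)


def segment_canopy(
    raster: RgbRaster,
    k: int = 5,
    seed: int = 0,
    mapping: dict[int, str] | None = None,
    threshold: float = 0.0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[CanopyMask, IndexRaster, KMeansModel]:
    """Full stage-1 segmentation: index, cluster into ``k`` classes, recode."""
    index = compute_rg_index(raster)
    # 3 restarts: 1-D index clustering is well conditioned, and whole-scene
    # pixel counts make additional restarts costly
    model, labels = kmeans_cluster(
        index.values.ravel(), k=k, seed=seed, max_iter=max_iter, tol=tol, n_init=3
    )
    mask = recode_to_plant_soil(
        model,
        labels.reshape(index.values.shape),
        transform=raster.transform,
        crs=raster.crs,
        mapping=mapping,
        threshold=threshold,
    )
    return mask, index, model
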