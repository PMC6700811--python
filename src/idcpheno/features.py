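"""Zonal plot features: per-plot color proportions and canopy coverage.

For every plot polygon the pixels whose centers fall inside are gathered
(the shared membership rule from :mod:`idcpheno.io`) and summarised into
green/yellow/brown counts, the proportions of plant pixels in each color,
and canopy coverage = plant pixels / all pixels in the plot — the standard
biomass proxy.  Plots with no plant pixels keep coverage 0 but carry missing
proportions rather than 0/0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from idcpheno.colors import BROWN, GREEN, YELLOW, ColorClassRaster
from idcpheno.io import PlotPolygonSet, pixels_in_polygon
from idcpheno.segmentation import CanopyMask

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "plot_id", "trial_id", "entry_id", "block_id",
    "n_pixels_total", "n_plant", "n_green", "n_yellow", "n_brown",
    "prop_green", "prop_yellow", "prop_brown", "canopy_coverage",
]


def extract_plot_features(
    colors: ColorClassRaster,
    mask: CanopyMask,
    plots: PlotPolygonSet,
) -> pd.DataFrame:
    """One feature record per plot polygon.

    Raises if a plot lies entirely outside the raster; plots only partially
    inside are flagged in a ``partially_outside`` column and summarised over
    the pixels they do cover.
    """
    if colors.labels.shape != mask.mask.shape:
        raise ValueError("color raster and mask shapes differ")
    shape = colors.labels.shape
    transform = colors.transform
    rows_out = []
    outside = []
    for rec, geom in zip(plots.records, plots.geometries):
        rr, cc = pixels_in_polygon(geom, transform, shape)
        n_total = len(rr)
        if n_total == 0:
            outside.append(rec["plot_id"])
            continue
        # flag plots clipped by the raster edge: polygon area implies more
        # pixel centers than we found
        expected = geom.area / (transform.pixel_width * transform.pixel_height)
        partially_outside = n_total < np.floor(expected) - 1
        labels = colors.labels[rr, cc]
        n_green = int((labels == GREEN).sum())
        n_yellow = int((labels == YELLOW).sum())
        n_brown = int((labels == BROWN).sum())
        n_plant = n_green + n_yellow + n_brown
        if n_plant > 0:
            pg, py, pb = (n_green / n_plant, n_yellow / n_plant, n_brown / n_plant)
        else:
            pg = py = pb = np.nan
            logger.warning("plot %r has no plant pixels; proportions missing",
                           rec["plot_id"])
        rows_out.append({
            "plot_id": rec["plot_id"],
            "trial_id": rec["trial_id"],
            "entry_id": rec["entry_id"],
            "block_id": rec["block_id"],
            "n_pixels_total": n_total,
            "n_plant": n_plant,
            "n_green": n_green,
            "n_yellow": n_yellow,
            "n_brown": n_brown,
            "prop_green": pg,
            "prop_yellow": py,
            "prop_brown": pb,
            "canopy_coverage": n_plant / n_total,
            "partially_outside": bool(partially_outside),
        })
    if outside:
        raise ValueError(f"plots entirely outside raster extent: {outside}")
    return pd.DataFrame(rows_out)


@dataclass
class CoverageSummary:
    """Per-severity-class canopy coverage with ANOVA and Tukey HSD results."""

    class_means: pd.Series  # index: score class, values: mean coverage
    class_counts: pd.Series
    f_statistic: float | None
    p_value: float | None
    tukey: pd.DataFrame | None  # pairwise comparisons, None if < 2 usable classes
    alpha: float


def summarize_coverage_by_class(
    features: pd.DataFrame,
    scores: pd.Series | dict,
    alpha: float = 0.05,
) -> CoverageSummary:
    """Compare canopy coverage across the 1-5 severity classes.

    ``scores`` maps plot_id -> class.  Returns per-class mean coverage, the
    one-way ANOVA F statistic, and Tukey honest-significant-difference
    pairwise comparisons at ``alpha``.  Classes with fewer than 2 plots are
    excluded from the pairwise tests (logged).
    """
    scores = pd.Series(scores)
    df = features[["plot_id", "canopy_coverage"]].copy()
    df["score"] = df["plot_id"].map(scores)
    if df["score"].isna().any():
        missing = df.loc[df["score"].isna(), "plot_id"].tolist()
        raise ValueError(f"plots without a score: {missing[:10]}")
    df = df.dropna(subset=["canopy_coverage"])
    class_means = df.groupby("score")["canopy_coverage"].mean()
    class_counts = df.groupby("score")["canopy_coverage"].size()

    usable = class_counts[class_counts >= 2].index
    dropped = sorted(set(class_counts.index) - set(usable))
    if dropped:
        logger.info("classes with < 2 plots excluded from comparisons: %s", dropped)
    sub = df[df["score"].isin(usable)]
    f_stat = p_val = None
    tukey = None
    if len(usable) >= 2:
        groups = [g["canopy_coverage"].to_numpy() for _, g in sub.groupby("score")]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f_stat, p_val = 0.0, 1.0  # all observations identical
        else:
            f_stat, p_val = stats.f_oneway(*groups)
            f_stat, p_val = float(f_stat), float(p_val)
        res = pairwise_tukeyhsd(
            sub["canopy_coverage"].to_numpy(), sub["score"].to_numpy(), alpha=alpha
        )
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return CoverageSummary(
        class_means=class_means,
        class_counts=class_counts,
        f_statistic=f_stat,
        p_value=p_val,
        tukey=tukey,
        alpha=alpha,
    )
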