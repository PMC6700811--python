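"""Synthetic IDC field generator: rasters, plot polygons and ground truth.

Emulates the imagery the pipeline consumes: a randomized-complete-block
nursery of single-row soybean plots on bare soil, photographed nadir at a
ground sampling distance of a centimetre or two.  Per-plot severity follows
a latent-normal RCBD model (grand mean + entry effect + block effect +
residual, all normal), discretized into the 1-5 scale by equal-width cut
points.  Severity drives the canopy: coverage falls with class (defaults
follow the observed per-class means 0.264, 0.246, 0.189, 0.096, 0.039) and
the canopy color mixture shifts from green-dominant (class 1) to
brown-dominant (class 5).

Each plot's canopy is rendered as a union of discs along the row axis —
a blob with ragged edges, so the downstream segmentation sees realistic
edge-pixel ambiguity — with the exact canopy pixel count drawn binomially
at the class coverage mean.  Pixel colors are Gaussian around per-class RGB
centroids; the soil background is Gaussian around a soil centroid.  All 8-bit
digital numbers, as from an uncalibrated RGB camera.

Everything is reproducible: one integer seed fixes scores, layout
randomization, blob shapes and pixel noise bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from idcpheno.io import GeoTransform, PlotPolygonSet, RgbRaster

#: latent-scale cut points separating classes 1..5 (equal width)
CUT_POINTS = (1.5, 2.5, 3.5, 4.5)

_DEFAULT_COVERAGE = (0.264, 0.246, 0.189, 0.096, 0.039)
_DEFAULT_COLOR_MIX = (
    (0.85, 0.12, 0.03),
    (0.60, 0.33, 0.07),
    (0.30, 0.55, 0.15),
    (0.10, 0.55, 0.35),
    (0.02, 0.28, 0.70),
)
_DEFAULT_CLASS_RGB = ((60.0, 140.0, 50.0), (175.0, 200.0, 60.0), (120.0, 80.0, 45.0))


@dataclass(frozen=True)
class FieldSimConfig:
    """Study conditions for the synthetic field.

    Defaults describe a small two-replicate IDC nursery: a handful of trials
    of 16 entries each, 1.6 cm pixels, plots of roughly 2000 pixels, and the
    observed severity-coverage relation.
    """

    n_trials: int = 4
    entries_per_trial: int = 16
    n_blocks: int = 2
    plot_px: tuple[int, int] = (56, 36)  # (rows, cols) of the plot bounding box
    alley_px: int = 6
    class_coverage_means: tuple[float, ...] = _DEFAULT_COVERAGE
    class_color_mix: tuple[tuple[float, float, float], ...] = _DEFAULT_COLOR_MIX
    class_rgb_means: tuple[tuple[float, float, float], ...] = _DEFAULT_CLASS_RGB
    canopy_rgb_sd: float = 10.0
    soil_rgb_mean: tuple[float, float, float] = (155.0, 110.0, 85.0)
    soil_rgb_sd: float = 10.0
    grand_mean: float = 2.3
    entry_effect_sd: float = 0.9
    block_effect_sd: float = 0.2
    residual_sd: float = 0.3
    rater_sd: float = 0.3  # sd of the extra noise in simulated visual ratings
    pixel_size: float = 0.016  # metres per pixel (ground sampling distance)
    origin: tuple[float, float] = (500000.0, 5013000.0)
    crs: str = "EPSG:32615"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")
        if self.n_trials < 1 or self.entries_per_trial < 1:
            raise ValueError("need at least one trial and one entry")
        if len(self.class_coverage_means) != 5 or len(self.class_color_mix) != 5:
            raise ValueError("coverage means and color mixes must have 5 entries")
        cov = np.asarray(self.class_coverage_means, dtype=float)
        if np.any(cov < 0) or np.any(cov > 1):
            raise ValueError("coverage means must be in [0,1]")
        if not np.all(np.diff(cov) < 0):
            raise ValueError("coverage means must strictly decrease with class")
        for mix in self.class_color_mix:
            m = np.asarray(mix, dtype=float)
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("color-mix proportions must be in [0,1]")
            if abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"color mix {mix} does not sum to 1")
        for trip in (*self.class_rgb_means, self.soil_rgb_mean):
            t = np.asarray(trip, dtype=float)
            if np.any(t < 0) or np.any(t > 255):
                raise ValueError(f"RGB mean {trip} outside [0,255]")
        for name in ("entry_effect_sd", "block_effect_sd", "residual_sd",
                     "rater_sd", "canopy_rgb_sd", "soil_rgb_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.alley_px < 0 or min(self.plot_px) < 1:
            raise ValueError("invalid plot/alley geometry")

    # -- plain-text config round trip --------------------------------------
    def to_file(self, path) -> None:
        lines = [f"{f.name} = {json.dumps(getattr(self, f.name))}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "FieldSimConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            parsed = json.loads(val.strip())
            if isinstance(parsed, list):
                parsed = _as_tuple(parsed)
            kwargs[key] = parsed
        return cls(**kwargs)


def _as_tuple(x):
    return tuple(_as_tuple(v) if isinstance(v, list) else v for v in x)


@dataclass
class ScoreSimulation:
    """Latent severities and discrete scores with the effects that built them."""

    plots: pd.DataFrame  # plot_id, trial_id, entry_id, block_id, latent,
    #                      true_score, visual_score
    entry_effects: pd.DataFrame  # trial_id, entry_id, effect
    block_effects: pd.DataFrame  # trial_id, block_id, effect
    grand_mean: float
    cut_points: tuple[float, ...] = CUT_POINTS


@dataclass
class SyntheticFieldTruth:
    """Ground truth for a rendered field: per-plot records and pixel classes."""

    plots: pd.DataFrame
    truth_raster: np.ndarray  # uint8: 0 soil, 1 green, 2 yellow, 3 brown
    config: FieldSimConfig


def latent_to_class(latent) -> np.ndarray:
    """Discretize latent severity by the fixed equal-width cut points."""
    return (np.digitize(np.asarray(latent, dtype=float), CUT_POINTS) + 1).astype(int)


def simulate_scores(config: FieldSimConfig) -> ScoreSimulation:
    """Draw the RCBD latent-severity model and discretize to 1-5 scores.

    Latent(plot) = grand_mean + entry_effect + block_effect + residual with
    independent zero-mean normal components; the same entry keeps its effect
    across blocks within a trial.  ``visual_score`` re-discretizes the latent
    value after adding rater noise (sd ``rater_sd``), emulating a human
    scorer; ``true_score`` discretizes the noise-free latent value.
    """
    rng = np.random.default_rng([config.seed, 0])
    rows, e_rows, b_rows = [], [], []
    plot_counter = 0
    for t in range(1, config.n_trials + 1):
        trial_id = f"T{t:02d}"
        entry_eff = rng.normal(0.0, config.entry_effect_sd,
                               size=config.entries_per_trial)
        block_eff = rng.normal(0.0, config.block_effect_sd, size=config.n_blocks)
        for e in range(config.entries_per_trial):
            e_rows.append({"trial_id": trial_id, "entry_id": f"E{e + 1:02d}",
                           "effect": entry_eff[e]})
        for b in range(config.n_blocks):
            b_rows.append({"trial_id": trial_id, "block_id": b + 1,
                           "effect": block_eff[b]})
        for b in range(config.n_blocks):
            for e in range(config.entries_per_trial):
                plot_counter += 1
                resid = rng.normal(0.0, config.residual_sd)
                latent = config.grand_mean + entry_eff[e] + block_eff[b] + resid
                rater = rng.normal(0.0, config.rater_sd)
                rows.append({
                    "plot_id": f"p{plot_counter:04d}",
                    "trial_id": trial_id,
                    "entry_id": f"E{e + 1:02d}",
                    "block_id": b + 1,
                    "latent": latent,
                    "true_score": int(latent_to_class(latent)),
                    "visual_score": int(latent_to_class(latent + rater)),
                })
    return ScoreSimulation(
        plots=pd.DataFrame(rows),
        entry_effects=pd.DataFrame(e_rows),
        block_effects=pd.DataFrame(b_rows),
        grand_mean=config.grand_mean,
    )


def _render_plot_canopy(rng, h: int, w: int, target: int) -> np.ndarray:
    """Blob of exactly ``target`` canopy pixels: discs along the row axis."""
    mask = np.zeros((h, w), dtype=bool)
    if target <= 0:
        return mask
    target = min(target, h * w)
    rr, cc = np.ogrid[:h, :w]
    guard = 0
    while int(mask.sum()) < target and guard < 2000:
        guard += 1
        rcen = rng.uniform(0, h)
        ccen = w / 2 + rng.uniform(-w / 8, w / 8)
        rad = rng.uniform(w / 6, w / 3)
        mask |= (rr - rcen) ** 2 + (cc - ccen) ** 2 <= rad * rad
    n = int(mask.sum())
    if n > target:
        idx = np.flatnonzero(mask.ravel())
        drop = rng.choice(idx, size=n - target, replace=False)
        flat = mask.ravel()
        flat[drop] = False
        mask = flat.reshape(h, w)
    return mask


def render_field(
    config: FieldSimConfig, sim: ScoreSimulation
) -> tuple[RgbRaster, PlotPolygonSet, SyntheticFieldTruth]:
    """Rasterize the field: soil background, per-plot canopy blobs, polygons.

    Layout: one horizontal strip per (trial, block), entries randomized
    within each strip (the RCBD randomization); strips and plots separated
    by soil alleys.  Returns the rendered RGB raster, georeferenced plot
    polygons carrying the design attributes, and the pixel-level truth.
    """
    rng = np.random.default_rng([config.seed, 1])
    ph, pw = config.plot_px
    alley = config.alley_px
    margin = max(alley, 2)
    n_strips = config.n_trials * config.n_blocks
    H = 2 * margin + n_strips * ph + (n_strips - 1) * alley
    W = 2 * margin + config.entries_per_trial * pw + (config.entries_per_trial - 1) * alley

    transform = GeoTransform(config.origin[0], config.origin[1],
                             config.pixel_size, config.pixel_size)

    # soil background
    pixels = rng.normal(
        np.asarray(config.soil_rgb_mean), config.soil_rgb_sd, size=(H, W, 3)
    )
    truth = np.zeros((H, W), dtype=np.uint8)

    plots = sim.plots.set_index(["trial_id", "block_id", "entry_id"])
    cov = np.asarray(config.class_coverage_means)
    mixes = np.asarray(config.class_color_mix)
    rgb_means = np.asarray(config.class_rgb_means)

    records, geometries, truth_rows = [], [], []
    strip = 0
    for t in range(1, config.n_trials + 1):
        trial_id = f"T{t:02d}"
        for b in range(1, config.n_blocks + 1):
            order = rng.permutation(config.entries_per_trial)
            for j, e_idx in enumerate(order):
                entry_id = f"E{e_idx + 1:02d}"
                rec = plots.loc[(trial_id, b, entry_id)]
                score = int(rec["true_score"])
                r0 = margin + strip * (ph + alley)
                c0 = margin + j * (pw + alley)

                n_bbox = ph * pw
                target = int(rng.binomial(n_bbox, cov[score - 1]))
                canopy = _render_plot_canopy(rng, ph, pw, target)
                n_canopy = int(canopy.sum())
                if n_canopy:
                    color_cls = rng.choice(3, size=n_canopy, p=mixes[score - 1])
                    colors = rng.normal(rgb_means[color_cls], config.canopy_rgb_sd)
                    sub = pixels[r0 : r0 + ph, c0 : c0 + pw]
                    sub[canopy] = colors
                    tsub = truth[r0 : r0 + ph, c0 : c0 + pw]
                    tsub[canopy] = (color_cls + 1).astype(np.uint8)

                x0 = transform.origin_x + c0 * transform.pixel_width
                x1 = transform.origin_x + (c0 + pw) * transform.pixel_width
                y0 = transform.origin_y - (r0 + ph) * transform.pixel_height
                y1 = transform.origin_y - r0 * transform.pixel_height
                geometries.append(box(x0, y0, x1, y1))
                records.append({
                    "plot_id": rec["plot_id"],
                    "trial_id": trial_id,
                    "entry_id": entry_id,
                    "block_id": b,
                })
                truth_rows.append({
                    "plot_id": rec["plot_id"],
                    "trial_id": trial_id,
                    "entry_id": entry_id,
                    "block_id": b,
                    "true_score": score,
                    "visual_score": int(rec["visual_score"]),
                    "latent": float(rec["latent"]),
                    "true_coverage": float(cov[score - 1]),
                    "realized_coverage": n_canopy / n_bbox,
                    "mix_green": float(mixes[score - 1][0]),
                    "mix_yellow": float(mixes[score - 1][1]),
                    "mix_brown": float(mixes[score - 1][2]),
                    "n_pixels_bbox": n_bbox,
                    "n_canopy": n_canopy,
                })
            strip += 1

    raster = RgbRaster(
        pixels=np.clip(pixels, 0, 255).astype(np.uint8),
        transform=transform,
        crs=config.crs,
    )
    polygons = PlotPolygonSet(records=records, geometries=geometries,
                              crs=config.crs)
    truth_obj = SyntheticFieldTruth(
        plots=pd.DataFrame(truth_rows), truth_raster=truth, config=config
    )
    return raster, polygons, truth_obj


def simulate_field(
    config: FieldSimConfig,
) -> tuple[RgbRaster, PlotPolygonSet, SyntheticFieldTruth, ScoreSimulation]:
    """Scores + rendering in one call."""
    sim = simulate_scores(config)
    raster, polygons, truth = render_field(config, sim)
    return raster, polygons, truth, sim
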