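"""Point-sampled thematic-map accuracy assessment.

An equalized random sample draws the same number of points from every
predicted class (so rare classes are assessed as thoroughly as common ones),
reference labels are attached — from a human interpreter in the field
workflow, or from a ground-truth raster in simulation — and an error matrix
yields overall, producer and user accuracies:

* overall  = sum of the diagonal / all sample units;
* producer accuracy (per reference class) = correct / reference-column total
  (complement of omission error);
* user accuracy (per predicted class) = correct / predicted-row total
  (complement of commission error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ErrorMatrix:
    """Reference-vs-predicted count table with the three accuracy statistics.

    ``counts`` has predicted classes on rows and reference classes on
    columns.  Accuracies are percentages (0-100).
    """

    counts: pd.DataFrame
    overall_accuracy: float
    user_accuracy: pd.Series  # per predicted class (row-wise)
    producer_accuracy: pd.Series  # per reference class (column-wise)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def report(self) -> str:
        """Plain-text report in the conventional accuracy-table layout."""
        lines = ["Error matrix (rows: predicted, columns: reference)", ""]
        tab = self.counts.copy()
        tab["row_total"] = self.row_totals
        tab["user_accuracy_%"] = self.user_accuracy.round(1)
        lines.append(tab.to_string())
        lines.append("")
        lines.append("column totals:      "
                     + "  ".join(f"{c}={int(v)}" for c, v in self.column_totals.items()))
        lines.append("producer accuracy %: "
                     + "  ".join(f"{c}={v:.1f}" for c, v in self.producer_accuracy.items()))
        lines.append(f"overall accuracy % = {self.overall_accuracy:.1f}")
        return "\n".join(lines)


def equalized_random_sample(
    class_raster: np.ndarray,
    n_per_class: int,
    seed: int = 0,
    classes: list | None = None,
) -> pd.DataFrame:
    """Draw ``n_per_class`` pixels uniformly without replacement per class.

    Returns a DataFrame with columns ``row``, ``col``, ``predicted``.  The
    equal per-class allocation is what makes the design "equalized": class
    frequencies in the sample are fixed regardless of map prevalence.
    """
    grid = np.asarray(class_raster)
    if classes is None:
        classes = sorted(np.unique(grid).tolist())
    rng = np.random.default_rng(seed)
    frames = []
    for cls in classes:
        rr, cc = np.nonzero(grid == cls)
        if len(rr) < n_per_class:
            raise ValueError(
                f"class {cls!r} has only {len(rr)} pixels, "
                f"cannot draw {n_per_class}"
            )
        idx = rng.choice(len(rr), size=n_per_class, replace=False)
        frames.append(pd.DataFrame(
            {"row": rr[idx], "col": cc[idx], "predicted": cls}
        ))
    return pd.concat(frames, ignore_index=True)


def label_points_from_truth(points: pd.DataFrame, truth: np.ndarray) -> pd.DataFrame:
    """Attach reference labels by look-up in a ground-truth raster."""
    out = points.copy()
    out["reference"] = np.asarray(truth)[out["row"].to_numpy(), out["col"].to_numpy()]
    return out


def build_error_matrix(
    points: pd.DataFrame | None = None,
    counts: pd.DataFrame | np.ndarray | None = None,
    classes: list | None = None,
) -> ErrorMatrix:
    """Build an :class:`ErrorMatrix` from labelled sample points or raw counts.

    Exactly one of ``points`` (columns ``predicted`` and ``reference``) or
    ``counts`` (square grid, predicted on rows) must be given.
    """
    if (points is None) == (counts is None):
        raise ValueError("provide exactly one of points or counts")
    if points is not None:
        if "reference" not in points.columns or points["reference"].isna().any():
            n_bad = (points["reference"].isna().sum()
                     if "reference" in points.columns else len(points))
            raise ValueError(f"{n_bad} sample points lack reference labels")
        if classes is None:
            classes = sorted(
                set(points["predicted"]).union(points["reference"])
            )
        counts = pd.crosstab(points["predicted"], points["reference"]).reindex(
            index=classes, columns=classes, fill_value=0
        )
    else:
        counts = pd.DataFrame(np.asarray(counts))
        if counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be square (predicted x reference)")
        if classes is not None:
            counts.index = classes
            counts.columns = classes
    counts = counts.astype(int)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    grand = counts.to_numpy().sum()
    diag = np.diag(counts.to_numpy())
    overall = 100.0 * diag.sum() / grand if grand else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        user = pd.Series(
            100.0 * diag / counts.sum(axis=1).to_numpy(), index=counts.index
        )
        producer = pd.Series(
            100.0 * diag / counts.sum(axis=0).to_numpy(), index=counts.columns
        )
    return ErrorMatrix(
        counts=counts,
        overall_accuracy=float(overall),
        user_accuracy=user,
        producer_accuracy=producer,
    )
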