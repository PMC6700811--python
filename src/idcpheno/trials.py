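"""Per-trial RCBD analysis: linear model, MSE, and least significant difference.

Each breeding trial is a randomized complete block design: every entry
(candidate line) appears once per block.  Plot scores are analysed with the
fixed-effects linear model

    score ~ entry + block  (+ iid residual)

fit by ordinary least squares; the residual mean square (MSE) estimates the
plot-to-plot noise after removing entry and block effects.  The least
significant difference at significance level alpha is then

    paper mode:     LSD = t(1 - alpha/2, df) * sqrt(MSE)
    standard mode:  LSD = t(1 - alpha/2, df) * sqrt(2 * MSE / r)

with r the replication (block) count.  The two coincide exactly at r = 2,
the usual two-replicate IDC nursery design.  Variety trials conventionally
relax alpha to 0.20 to gain power, so that is the default.

A smaller LSD at fixed design means a more precise phenotype: comparing the
per-trial LSDs obtained from visual scores against those from image-derived
scores quantifies which scoring method separates breeding lines better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TrialModelFit:
    """OLS fit of score ~ entry + block for one trial."""

    mse: float
    df_resid: int
    entry_means: pd.Series  # least-squares entry means
    n_entries: int
    n_blocks: int
    n_obs: int


@dataclass
class TrialLsdResult:
    trial_id: object
    source: str  # "visual" | "uas"
    n_entries: int
    n_blocks: int
    df_resid: int
    mse: float
    t_quantile: float
    lsd: float
    alpha: float
    mode: str


@dataclass
class LsdComparison:
    """Head-to-head per-trial LSD comparison of two score sources."""

    table: pd.DataFrame  # trial_id, lsd_visual, lsd_uas, difference
    n_trials: int
    n_uas_lower: int
    mean_difference: float  # mean of (lsd_uas - lsd_visual); negative = UAS wins


def fit_trial_model(
    scores: pd.Series | np.ndarray,
    entry_ids: pd.Series | np.ndarray,
    block_ids: pd.Series | np.ndarray,
) -> TrialModelFit:
    """OLS fit of score ~ entry + block; design may be incomplete.

    Returns the residual mean square, residual degrees of freedom and the
    least-squares entry means (entry effect evaluated at the average block
    effect).
    """
    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "entry": pd.Categorical(np.asarray(entry_ids)),
        "block": pd.Categorical(np.asarray(block_ids)),
    }).dropna(subset=["score"])
    n_entries = df["entry"].nunique()
    n_blocks = df["block"].nunique()
    if n_entries < 2 or n_blocks < 2:
        raise ValueError(
            f"need >= 2 entries and >= 2 blocks, got {n_entries} x {n_blocks}"
        )
    res = smf.ols("score ~ C(entry) + C(block)", data=df).fit()
    if res.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom (saturated design)")
    mse = float(res.ssr / res.df_resid)
    # least-squares means: prediction per entry averaged over all block levels
    entries = df["entry"].cat.categories
    blocks = df["block"].cat.categories
    grid = pd.DataFrame(
        [(e, b) for e in entries for b in blocks], columns=["entry", "block"]
    )
    pred = res.predict(grid)
    lsmeans = pd.Series(pred.to_numpy(), index=pd.MultiIndex.from_frame(grid))
    entry_means = lsmeans.groupby(level="entry", observed=True).mean()
    entry_means.index = entry_means.index.astype(entries.dtype)
    return TrialModelFit(
        mse=mse,
        df_resid=int(res.df_resid),
        entry_means=entry_means,
        n_entries=n_entries,
        n_blocks=n_blocks,
        n_obs=len(df),
    )


def compute_lsd(
    mse: float,
    df: int,
    alpha: float = 0.20,
    mode: str = "paper",
    r: int | None = None,
) -> tuple[float, float]:
    """Least significant difference and the t quantile used.

    ``mode="paper"`` multiplies sqrt(MSE) by the two-sided t quantile
    (cumulative 1 - alpha/2); ``mode="standard"`` uses the textbook
    sqrt(2 MSE / r) standard error of a mean difference, requiring the
    replication count ``r``.  Identical at r = 2.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if mse < 0:
        raise ValueError("MSE must be >= 0")
    if df < 1:
        raise ValueError("residual df must be >= 1")
    t = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    if mode == "paper":
        lsd = t * np.sqrt(mse)
    elif mode == "standard":
        if r is None or r < 1:
            raise ValueError("standard mode needs the replication count r")
        lsd = t * np.sqrt(2.0 * mse / r)
    else:
        raise ValueError(f"unknown LSD mode {mode!r}")
    return float(lsd), t


def trial_lsd_table(
    scores: pd.DataFrame,
    score_col: str,
    source: str,
    alpha: float = 0.20,
    mode: str = "paper",
) -> list[TrialLsdResult]:
    """Fit every trial in a long score table and compute its LSD.

    ``scores`` needs columns trial_id, entry_id, block_id and ``score_col``.
    """
    out = []
    for trial_id, grp in scores.groupby("trial_id"):
        fit = fit_trial_model(grp[score_col], grp["entry_id"], grp["block_id"])
        lsd, t = compute_lsd(fit.mse, fit.df_resid, alpha=alpha, mode=mode,
                             r=fit.n_blocks)
        out.append(TrialLsdResult(
            trial_id=trial_id,
            source=source,
            n_entries=fit.n_entries,
            n_blocks=fit.n_blocks,
            df_resid=fit.df_resid,
            mse=fit.mse,
            t_quantile=t,
            lsd=lsd,
            alpha=alpha,
            mode=mode,
        ))
    return out


def lsd_results_frame(results: list[TrialLsdResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def compare_lsds(
    visual: list[TrialLsdResult], uas: list[TrialLsdResult]
) -> LsdComparison:
    """Per-trial LSD differences between visual and image-based scoring."""
    v = {r.trial_id: r.lsd for r in visual}
    u = {r.trial_id: r.lsd for r in uas}
    if set(v) != set(u):
        raise ValueError(
            f"trial sets differ: only-visual={sorted(set(v) - set(u))}, "
            f"only-uas={sorted(set(u) - set(v))}"
        )
    rows = [
        {"trial_id": t, "lsd_visual": v[t], "lsd_uas": u[t],
         "difference": u[t] - v[t]}
        for t in sorted(v)
    ]
    table = pd.DataFrame(rows)
    return LsdComparison(
        table=table,
        n_trials=len(table),
        n_uas_lower=int((table["difference"] < 0).sum()),
        mean_difference=float(table["difference"].mean()),
    )
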