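"""Class-conditional Dirichlet feature benchmark for the score classifiers.

Real plot features (proportions of green/yellow/brown canopy pixels) live on
the 2-simplex and overlap between adjacent severity classes.  This benchmark
draws features from per-class Dirichlet distributions whose mean vectors are
the severity-class color mixes, with a shared concentration parameter that
controls the class overlap.  Because the generating densities are known, the
Bayes-optimal classifier (argmax of the class-conditional density, equal
priors) and hence the Bayes accuracy can be computed by Monte Carlo — an
upper bound no classifier can beat, against which fitted models are judged.

The default concentration (11) puts the Bayes rate near 75%, the practical
accuracy regime for aerial 1-5 chlorosis scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import dirichlet

from idcpheno.scoring import FEATURES

#: severity-class mean color mixes (green, yellow, brown), classes 1..5
DEFAULT_MIXES = (
    (0.85, 0.12, 0.03),
    (0.60, 0.33, 0.07),
    (0.30, 0.55, 0.15),
    (0.10, 0.55, 0.35),
    (0.02, 0.28, 0.70),
)
DEFAULT_CONCENTRATION = 11.0
#: offset keeping every Dirichlet parameter comfortably positive
_ALPHA_OFFSET = 0.5


def class_alphas(
    concentration: float = DEFAULT_CONCENTRATION,
    mixes=DEFAULT_MIXES,
) -> np.ndarray:
    return np.asarray(mixes, dtype=float) * concentration + _ALPHA_OFFSET


def dirichlet_feature_dataset(
    n: int,
    seed: int = 0,
    concentration: float = DEFAULT_CONCENTRATION,
    mixes=DEFAULT_MIXES,
) -> pd.DataFrame:
    """Draw ``n`` plots with equal class priors; columns = features + score."""
    alphas = class_alphas(concentration, mixes)
    rng = np.random.default_rng(seed)
    y = rng.integers(0, len(alphas), size=n) + 1
    X = np.vstack([rng.dirichlet(alphas[c - 1]) for c in y])
    df = pd.DataFrame(X, columns=FEATURES)
    df["score"] = y
    return df


def bayes_predict(
    X: np.ndarray,
    concentration: float = DEFAULT_CONCENTRATION,
    mixes=DEFAULT_MIXES,
) -> np.ndarray:
    """Bayes-optimal class (equal priors): argmax class-conditional density."""
    alphas = class_alphas(concentration, mixes)
    Xc = np.clip(np.asarray(X, dtype=float), 1e-12, None)
    Xc = Xc / Xc.sum(axis=1, keepdims=True)
    logp = np.vstack([dirichlet.logpdf(Xc.T, a) for a in alphas]).T
    return np.argmax(logp, axis=1) + 1


def bayes_accuracy(
    n_mc: int = 20000,
    seed: int = 0,
    concentration: float = DEFAULT_CONCENTRATION,
    mixes=DEFAULT_MIXES,
) -> float:
    """Monte-Carlo Bayes accuracy (percent) of the generating model."""
    data = dirichlet_feature_dataset(n_mc, seed=seed, concentration=concentration,
                                     mixes=mixes)
    pred = bayes_predict(data[FEATURES].to_numpy(), concentration, mixes)
    return 100.0 * float((pred == data["score"].to_numpy()).mean())
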