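"""Monte-Carlo calibration studies for the factorial Wald analysis.

Utilities to measure, under the package's own generative model, the type-I
error of the Wald contrasts and the coverage of the Wald confidence
intervals. Replicate responses are drawn at the averaged-cell level —
a biological residual per treatment cell plus the mean of the technical
noise over ``n_technical`` wells, which is exactly the law of
``simulate_assay`` followed by technical-replicate averaging — and every
replicate is pushed through the ordinary fit/contrast path.
"""

from __future__ import annotations

from collections.abc import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .immune_lm import (DesignMatrix, ModelFit, build_design_matrix,
                        contrast_vector, fit_ols, wald_contrast)
from .synthetic_data import EffectParameters, ExperimentDesign


def cell_table(design: ExperimentDesign) -> pd.DataFrame:
    """One row per treatment cell (fish x time x LPS x concentration)."""
    rows = [(f, t, l, c)
            for f in design.fish_ids
            for t in design.time_points
            for l in design.lps_levels
            for c in design.concentrations]
    df = pd.DataFrame(rows, columns=["fish_id", "time", "lps",
                                     "concentration"])
    df["mean"] = 0.0
    return df


def true_beta(params: EffectParameters, dm: DesignMatrix) -> np.ndarray:
    """Generating coefficients arranged in the design-matrix column order."""
    beta = np.zeros(len(dm.columns))
    for j, label in enumerate(dm.columns):
        if label == "intercept":
            beta[j] = params.intercept
        elif label.startswith("fish:"):
            beta[j] = params.fish_effects.get(label[5:], 0.0)
        elif label == "time:19h":
            beta[j] = params.time_effect
        elif label == "lps:yes":
            beta[j] = params.lps_effect
        elif label == "time:19h|lps:yes":
            beta[j] = params.time_lps_interaction
        elif label.startswith("time:19h|conc:"):
            beta[j] = params.time_conc_interactions.get(float(label[14:]), 0.0)
        elif label.startswith("lps:yes|conc:"):
            beta[j] = params.lps_conc_interactions.get(float(label[13:]), 0.0)
        elif label.startswith("conc:"):
            beta[j] = params.conc_effects.get(float(label[5:]), 0.0)
    return beta


def simulate_fits(design: ExperimentDesign, params: EffectParameters,
                  n_sim: int, seed: int) -> Iterator[ModelFit]:
    """Yield ``n_sim`` fits of averaged replicate datasets.

    Each averaged cell observation is Xbeta + N(0, residual_sd^2) +
    mean of n_technical N(0, technical_sd^2) draws.
    """
    params.validate_against(design)
    dm = build_design_matrix(cell_table(design))
    mu = dm.X @ true_beta(params, dm)
    sd_eff = np.sqrt(params.residual_sd ** 2
                     + params.technical_sd ** 2 / design.n_technical)
    rng = np.random.default_rng(seed)
    for _ in range(n_sim):
        dm.y = mu + rng.normal(0.0, sd_eff, size=mu.size)
        yield fit_ols(dm)


def null_rejection_rate(design: ExperimentDesign, params: EffectParameters,
                        contrast_terms: dict[str, float], n_sim: int,
                        seed: int, alpha: float = 0.05) -> float:
    """Fraction of null-true replicates a Wald contrast rejects at alpha.

    ``contrast_terms`` maps column labels to weights; the generating
    parameters must make the contrast's true value 0 for this to be a
    type-I error rate.
    """
    rejections = 0
    c = None
    for fit in simulate_fits(design, params, n_sim, seed):
        if c is None:
            c = contrast_vector(fit, contrast_terms)
        if wald_contrast(fit, c).p <= alpha:
            rejections += 1
    return rejections / n_sim


def interval_coverage(design: ExperimentDesign, params: EffectParameters,
                      n_sim: int, seed: int,
                      level: float = 0.95) -> pd.Series:
    """Per-coefficient coverage of the Wald t-intervals.

    Returns the fraction of replicates in which each generating coefficient
    lies inside estimate +- t_{(1+level)/2, df} * SE.
    """
    hits = None
    beta0 = None
    for fit in simulate_fits(design, params, n_sim, seed):
        if hits is None:
            dm = fit.design
            beta0 = true_beta(params, dm)
            hits = np.zeros(len(dm.columns))
            labels = list(dm.columns)
        tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
        se = np.sqrt(np.clip(np.diag(fit.cov), 0.0, None))
        hits += (np.abs(fit.beta - beta0) <= tcrit * se)
    return pd.Series(hits / n_sim, index=labels)
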