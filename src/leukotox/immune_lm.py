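"""Factorial linear model, Wald contrasts and LOEC extraction.

The screening analysis models each immune endpoint Y (averaged over
technical replicates) as

    Y = b0 + sum_f b_f I(fish=f) + b_t I(time=19h) + b_l I(LPS=yes)
        + sum_c b_c I(conc=c)
        + b_tl I(time=19h) I(LPS=yes)
        + sum_c b_tc I(time=19h) I(conc=c)
        + sum_c b_lc I(LPS=yes) I(conc=c)   + eps,   eps ~ N(0, sigma^2)

with reference levels (first fish, 3 h, no LPS, concentration 0) absorbed
into the intercept. Treatment comparisons — LPS-stimulated vs
non-stimulated control, and each concentration vs its control with or
without LPS, at each time point — are Wald tests on linear combinations of
the coefficients. The LOEC of an endpoint in a scenario is the lowest
tested concentration whose comparison to control reaches p <= 0.05.

Concentrations are unordered factor levels (no dose-trend term), tests are
two-sided, and no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

log = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class DesignMatrix:
    """Indicator design matrix with labelled columns and response vector."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    meta: pd.DataFrame
    concentrations: tuple[float, ...]   # non-control levels, ascending
    time_levels: tuple[str, ...]
    lps_levels: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


@dataclass
class ModelFit:
    """Least-squares fit: coefficients, dispersion and covariance."""

    beta: np.ndarray
    sigma2: float
    cov: np.ndarray
    df_resid: int
    fitted: np.ndarray
    residuals: np.ndarray
    columns: list[str]
    rank: int
    aliased: list[str] = field(default_factory=list)
    design: DesignMatrix | None = None

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))
        return pd.DataFrame({"term": self.columns, "estimate": self.beta,
                             "se": se})


@dataclass(frozen=True)
class ContrastResult:
    """One Wald test of a linear combination c'beta."""

    label: str
    contrast: np.ndarray
    estimate: float
    se: float
    t: float
    p: float
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LoecResult:
    """Lowest observed effect concentration for one endpoint x scenario."""

    endpoint: str
    scenario: str
    loec: float | None
    direction: str | None   # 'increase' | 'decrease'
    determinable: bool

    def __str__(self) -> str:
        if not self.determinable:
            return "n.d."
        return f"{self.loec:g} ({self.direction})"


def _conc_label(c: float) -> str:
    return f"conc:{c:g}"


def build_design_matrix(averaged: pd.DataFrame,
                        response: str = "mean") -> DesignMatrix:
    """Expand averaged treatment observations into indicator coding.

    Reference levels are the first fish (order of appearance), 3 h, no LPS
    and concentration 0. Factors with a single observed level contribute no
    columns (logged, not an error). Duplicate treatment rows are rejected.
    """
    required = {"fish_id", "time", "lps", "concentration", response}
    missing = required - set(averaged.columns)
    if missing:
        raise ValueError(f"averaged table lacks columns: {sorted(missing)}")
    dup_keys = ["fish_id", "time", "lps", "concentration"]
    if averaged.duplicated(subset=dup_keys).any():
        raise ValueError("duplicate treatment rows; average technical "
                         "replicates before building the design matrix")

    fish = list(pd.unique(averaged["fish_id"]))
    times = [t for t in ("3h", "19h") if t in set(averaged["time"])]
    lps = [l for l in ("no", "yes") if l in set(averaged["lps"])]
    concs = sorted(set(averaged["concentration"]) - {0.0})

    f = averaged["fish_id"].to_numpy()
    t19 = (averaged["time"] == "19h").to_numpy(float)
    stim = (averaged["lps"] == "yes").to_numpy(float)
    conc = averaged["concentration"].to_numpy(float)

    cols: list[np.ndarray] = [np.ones(len(averaged))]
    labels: list[str] = ["intercept"]
    for fid in fish[1:]:
        cols.append((f == fid).astype(float))
        labels.append(f"fish:{fid}")
    if len(times) > 1:
        cols.append(t19)
        labels.append("time:19h")
    else:
        log.info("single time level %s: no time column", times)
    if len(lps) > 1:
        cols.append(stim)
        labels.append("lps:yes")
    else:
        log.info("single LPS level %s: no lps column", lps)
    for c in concs:
        cols.append((conc == c).astype(float))
        labels.append(_conc_label(c))
    if len(times) > 1 and len(lps) > 1:
        cols.append(t19 * stim)
        labels.append("time:19h|lps:yes")
    for c in concs:
        if len(times) > 1:
            cols.append(t19 * (conc == c).astype(float))
            labels.append(f"time:19h|{_conc_label(c)}")
    for c in concs:
        if len(lps) > 1:
            cols.append(stim * (conc == c).astype(float))
            labels.append(f"lps:yes|{_conc_label(c)}")

    X = np.column_stack(cols)
    y = averaged[response].to_numpy(float)
    return DesignMatrix(X=X, columns=labels, y=y,
                        meta=averaged[dup_keys].reset_index(drop=True),
                        concentrations=tuple(concs),
                        time_levels=tuple(times), lps_levels=tuple(lps))


def fit_ols(dm: DesignMatrix) -> ModelFit:
    """Ordinary least squares fit of the factorial model.

    sigma^2 is RSS / (n - rank); the coefficient covariance is
    sigma^2 (X'X)^- (Moore-Penrose generalised inverse when the design is
    rank-deficient, with aliased columns reported on the fit).
    """
    X, y = dm.X, dm.y
    n, p = X.shape
    # column-pivoted QR identifies which columns are aliased
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(n, p) * _RANK_TOL if diag.size else 0.0
    rank = int((diag > tol).sum())
    aliased = [dm.columns[j] for j in sorted(piv[rank:])]
    if n - rank <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df = n - rank
    sigma2 = rss / df
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    if aliased:
        log.warning("rank-deficient design; aliased columns: %s", aliased)
    return ModelFit(beta=beta, sigma2=sigma2, cov=cov, df_resid=df,
                    fitted=fitted, residuals=resid, columns=dm.columns,
                    rank=rank, aliased=aliased, design=dm)


def contrast_vector(fit: ModelFit, terms: dict[str, float]) -> np.ndarray:
    """Build a contrast vector from {column label: weight}."""
    c = np.zeros(len(fit.columns))
    for label, w in terms.items():
        try:
            c[fit.columns.index(label)] = w
        except ValueError:
            raise KeyError(f"no model column named {label!r}") from None
    return c


def wald_contrast(fit: ModelFit, c: np.ndarray, label: str = "",
                  meta: dict | None = None) -> ContrastResult:
    """Wald test of c'beta = 0 against the two-sided Student-t tail."""
    c = np.asarray(c, float)
    if c.shape != (len(fit.columns),):
        raise ValueError(f"contrast length {c.size} != {len(fit.columns)} "
                         "coefficients")
    var = float(c @ fit.cov @ c)
    scale = float(np.abs(fit.cov).max()) or 1.0
    if not np.any(c) or var <= scale * 1e-14:
        raise ValueError(f"non-estimable contrast {label!r}")
    est = float(c @ fit.beta)
    se = float(np.sqrt(var))
    t = est / se
    p = 2.0 * float(stats.t.sf(abs(t), fit.df_resid))
    return ContrastResult(label=label, contrast=c, estimate=est, se=se,
                          t=t, p=p, meta=meta or {})


def standard_comparisons(fit: ModelFit) -> list[ContrastResult]:
    """The screen's standard treatment comparisons, per time point.

    For each time point: (i) LPS-stimulated control vs non-stimulated
    control; (ii) each tested concentration vs control without LPS;
    (iii) each tested concentration vs control with LPS. At 19 h the
    relevant interaction coefficients enter the linear combination.
    Concentrations absent from the fit are skipped with a log entry.
    """
    dm = fit.design
    if dm is None:
        raise ValueError("fit carries no design metadata")
    results: list[ContrastResult] = []
    have = set(fit.columns)
    for time in dm.time_levels:
        at19 = time == "19h"
        if "lps:yes" in have:
            terms = {"lps:yes": 1.0}
            if at19 and "time:19h|lps:yes" in have:
                terms["time:19h|lps:yes"] = 1.0
            results.append(wald_contrast(
                fit, contrast_vector(fit, terms),
                label=f"{time}|LPS control vs non-stimulated control",
                meta={"time": time, "comparison": "lps_vs_control"}))
        for conc in dm.concentrations:
            if _conc_label(conc) not in have:
                log.info("concentration %g absent from fit; skipped", conc)
                continue
            for lps in dm.lps_levels:
                terms = {_conc_label(conc): 1.0}
                if at19 and f"time:19h|{_conc_label(conc)}" in have:
                    terms[f"time:19h|{_conc_label(conc)}"] = 1.0
                if lps == "yes" and f"lps:yes|{_conc_label(conc)}" in have:
                    terms[f"lps:yes|{_conc_label(conc)}"] = 1.0
                results.append(wald_contrast(
                    fit, contrast_vector(fit, terms),
                    label=f"{time}|conc {conc:g} vs control|LPS={lps}",
                    meta={"time": time, "lps": lps, "concentration": conc,
                          "comparison": "conc_vs_control"}))
    return results


def determine_loec(contrasts: list[ContrastResult], alpha: float = 0.05,
                   endpoint: str = "", scenario: str = "") -> LoecResult:
    """Lowest tested concentration significant against its control.

    ``contrasts`` must be concentration-vs-control results carrying a
    ``concentration`` meta entry; they are ordered by concentration and the
    smallest with p <= alpha wins (non-monotone p profiles allowed). When
    none is significant the LOEC is not determinable.
    """
    with_conc = [c for c in contrasts if "concentration" in c.meta]
    for c in sorted(with_conc, key=lambda r: r.meta["concentration"]):
        if c.p <= alpha:
            direction = "increase" if c.estimate > 0 else "decrease"
            return LoecResult(endpoint=endpoint, scenario=scenario,
                              loec=float(c.meta["concentration"]),
                              direction=direction, determinable=True)
    return LoecResult(endpoint=endpoint, scenario=scenario, loec=None,
                      direction=None, determinable=False)


def contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    rows = [{"label": r.label, "estimate": r.estimate, "se": r.se,
             "t": r.t, "p": r.p, **r.meta} for r in results]
    return pd.DataFrame(rows)
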