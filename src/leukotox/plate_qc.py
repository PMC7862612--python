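"""Plate-level normalisation and quality control.

Raw well signals are normalised against blank wells, technical replicates
are averaged into one observation per treatment cell, and each fish is
screened with the LPS positive-control rule: a fish's data for an endpoint
enter the statistical analysis only if LPS stimulation raised the control
wells above the non-stimulated controls by more than the technical error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TREATMENT_KEYS = ["fish_id", "time", "lps", "concentration", "endpoint"]


@dataclass(frozen=True)
class QcDecision:
    """Validity verdict for one fish x endpoint."""

    fish_id: str
    endpoint: str
    valid: bool
    stimulated_control_mean: float
    unstimulated_control_mean: float
    technical_error: float
    margin: float
    reason: str = ""


def blank_normalize(records: pd.DataFrame,
                    group_cols: list[str] | None = None) -> pd.DataFrame:
    """Subtract the mean blank signal from every sample well.

    Blanks are ``role == 'blank'`` rows; the subtraction is applied per
    grouping (default: per endpoint). Blank rows are removed from the
    output. Raises if a grouping has no blanks.
    """
    group_cols = group_cols or ["endpoint"]
    blanks = records[records["role"] == "blank"]
    samples = records[records["role"] != "blank"].copy()
    if blanks.empty:
        raise ValueError(f"no blank wells found for grouping {group_cols}")
    gb = group_cols[0] if len(group_cols) == 1 else group_cols
    blank_means = blanks.groupby(gb)["value"].mean()
    for key, grp in samples.groupby(gb):
        if key not in blank_means.index:
            raise ValueError(f"missing blanks for grouping {group_cols}={key!r}")
    keys = (samples[group_cols[0]] if len(group_cols) == 1
            else pd.MultiIndex.from_frame(samples[group_cols]))
    samples["value"] = samples["value"].to_numpy() - blank_means.loc[keys].to_numpy()
    return samples.reset_index(drop=True)


def average_technical_replicates(records: pd.DataFrame,
                                 keys: list[str] | None = None
                                 ) -> pd.DataFrame:
    """Collapse technical replicate wells into per-treatment means.

    Returns one row per fish x time x LPS x concentration x endpoint with
    ``mean``, ``sd`` (sample SD, 0 for a single replicate) and ``n_wells``.
    """
    keys = keys or TREATMENT_KEYS
    grouped = records.groupby(keys, sort=False, dropna=False)["value"]
    out = grouped.agg(mean="mean", sd="std", n_wells="size").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def pooled_technical_sd(records: pd.DataFrame,
                        keys: list[str] | None = None) -> float:
    """Pooled within-cell SD of technical replicates (df-weighted)."""
    keys = keys or TREATMENT_KEYS
    stats = records.groupby(keys, dropna=False)["value"].agg(["var", "size"])
    df = stats["size"] - 1
    if df.sum() <= 0:
        return 0.0
    return float(np.sqrt((stats["var"].fillna(0.0) * df).sum() / df.sum()))


def lps_quality_control(records: pd.DataFrame, k: float = 1.0
                        ) -> list[QcDecision]:
    """Apply the LPS positive-control validity rule per fish x endpoint.

    A fish's data for an endpoint are valid when the LPS-stimulated control
    wells (concentration 0, lps = yes) exceed the non-stimulated controls
    by more than ``k`` times the technical error, defined as the pooled SD
    of that fish's control technical replicates. Fish missing either
    control arm are marked invalid with reason ``incomplete controls``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    decisions: list[QcDecision] = []
    controls = records[(records["concentration"] == 0)
                       & (records["role"] != "blank")]
    for (fish, endpoint), grp in records.groupby(["fish_id", "endpoint"],
                                                 sort=False):
        ctl = controls[(controls["fish_id"] == fish)
                       & (controls["endpoint"] == endpoint)]
        stim = ctl[ctl["lps"] == "yes"]["value"]
        unstim = ctl[ctl["lps"] == "no"]["value"]
        if stim.empty or unstim.empty:
            decisions.append(QcDecision(fish, endpoint, False,
                                        np.nan, np.nan, np.nan, np.nan,
                                        reason="incomplete controls"))
            continue
        tech_err = pooled_technical_sd(ctl)
        s, u = float(stim.mean()), float(unstim.mean())
        margin = k * tech_err
        valid = (s - u) > margin
        reason = "" if valid else "LPS stimulation within technical error"
        if s <= u:
            reason = "no LPS stimulation of control cells"
        decisions.append(QcDecision(fish, endpoint, valid, s, u, tech_err,
                                    margin, reason=reason))
        if not valid:
            log.info("QC exclusion: fish=%s endpoint=%s (%s)", fish,
                     endpoint, reason)
    return decisions


def qc_report(decisions: list[QcDecision]) -> pd.DataFrame:
    """Tabulate QC decisions (fish_id, endpoint, valid, reason, ...)."""
    return pd.DataFrame([{
        "fish_id": d.fish_id, "endpoint": d.endpoint, "valid": d.valid,
        "stimulated_control_mean": d.stimulated_control_mean,
        "unstimulated_control_mean": d.unstimulated_control_mean,
        "technical_error": d.technical_error, "margin": d.margin,
        "reason": d.reason,
    } for d in decisions])


def filter_valid(records: pd.DataFrame,
                 decisions: list[QcDecision]) -> pd.DataFrame:
    """Drop rows belonging to fish x endpoint combinations that failed QC."""
    invalid = {(d.fish_id, d.endpoint) for d in decisions if not d.valid}
    if not invalid:
        return records
    mask = [(f, e) not in invalid
            for f, e in zip(records["fish_id"], records["endpoint"])]
    return records[mask].reset_index(drop=True)
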