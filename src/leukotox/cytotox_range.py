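"""Cytotoxicity screening: normalised viability, EC20 and the admissible
concentration range.

Cell viability is the calcein/DAPI signal ratio normalised to the control
ratio (control = 1.0). The EC20 of an exposure scenario is the nominal
concentration at which viability crosses 80% of control (20% cytotoxicity),
located by log-linear interpolation between the bracketing tested levels;
when no tested level drops below 80% the EC20 is right-censored at the
highest tested concentration. Concentrations strictly below the EC20 form
the non-cytotoxic range in which the immune parameters are evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VIABILITY_THRESHOLD = 0.8


@dataclass(frozen=True)
class Ec20Result:
    """EC20 of one chemical x exposure scenario, possibly censored."""

    chemical: str
    scenario: str
    value: float | None          # None when censored
    censored: bool
    max_tested: float
    viabilities: dict[float, float] = field(default_factory=dict)
    flagged_nonmonotone: bool = False
    at_lowest_bound: bool = False   # crossing below the lowest non-zero level

    def __str__(self) -> str:
        if self.censored:
            return f"> {self.max_tested:g}"
        prefix = "<= " if self.at_lowest_bound else ""
        return f"{prefix}{self.value:g}"


def viability_fraction(records: pd.DataFrame,
                       keys: list[str] | None = None) -> pd.DataFrame:
    """Normalised viability per treatment: (calcein/DAPI) / control ratio.

    ``records`` carries blank-corrected ``calcein`` and ``dapi`` signals.
    Signals are averaged per scenario x concentration (within ``keys``,
    default time x lps), the ratio is taken, and each scenario is
    normalised to its own control (concentration 0) so the control is
    exactly 1.0. Treatments with DAPI <= 0 are excluded with a reason.
    """
    keys = keys or ["time", "lps"]
    df = records[records.get("role", "sample") != "blank"].copy()
    neg = (df["calcein"] < 0) | (df["dapi"] < 0)
    if neg.any():
        log.warning("%d wells with negative blank-corrected signals clipped "
                    "to 0", int(neg.sum()))
        df[["calcein", "dapi"]] = df[["calcein", "dapi"]].clip(lower=0.0)

    agg = df.groupby(keys + ["concentration"], sort=False)[
        ["calcein", "dapi"]].mean().reset_index()
    bad = agg["dapi"] <= 0
    for row in agg[bad].itertuples(index=False):
        log.warning("treatment excluded (DAPI <= 0): %s", tuple(row))
    agg = agg[~bad].copy()
    agg["ratio"] = agg["calcein"] / agg["dapi"]

    out = []
    for key, grp in agg.groupby(keys, sort=False):
        ctrl = grp[grp["concentration"] == 0]
        if ctrl.empty:
            raise ValueError(f"no control (concentration 0) for scenario {key!r}")
        grp = grp.copy()
        grp["viability"] = grp["ratio"] / float(ctrl["ratio"].iloc[0])
        out.append(grp)
    return pd.concat(out, ignore_index=True).drop(columns=["ratio"])


def estimate_ec20(concentrations: np.ndarray | list[float],
                  viabilities: np.ndarray | list[float],
                  chemical: str = "", scenario: str = "",
                  threshold: float = VIABILITY_THRESHOLD) -> Ec20Result:
    """Locate the concentration where viability crosses the 80% threshold.

    The control (concentration 0) anchors the curve but is excluded from
    the log-scale interpolation. A tested level with viability exactly at
    the threshold is itself the EC20. If even the lowest non-zero level is
    below the threshold, that level is reported as an upper bound. With no
    level below the threshold the result is censored ``> max tested``.
    Multiple threshold crossings use the first from low concentration,
    flagged as non-monotone.
    """
    conc = np.asarray(concentrations, float)
    via = np.asarray(viabilities, float)
    order = np.argsort(conc)
    conc, via = conc[order], via[order]
    if conc.size < 3 or conc[0] != 0:
        raise ValueError("need the control and at least two non-zero "
                         "concentrations")
    vmap = {float(c): float(v) for c, v in zip(conc, via)}
    nz_c, nz_v = conc[conc > 0], via[conc > 0]
    max_tested = float(nz_c[-1])

    below = nz_v < threshold
    # number of entries into the below-threshold state; >1 means the curve
    # recovered above the threshold and crossed again
    entries = int(np.sum(below & np.r_[True, ~below[:-1]]))
    nonmono = entries > 1
    if nonmono:
        log.warning("non-monotone viability curve for %s/%s: first crossing "
                    "used", chemical, scenario)

    exact = np.isclose(nz_v, threshold)
    if exact.any() and not below[: int(np.argmax(exact))].any():
        return Ec20Result(chemical, scenario, float(nz_c[np.argmax(exact)]),
                          False, max_tested, vmap,
                          flagged_nonmonotone=nonmono)
    if not below.any():
        return Ec20Result(chemical, scenario, None, True, max_tested, vmap,
                          flagged_nonmonotone=nonmono)
    first = int(np.argmax(below))
    if first == 0:
        # already past the threshold at the lowest non-zero level
        return Ec20Result(chemical, scenario, float(nz_c[0]), False,
                          max_tested, vmap, flagged_nonmonotone=nonmono,
                          at_lowest_bound=True)
    c_lo, c_hi = nz_c[first - 1], nz_c[first]
    v_lo, v_hi = nz_v[first - 1], nz_v[first]
    frac = (v_lo - threshold) / (v_lo - v_hi)
    log_ec20 = np.log(c_lo) + frac * (np.log(c_hi) - np.log(c_lo))
    return Ec20Result(chemical, scenario, float(np.exp(log_ec20)), False,
                      max_tested, vmap, flagged_nonmonotone=nonmono)


def estimate_ec20_table(viability: pd.DataFrame, chemical: str = "",
                        keys: list[str] | None = None) -> list[Ec20Result]:
    """Per-scenario EC20s from a normalised viability table."""
    keys = keys or ["time", "lps"]
    results = []
    for key, grp in viability.groupby(keys, sort=False):
        scen = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        results.append(estimate_ec20(grp["concentration"], grp["viability"],
                                     chemical=chemical, scenario=scen))
    return results


def noncytotoxic_range(ec20: Ec20Result,
                       tested_grid: list[float]) -> list[float]:
    """Tested concentrations admissible for the immune assays.

    Returns the grid entries strictly below the EC20 (the whole grid when
    the EC20 is censored). Raises when no non-zero concentration qualifies.
    """
    grid = sorted(float(c) for c in tested_grid)
    if ec20.censored:
        admissible = grid
    else:
        admissible = [c for c in grid if c < ec20.value]
    if not any(c > 0 for c in admissible):
        raise ValueError(
            f"no non-cytotoxic concentration: EC20 {ec20} is at or below "
            f"the lowest tested level")
    return admissible
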