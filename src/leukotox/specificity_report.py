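"""Toxic-ratio / specificity-ratio classification and summary tables.

The screen's final verdicts combine three numbers per chemical:

* TR (toxic ratio) = IC10_baseline / average EC20_Cytotox. TR > 10 means
  the observed cytotoxicity is more potent than baseline narcosis predicts
  — a specific mode of action; TR <= 10 means non-specific baseline
  toxicity.
* SR (specificity ratio) = EC20_Cytotox / LOEC of an immune endpoint.
  SR < 10 means the immune effect is no more potent than non-specific
  action.

Censored EC20s ("> max tested") and non-determinable LOECs propagate: no
finite ratio is emitted from a censored input, though a bound derived from
the censoring limit is carried along, flagged as a bound. Table output is
rounded to one decimal (half away from zero); full precision is retained
on the record objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytotox_range import Ec20Result
from .immune_lm import ContrastResult, LoecResult

log = logging.getLogger(__name__)

RATIO_THRESHOLD = 10.0


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (table convention), e.g. 0.25 -> 0.3."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class RatioResult:
    """TR or SR with censoring-aware value, bound and classification."""

    kind: str                     # 'TR' | 'SR'
    value: float | None           # None when not determinable
    classification: str           # 'specific' | 'non-specific' | 'not determinable'
    bound: float | None = None    # ratio at the censoring limit, if censored
    bound_kind: str | None = None  # '<' (upper) or '>' (lower)
    borderline: bool = False

    @property
    def determinable(self) -> bool:
        return self.value is not None

    def rounded(self, decimals: int = 1) -> float | None:
        return None if self.value is None else round_half_away(self.value,
                                                               decimals)

    def __str__(self) -> str:
        if self.value is None:
            if self.bound is not None:
                return f"{self.bound_kind} {round_half_away(self.bound):g}"
            return "n.d."
        return f"{self.rounded():g}"


def toxic_ratio(ic10_um: float, ec20) -> RatioResult:
    """TR = IC10_baseline / EC20; specific iff TR > 10.

    ``ec20`` may be a number (uM) or an :class:`Ec20Result`. A censored
    EC20 (> max tested) yields no finite TR, only an upper bound at the
    censoring limit. TR within one unit of the threshold is flagged
    borderline (the screen's call at e.g. TR = 10.9 is mechanical but
    worth surfacing).
    """
    if ic10_um <= 0 or not np.isfinite(ic10_um):
        raise ValueError("IC10 must be positive and finite")
    if isinstance(ec20, Ec20Result):
        if ec20.censored:
            bound = ic10_um / ec20.max_tested
            return RatioResult("TR", None, "not determinable",
                               bound=bound, bound_kind="<")
        ec20_value = ec20.value
    else:
        ec20_value = float(ec20)
    if ec20_value == 0:
        raise ValueError("EC20 must be non-zero")
    if ec20_value < 0:
        raise ValueError("EC20 must be positive")
    tr = ic10_um / ec20_value
    cls = "specific" if tr > RATIO_THRESHOLD else "non-specific"
    return RatioResult("TR", tr, cls,
                       borderline=abs(tr - RATIO_THRESHOLD) <= 1.0)


def specificity_ratio(ec20, loec) -> RatioResult:
    """SR = EC20 / LOEC; specific iff SR > 10 (SR < 10 non-specific).

    Either input may be censored (``Ec20Result``) or not determinable
    (``LoecResult``); in that case no finite SR is emitted. A censored
    EC20 with a finite LOEC yields a lower bound at the censoring limit.
    """
    if isinstance(loec, LoecResult):
        if not loec.determinable:
            return RatioResult("SR", None, "not determinable")
        loec_value = loec.loec
    else:
        loec_value = float(loec)
    if loec_value == 0:
        raise ValueError("LOEC must be non-zero")
    if loec_value < 0:
        raise ValueError("LOEC must be positive")
    if isinstance(ec20, Ec20Result):
        if ec20.censored:
            return RatioResult("SR", None, "not determinable",
                               bound=ec20.max_tested / loec_value,
                               bound_kind=">")
        ec20_value = ec20.value
    else:
        ec20_value = float(ec20)
    if ec20_value <= 0:
        raise ValueError("EC20 must be positive")
    sr = ec20_value / loec_value
    cls = "specific" if sr > RATIO_THRESHOLD else "non-specific"
    return RatioResult("SR", sr, cls)


def scenario_average(values: list) -> tuple[float | None, bool, float | None]:
    """Average determinable scenario values, propagating censoring.

    ``values`` are numbers, ``Ec20Result``/``LoecResult`` objects or None
    (not determinable). Returns (mean, censored, censor_bound): the
    arithmetic mean of the determinable values, or, when every value is
    censored/non-determinable, a censored result carrying the largest
    censoring bound available.
    """
    finite: list[float] = []
    bounds: list[float] = []
    for v in values:
        if v is None:
            continue
        if isinstance(v, Ec20Result):
            if v.censored:
                bounds.append(v.max_tested)
            else:
                finite.append(v.value)
        elif isinstance(v, LoecResult):
            if v.determinable:
                finite.append(v.loec)
        else:
            finite.append(float(v))
    if finite:
        return float(np.mean(finite)), False, None
    return None, True, (max(bounds) if bounds else None)


@dataclass(frozen=True)
class SpecificityRecord:
    """All screening verdicts for one chemical."""

    chemical: str
    ic10_um: float
    ec20_by_scenario: dict[str, Ec20Result] = field(default_factory=dict)
    loec_by_endpoint: dict[str, dict[str, LoecResult]] = field(default_factory=dict)

    @property
    def ec20_average(self):
        mean, censored, bound = scenario_average(
            list(self.ec20_by_scenario.values()))
        if censored:
            any_res = next(iter(self.ec20_by_scenario.values()))
            return Ec20Result(self.chemical, "average", None, True,
                              bound if bound is not None else any_res.max_tested)
        return Ec20Result(self.chemical, "average", mean, False,
                          max(r.max_tested for r in
                              self.ec20_by_scenario.values()))

    @property
    def toxic_ratio(self) -> RatioResult:
        return toxic_ratio(self.ic10_um, self.ec20_average)

    def loec_average(self, endpoint: str):
        return scenario_average(list(self.loec_by_endpoint.get(endpoint,
                                                               {}).values()))

    def specificity_ratios(self, mode: str = "per_scenario"
                           ) -> dict[str, RatioResult]:
        """Average SR per endpoint.

        ``per_scenario`` (primary): SR is formed per exposure scenario from
        that scenario's EC20 and LOEC, then the determinable SRs are
        averaged — matching how scenario-wise ratios are summarised.
        ``of_averages``: ratio of the averaged EC20 to the averaged LOEC,
        emitted for comparison only.
        """
        out: dict[str, RatioResult] = {}
        for endpoint, loecs in self.loec_by_endpoint.items():
            if mode == "of_averages":
                mean_loec, nd, _ = self.loec_average(endpoint)
                if nd:
                    out[endpoint] = RatioResult("SR", None, "not determinable")
                else:
                    out[endpoint] = specificity_ratio(self.ec20_average,
                                                      mean_loec)
                continue
            per_scenario = []
            for scen, loec in loecs.items():
                ec20 = self.ec20_by_scenario.get(scen)
                if ec20 is None:
                    log.warning("no EC20 for scenario %s of %s", scen,
                                self.chemical)
                    continue
                sr = specificity_ratio(ec20, loec)
                if sr.determinable:
                    per_scenario.append(sr.value)
            if per_scenario:
                mean_sr = float(np.mean(per_scenario))
                cls = ("specific" if mean_sr > RATIO_THRESHOLD
                       else "non-specific")
                out[endpoint] = RatioResult("SR", mean_sr, cls)
            else:
                out[endpoint] = RatioResult("SR", None, "not determinable")
        return out


def p_category(p: float, estimate: float) -> str:
    """Signed significance bin: ***/**/* x increase/decrease, or 'ns'."""
    if p < 0.001:
        stars = "***"
    elif p < 0.01:
        stars = "**"
    elif p < 0.05:
        stars = "*"
    else:
        return "ns"
    direction = "increase" if estimate > 0 else "decrease"
    return f"{stars}, {direction}"


def contrast_matrix(results: dict[str, list[ContrastResult]]) -> pd.DataFrame:
    """Signed p-category matrix: chemicals x scenarios as rows, the
    standard comparisons as columns."""
    rows = []
    for chemical, contrasts in results.items():
        for r in contrasts:
            rows.append({"chemical": chemical, "label": r.label,
                         "time": r.meta.get("time"),
                         "lps": r.meta.get("lps"),
                         "comparison": r.meta.get("comparison"),
                         "p": r.p,
                         "category": p_category(r.p, r.estimate)})
    return pd.DataFrame(rows)


def build_summary(records: list[SpecificityRecord],
                  contrasts: dict[str, list[ContrastResult]] | None = None
                  ) -> dict[str, pd.DataFrame]:
    """Emit the report bundle.

    Returns ``toxic_ratios`` (chemical, IC10, average EC20, TR — the
    Table-3 shape), ``specificity`` (average LOEC and SR per endpoint —
    the Table-4 shape, per-scenario SR mode plus the ratio-of-averages
    column) and, when contrasts are supplied, ``p_matrix``. Raises when
    the contrast table names chemicals absent from the records.
    """
    if not records:
        raise ValueError("no specificity records")
    if contrasts is not None:
        mismatch = set(contrasts) - {r.chemical for r in records}
        if mismatch:
            raise ValueError(f"contrast results for unknown chemicals: "
                             f"{sorted(mismatch)}")

    tr_rows = []
    for rec in records:
        ec20 = rec.ec20_average
        tr = rec.toxic_ratio
        tr_rows.append({
            "chemical": rec.chemical,
            "ic10_baseline_um": rec.ic10_um,
            "ec20_average_um": None if ec20.censored else ec20.value,
            "ec20_display": str(ec20),
            "tr": tr.rounded(),
            "tr_display": "-" if tr.value is None else f"{tr.rounded():g}",
            "tr_classification": tr.classification,
            "tr_borderline": tr.borderline,
        })

    sr_rows = []
    for rec in records:
        endpoints = sorted(rec.loec_by_endpoint)
        srs = rec.specificity_ratios()
        srs_avg = rec.specificity_ratios(mode="of_averages")
        for endpoint in endpoints:
            mean_loec, nd, _ = rec.loec_average(endpoint)
            sr = srs[endpoint]
            sr_rows.append({
                "chemical": rec.chemical, "endpoint": endpoint,
                "loec_average_um": mean_loec,
                "loec_display": "n.d." if nd else f"{mean_loec:g}",
                "sr": sr.rounded(),
                "sr_display": str(sr),
                "sr_classification": sr.classification,
                "sr_of_averages": srs_avg[endpoint].rounded(),
            })

    out = {"toxic_ratios": pd.DataFrame(tr_rows),
           "specificity": pd.DataFrame(sr_rows)}
    if contrasts is not None:
        out["p_matrix"] = contrast_matrix(contrasts)
    return out
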