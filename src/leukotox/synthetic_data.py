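"""Generators for synthetic plate, viability and qPCR data.

The raw measurements behind the screening study this package reanalyses are
not publicly deposited, so every downstream stage is exercised on synthetic
data that carries the exact statistical structure the analysis assumes:

* assay wells follow a fixed-effects factorial model — per-fish base level,
  additive 19 h time effect, LPS stimulation effect, per-concentration
  effects, and the three interaction families (time x LPS, time x conc,
  LPS x conc) — with a Gaussian biological residual shared by the technical
  replicates of a treatment cell and independent Gaussian technical noise
  per well;
* viability declines along a decreasing Hill curve of the nominal
  concentration;
* qPCR Ct values are built from a per-sample reference-gene Ct plus a
  per-gene delta-Ct, an optional planted treatment shift (the true ddCt),
  and duplicate-level cycle noise.

All generators take an explicit integer seed and are deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ASSAY_COLUMNS = [
    "fish_id", "time", "lps", "concentration", "endpoint", "replicate",
    "value", "role",
]
CT_COLUMNS = ["sample_id", "fish_id", "time", "lps", "concentration",
              "gene", "duplicate", "ct"]

TIME_POINTS = ("3h", "19h")
LPS_LEVELS = ("no", "yes")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of one chemical x endpoint experiment.

    ``concentrations`` is the nominal grid (uM or mM, one unit per
    chemical); the first entry must be exactly 0 and acts as the control.
    Each fish is measured at every time point (3 h, 19 h), with and without
    LPS stimulation, at every concentration, in ``n_technical`` replicate
    wells.
    """

    fish_ids: tuple[str, ...]
    concentrations: tuple[float, ...]
    n_technical: int = 3
    endpoint: str = "phagocytosis"
    time_points: tuple[str, ...] = TIME_POINTS
    lps_levels: tuple[str, ...] = LPS_LEVELS

    def __post_init__(self):
        object.__setattr__(self, "fish_ids", tuple(self.fish_ids))
        object.__setattr__(self, "concentrations",
                           tuple(float(c) for c in self.concentrations))
        if len(self.fish_ids) == 0:
            raise ValueError("at least one fish is required")
        conc = self.concentrations
        if len(conc) == 0 or conc[0] != 0.0:
            raise ValueError("first concentration must be exactly 0 (control)")
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if self.n_technical < 1:
            raise ValueError("n_technical must be >= 1")

    @property
    def treatment_concentrations(self) -> tuple[float, ...]:
        """Non-control concentrations (the model's set C)."""
        return self.concentrations[1:]

    @property
    def n_wells(self) -> int:
        return (len(self.fish_ids) * len(self.time_points)
                * len(self.lps_levels) * len(self.concentrations)
                * self.n_technical)


@dataclass(frozen=True)
class EffectParameters:
    """True coefficients of the factorial generative model.

    Maps over concentrations are keyed by the non-control grid C. The first
    fish of the design is the reference level and must carry effect 0 (it
    may simply be omitted from ``fish_effects``). ``residual_sd`` is the
    biological residual shared by a treatment cell's technical replicates;
    ``technical_sd`` is additional independent well-to-well noise.
    """

    intercept: float = 0.0
    fish_effects: dict[str, float] = field(default_factory=dict)
    time_effect: float = 0.0
    lps_effect: float = 0.0
    conc_effects: dict[float, float] = field(default_factory=dict)
    time_lps_interaction: float = 0.0
    time_conc_interactions: dict[float, float] = field(default_factory=dict)
    lps_conc_interactions: dict[float, float] = field(default_factory=dict)
    residual_sd: float = 1.0
    technical_sd: float = 0.0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.technical_sd < 0:
            raise ValueError("technical_sd must be >= 0")

    def validate_against(self, design: ExperimentDesign) -> None:
        ref = design.fish_ids[0]
        if self.fish_effects.get(ref, 0.0) != 0.0:
            raise ValueError(f"reference fish {ref!r} must have effect 0")
        unknown = set(self.fish_effects) - set(design.fish_ids)
        if unknown:
            raise ValueError(f"fish_effects for unknown fish: {sorted(unknown)}")
        grid = set(design.treatment_concentrations)
        for name, mapping in [("conc_effects", self.conc_effects),
                              ("time_conc_interactions", self.time_conc_interactions),
                              ("lps_conc_interactions", self.lps_conc_interactions)]:
            missing = set(mapping) - grid
            if missing:
                raise ValueError(
                    f"{name} keyed by concentration(s) not in the design grid: "
                    f"{sorted(missing)}")

    def linear_predictor(self, fish: str, time: str, lps: str,
                         conc: float) -> float:
        """E[Y] for one treatment cell under the factorial model."""
        is19 = time == "19h"
        stim = lps == "yes"
        mu = self.intercept + self.fish_effects.get(fish, 0.0)
        if is19:
            mu += self.time_effect
        if stim:
            mu += self.lps_effect
        if conc != 0:
            mu += self.conc_effects.get(conc, 0.0)
            if is19:
                mu += self.time_conc_interactions.get(conc, 0.0)
            if stim:
                mu += self.lps_conc_interactions.get(conc, 0.0)
        if is19 and stim:
            mu += self.time_lps_interaction
        return mu


@dataclass(frozen=True)
class ViabilityTruth:
    """Decreasing Hill curve used to generate viability screens.

    Mean viability at nominal concentration c is top / (1 + (c/ec50)^hill);
    the control (c = 0) sits at ``top`` (1.0 = 100% viability).
    """

    ec50: float
    hill: float = 1.0
    top: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def viability(self, conc: float) -> float:
        if conc < 0:
            raise ValueError("concentration must be non-negative")
        if conc == 0:
            return self.top
        return self.top / (1.0 + (conc / self.ec50) ** self.hill)


@dataclass(frozen=True)
class QpcrTruth:
    """Generative Ct structure for reference and target genes.

    ``delta_ct_control`` gives each target gene's true Ct offset from the
    reference gene in control samples; ``treatment_shift`` is the planted
    true ddCt added in treated samples (positive shift = later Ct = lower
    expression, fold change 2^-shift).
    """

    ref_gene: str = "EF-1a"
    ref_ct_mean: float = 18.0
    ref_ct_sd: float = 0.5
    delta_ct_control: dict[str, float] = field(
        default_factory=lambda: {"IL-1b": 5.0, "TNFa": 7.0, "IL-10": 8.0})
    treatment_shift: dict[str, float] = field(default_factory=dict)
    ct_noise_sd: float = 0.25

    def __post_init__(self):
        if self.ref_ct_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.delta_ct_control:
            raise ValueError("at least one target gene is required")
        if self.ref_gene in self.delta_ct_control:
            raise ValueError("reference gene cannot also be a target gene")


def simulate_assay(design: ExperimentDesign, params: EffectParameters,
                   seed: int, n_blank_wells: int = 0,
                   blank_mean: float = 0.0) -> pd.DataFrame:
    """Simulate one long-format plate table of immune-parameter wells.

    One row per fish x time x LPS x concentration x technical replicate
    with ``role='sample'``. Each treatment cell receives a shared Gaussian
    biological residual (SD ``params.residual_sd``); each well adds
    independent technical noise (SD ``params.technical_sd``). If
    ``n_blank_wells`` > 0, that many ``role='blank'`` wells with mean
    ``blank_mean`` (technical noise only) are appended, in which case all
    sample wells are shifted by ``blank_mean`` so blank subtraction
    recovers the factorial signal.
    """
    params.validate_against(design)
    rng = np.random.default_rng(seed)

    rows = []
    for fish in design.fish_ids:
        for time in design.time_points:
            for lps in design.lps_levels:
                for conc in design.concentrations:
                    mu = params.linear_predictor(fish, time, lps, conc)
                    bio = rng.normal(0.0, params.residual_sd)
                    tech = rng.normal(0.0, params.technical_sd,
                                      size=design.n_technical)
                    for rep in range(1, design.n_technical + 1):
                        rows.append((fish, time, lps, conc, design.endpoint,
                                     rep, blank_mean + mu + bio + tech[rep - 1],
                                     "sample"))
    for b in range(1, n_blank_wells + 1):
        rows.append(("", "", "", 0.0, design.endpoint, b,
                     blank_mean + rng.normal(0.0, params.technical_sd),
                     "blank"))
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS)


def simulate_viability(design: ExperimentDesign, truth: ViabilityTruth,
                       seed: int, dapi_signal: float = 1000.0,
                       calcein_scale: float = 500.0) -> pd.DataFrame:
    """Simulate a calcein/DAPI viability screen over the design's grid.

    Emits one row per fish x time x LPS x concentration with blank-corrected
    ``calcein`` and ``dapi`` signals such that the calcein/DAPI ratio,
    normalised to the control ratio, has mean viability
    top / (1 + (c/ec50)^hill). Gaussian noise of SD ``truth.noise_sd`` is
    added on the viability scale.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fish in design.fish_ids:
        for time in design.time_points:
            for lps in design.lps_levels:
                for conc in design.concentrations:
                    v = truth.viability(conc) + rng.normal(0.0, truth.noise_sd)
                    rows.append((fish, time, lps, conc,
                                 calcein_scale * v, dapi_signal, "sample"))
    return pd.DataFrame(rows, columns=["fish_id", "time", "lps",
                                       "concentration", "calcein", "dapi",
                                       "role"])


def simulate_qpcr(design: ExperimentDesign, truth: QpcrTruth, seed: int,
                  all_concentrations: bool = False) -> pd.DataFrame:
    """Simulate a Ct table in technical duplicates.

    By default only the control and the highest tested concentration are
    generated, matching the screening protocol (only those levels are
    quantified); pass ``all_concentrations=True`` for the full grid. Per
    sample the reference-gene Ct is drawn once; each target gene sits at
    reference + delta_ct_control (+ treatment_shift in treated samples);
    duplicate wells add independent cycle noise. Raises if any generated Ct
    leaves the valid (0, 45] cycle window.
    """
    rng = np.random.default_rng(seed)
    if all_concentrations:
        concs = design.concentrations
    else:
        concs = (design.concentrations[0], design.concentrations[-1])
    rows = []
    for fish in design.fish_ids:
        for time in design.time_points:
            for lps in design.lps_levels:
                for conc in concs:
                    sample_id = f"{fish}|{time}|{lps}|{conc:g}"
                    ref_ct = rng.normal(truth.ref_ct_mean, truth.ref_ct_sd)
                    gene_base = {truth.ref_gene: ref_ct}
                    for gene, dct in truth.delta_ct_control.items():
                        base = ref_ct + dct
                        if conc != 0:
                            base += truth.treatment_shift.get(gene, 0.0)
                        gene_base[gene] = base
                    for gene, base in gene_base.items():
                        for dup in (1, 2):
                            ct = base + rng.normal(0.0, truth.ct_noise_sd)
                            rows.append((sample_id, fish, time, lps, conc,
                                         gene, dup, ct))
    out = pd.DataFrame(rows, columns=CT_COLUMNS)
    if ((out["ct"] <= 0) | (out["ct"] > 45)).any():
        raise ValueError("generated Ct values fall outside (0, 45] cycles; "
                         "adjust the truth parameters")
    return out
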