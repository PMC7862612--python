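"""Relative qPCR quantification by the 2^-ddCt method.

Technical duplicate Ct values are averaged, each target gene is normalised
to the reference gene (dCt = Ct_target - Ct_reference, EF-1a by default),
and expression is reported as fold change 2^-ddCt relative to the same
fish's control sample in the same exposure scenario, so every fish's
control maps to fold change 1. Statistical testing downstream operates on
the dCt values, not on fold changes. Amplification efficiency is fixed at
2 per cycle; no efficiency correction is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENE = "EF-1a"
SCENARIO_KEYS = ["fish_id", "time", "lps"]


def collapse_duplicates(records: pd.DataFrame,
                        spread_cutoff: float = 1.0) -> pd.DataFrame:
    """Average technical duplicate Cts into one value per sample x gene.

    Adds a ``flagged`` column marking sample x gene pairs whose duplicate
    spread exceeds ``spread_cutoff`` cycles (default 1); flagged records
    are kept, not dropped.
    """
    keys = ["sample_id", "fish_id", "time", "lps", "concentration", "gene"]
    keys = [k for k in keys if k in records.columns]
    g = records.groupby(keys, sort=False)["ct"]
    out = g.agg(ct="mean", spread=lambda s: s.max() - s.min(),
                n_dups="size").reset_index()
    out["flagged"] = out["spread"] > spread_cutoff
    n_flag = int(out["flagged"].sum())
    if n_flag:
        log.warning("%d sample x gene pairs exceed duplicate spread cutoff "
                    "%.2f cycles", n_flag, spread_cutoff)
    return out


def delta_ct(collapsed: pd.DataFrame,
             reference_gene: str = DEFAULT_REFERENCE_GENE) -> pd.DataFrame:
    """Normalise target Cts to the reference gene per sample.

    Returns one row per sample x target gene with ``delta_ct`` =
    Ct_target - Ct_reference. Samples lacking the reference gene are
    excluded with a logged reason.
    """
    ref = collapsed[collapsed["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref_ct = ref.set_index("sample_id")["ct"]
    targets = collapsed[collapsed["gene"] != reference_gene].copy()
    missing = ~targets["sample_id"].isin(ref_ct.index)
    if missing.any():
        for sid in targets.loc[missing, "sample_id"].unique():
            log.warning("sample %s excluded: missing reference gene %s",
                        sid, reference_gene)
        targets = targets[~missing]
    targets["delta_ct"] = (targets["ct"].to_numpy()
                           - ref_ct.loc[targets["sample_id"]].to_numpy())
    return targets.reset_index(drop=True)


def fold_change(dct: pd.DataFrame, protocol_levels: tuple[float, ...] | None = None
                ) -> pd.DataFrame:
    """Fold change 2^-ddCt relative to the same fish's control.

    ddCt is computed per fish x time x LPS x gene against that scenario's
    control sample (concentration 0). Raises when a treated sample has no
    matching control. If ``protocol_levels`` is given, concentrations
    outside it are flagged ``off_protocol`` (the screening protocol
    quantifies only the control and the highest concentration).
    """
    required = set(SCENARIO_KEYS) | {"concentration", "gene", "delta_ct"}
    missing = required - set(dct.columns)
    if missing:
        raise ValueError(f"delta-Ct table lacks columns: {sorted(missing)}")
    out = dct.copy()
    keys = SCENARIO_KEYS + ["gene"]
    controls = out[out["concentration"] == 0].set_index(keys)["delta_ct"]
    if controls.index.has_duplicates:
        raise ValueError("multiple control samples per fish x scenario x gene")

    ddct = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        key = (row.fish_id, row.time, row.lps, row.gene)
        try:
            ctrl = controls.loc[key]
        except KeyError:
            raise ValueError(
                f"no control sample for fish {row.fish_id!r}, scenario "
                f"{row.time}/LPS={row.lps}, gene {row.gene}") from None
        ddct[i] = row.delta_ct - ctrl
    out["delta_delta_ct"] = ddct
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    if protocol_levels is not None:
        off = ~out["concentration"].isin(protocol_levels)
        out["off_protocol"] = off
        if off.any():
            log.warning("%d rows at concentrations outside the quantification "
                        "protocol", int(off.sum()))
    return out


def quantify(records: pd.DataFrame,
             reference_gene: str = DEFAULT_REFERENCE_GENE,
             spread_cutoff: float = 1.0,
             protocol_levels: tuple[float, ...] | None = None) -> pd.DataFrame:
    """Full Ct-table pipeline: collapse duplicates, dCt, fold change."""
    collapsed = collapse_duplicates(records, spread_cutoff=spread_cutoff)
    dct = delta_ct(collapsed, reference_gene=reference_gene)
    return fold_change(dct, protocol_levels=protocol_levels)
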