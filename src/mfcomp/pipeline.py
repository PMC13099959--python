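"""Orchestration of the pooled-competition analysis over a whole experiment.

Groups a demultiplexed count table by its sample metadata (medium, pH, cycle,
replicate) and runs the standard contrasts of the assay:

* selection within one condition — final cycle vs the shared cycle-0 pool;
* pH effect — final-cycle frequencies of a test pH vs the reference pH (5.5)
  on the same medium, replicate k paired with replicate k.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .fitness import (
    ALPHA_DEFAULT,
    FC_THRESHOLD_DEFAULT,
    condition_contrast,
    enrichment_table,
    to_frequencies,
)
from .quantify import CountTable

REFERENCE_PH_DEFAULT = 5.5


def _sample_meta(count_table: CountTable) -> pd.DataFrame:
    if count_table.samples is None:
        raise ValueError("count table carries no sample metadata (medium/pH/cycle/replicate)")
    meta = count_table.samples
    required = {"medium", "pH", "cycle", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    return meta


def _group_columns(meta: pd.DataFrame, medium: str, ph: float, cycle: int) -> dict[int, str]:
    sel = meta[(meta["medium"] == medium) & (meta["pH"] == ph) & (meta["cycle"] == cycle)]
    return dict(zip(sel["replicate"].astype(int), sel.index))


def enrichment_by_condition(
    count_table: CountTable,
    pseudocount: float = 0.5,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    method: str = "BH",
) -> dict[str, pd.DataFrame]:
    """Per condition: enrichment of the final sampled cycle over cycle 0."""
    meta = _sample_meta(count_table)
    freqs = to_frequencies(count_table, pseudocount)
    out: dict[str, pd.DataFrame] = {}
    for (medium, ph), grp in meta.groupby(["medium", "pH"]):
        cycles = sorted(grp["cycle"].unique())
        if len(cycles) < 2:
            continue
        start, end = cycles[0], cycles[-1]
        start_cols = _group_columns(meta, medium, ph, start)
        end_cols = _group_columns(meta, medium, ph, end)
        pairing = {end_cols[r]: start_cols[r] for r in end_cols if r in start_cols}
        if not pairing:
            continue
        label = f"{medium}_pH{ph:g}"
        out[label] = enrichment_table(
            freqs[list(pairing.keys())],
            freqs[list(pairing.values())],
            pairing,
            fc_threshold=fc_threshold,
            alpha=alpha,
            method=method,
        )
    return out


def contrasts_vs_reference(
    count_table: CountTable,
    reference_pH: float = REFERENCE_PH_DEFAULT,
    pseudocount: float = 0.5,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    method: str = "BH",
) -> dict[str, pd.DataFrame]:
    """Per medium and non-reference pH: final-cycle frequencies contrasted
    against the reference pH on the same medium (reference in the
    denominator), replicate k paired with replicate k."""
    meta = _sample_meta(count_table)
    freqs = to_frequencies(count_table, pseudocount)
    out: dict[str, pd.DataFrame] = {}
    for medium, med_grp in meta.groupby("medium"):
        phs = sorted(med_grp["pH"].unique())
        if reference_pH not in phs:
            continue
        end = int(med_grp["cycle"].max())
        ref_cols = _group_columns(meta, medium, reference_pH, end)
        for ph in phs:
            if ph == reference_pH:
                continue
            test_cols = _group_columns(meta, medium, ph, end)
            pairing = {test_cols[r]: ref_cols[r] for r in test_cols if r in ref_cols}
            if not pairing:
                continue
            label = f"{medium}_pH{ph:g}_vs_pH{reference_pH:g}"
            out[label] = enrichment_table(
                freqs[list(pairing.keys())],
                freqs[list(pairing.values())],
                pairing,
                fc_threshold=fc_threshold,
                alpha=alpha,
                method=method,
            )
    return out


def call_summary(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Flat summary of volcano calls across contrasts."""
    rows = []
    for label, tbl in tables.items():
        for cls in ("enriched", "depleted"):
            for vid in tbl.index[tbl["class"] == cls]:
                rows.append(
                    (label, vid, cls, tbl.loc[vid, "log2fc_mean"], tbl.loc[vid, "adj_p"])
                )
    return pd.DataFrame(rows, columns=["contrast", "variant_id", "class", "log2fc_mean", "adj_p"])
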