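"""Single-strain phenotype calculators and the double-mutant buffering
analysis.

Mating success is scored microscopically per field as

    rate(%) = (2Z + 2A + 0.5S) * 100 / (V + 2Z + 2A + 0.5S)

where V, Z, A, S count vegetative cells, zygotes, asci and free spores: each
zygote or ascus represents two mated cells, each free spore half a mated cell.
Fields are averaged within a biological replicate and replicate means are the
statistical unit downstream, never pooled fields.

Receptor activation by synthetic peptide is read out as Miller units of a
lacZ reporter, MU = (OD420 * 1000) / (V_mL * t_min * OD600), and vegetative
fitness as the lag time for a growth curve to reach OD600 = 0.5.

For the buffering analysis, the expected phenotype of a double mutant under a
no-epistasis multiplicative null is m_wt * (m_a/m_wt) * (m_b/m_wt); a
deleterious substitution counts as rescued by a permissive partner when its
single-mutant rate is near zero (< 1%) but the double reaches >= 3%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitness import welch_t_test  # observed-vs-expected comparisons reuse Welch


@dataclass(frozen=True)
class MatingCounts:
    """Cell-type counts of one microscopic field."""

    V: int
    Z: int
    A: int
    S: int

    def __post_init__(self) -> None:
        if min(self.V, self.Z, self.A, self.S) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ReporterMeasurement:
    """One beta-galactosidase reporter reaction."""

    od420: float
    od600: float
    volume_ml: float
    time_min: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.time_min <= 0 or self.od600 <= 0:
            raise ValueError("volume, time and OD600 must be positive")


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series with strictly increasing time points."""

    times_min: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "od600", od)
        if len(t) < 2 or len(t) != len(od):
            raise ValueError("need >= 2 (time, OD) points of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


def mating_rate(counts: MatingCounts) -> float:
    """Percent of cells that mated, from one field's V/Z/A/S counts."""
    mated = 2 * counts.Z + 2 * counts.A + 0.5 * counts.S
    denom = counts.V + mated
    if denom == 0:
        raise ValueError("unscorable field: no cells counted")
    return 100.0 * mated / denom


@dataclass(frozen=True)
class FieldAggregate:
    """Two-level aggregation of field-wise mating rates."""

    replicate_means: pd.Series
    mean: float
    sd: float | None  # absent with a single replicate


def aggregate_fields(field_rates: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> FieldAggregate:
    """Average fields within each replicate, then summarise across replicates.

    ``field_rates`` maps replicate label -> per-field rates (a plain sequence
    of sequences is labelled 1..K).  Replicate means are the downstream
    statistical units; fields are never pooled across replicates.
    """
    if not isinstance(field_rates, Mapping):
        field_rates = {i + 1: rates for i, rates in enumerate(field_rates)}
    if not field_rates:
        raise ValueError("no replicates given")
    means = {}
    for rep, rates in field_rates.items():
        rates = np.asarray(list(rates), dtype=float)
        if rates.size == 0:
            raise ValueError(f"replicate {rep!r} has no fields")
        means[rep] = float(rates.mean())
    s = pd.Series(means, name="mating_rate")
    sd = float(s.std(ddof=1)) if len(s) > 1 else None
    return FieldAggregate(replicate_means=s, mean=float(s.mean()), sd=sd)


def miller_units(meas: ReporterMeasurement) -> float:
    """Normalised beta-galactosidase activity of one reaction."""
    return (meas.od420 * 1000.0) / (meas.volume_ml * meas.time_min * meas.od600)


def lag_time(curve: GrowthCurve, threshold: float = 0.5) -> float | None:
    """Time (min) at which the curve first reaches the OD600 threshold, by
    linear interpolation between the bracketing samples; 0 if already above
    at the first point; ``None`` when the threshold is never reached."""
    t, od = curve.times_min, curve.od600
    if od[0] >= threshold:
        return 0.0
    above = np.nonzero(od >= threshold)[0]
    if len(above) == 0:
        return None
    j = int(above[0])
    i = j - 1
    frac = (threshold - od[i]) / (od[j] - od[i])
    return float(t[i] + frac * (t[j] - t[i]))


@dataclass(frozen=True)
class PHProfile:
    """Per-pH mating summary across a gradient."""

    table: pd.DataFrame  # index pH; columns mean, sd, n_replicates
    optimum_pH: float  # argmax of the mean; ties broken toward lower pH


def ph_profile(rates_by_pH: Mapping[float, Sequence[float]]) -> PHProfile:
    """Summarise replicate mating rates across a pH gradient."""
    if len(rates_by_pH) < 2:
        raise ValueError("need >= 2 pH levels")
    rows = []
    for ph in sorted(rates_by_pH):
        rates = np.asarray(list(rates_by_pH[ph]), dtype=float)
        sd = float(rates.std(ddof=1)) if len(rates) > 1 else np.nan
        rows.append((ph, float(rates.mean()), sd, len(rates)))
    table = pd.DataFrame(rows, columns=["pH", "mean", "sd", "n_replicates"]).set_index("pH")
    best = table["mean"].max()
    optimum = float(min(ph for ph in table.index if table.loc[ph, "mean"] == best))
    return PHProfile(table=table, optimum_pH=optimum)


def expected_double(m_a: float, m_b: float, m_wt: float) -> float:
    """Multiplicative no-epistasis null for a double mutant's mating rate (%):
    m_wt * (m_a/m_wt) * (m_b/m_wt), clipped to [0, 100]."""
    for x in (m_a, m_b, m_wt):
        if not (0.0 <= x <= 100.0):
            raise ValueError("rates must lie in [0, 100]")
    if m_wt == 0:
        raise ValueError("wild-type rate must be positive")
    return float(min(100.0, max(0.0, m_a * m_b / m_wt)))


def classify_rescue(
    single_rate: float,
    double_rate: float,
    null_floor: float = 1.0,
    rescue_min: float = 3.0,
) -> str:
    """Call a deleterious substitution rescued by a permissive partner.

    'rescued' iff the single mutant is near-sterile (< null_floor %) while the
    double mutant reaches >= rescue_min %.  The default thresholds encode the
    convention that restoration from near-zero to a few percent counts."""
    for x in (single_rate, double_rate):
        if not (0.0 <= x <= 100.0):
            raise ValueError("rates must lie in [0, 100]")
    if single_rate < null_floor and double_rate >= rescue_min:
        return "rescued"
    return "not_rescued"


def rescue_panel(
    singles: Mapping[str, float],
    doubles: Mapping[str, float],
    wt_rate: float,
    null_floor: float = 1.0,
    rescue_min: float = 3.0,
) -> pd.DataFrame:
    """Buffering summary for a panel of deleterious singles vs their doubles
    with one permissive partner.

    ``singles`` maps variant -> single-mutant mean rate; ``doubles`` maps the
    same variants -> double-mutant (variant + permissive partner) mean rate.
    Adds the multiplicative expectation (treating the permissive partner's
    effect as already folded into the double) and the rescue call.
    """
    missing = set(singles) ^ set(doubles)
    if missing:
        raise ValueError(f"singles/doubles panels disagree on variants: {sorted(missing)}")
    rows = []
    for vid in singles:
        rows.append(
            (
                vid,
                singles[vid],
                doubles[vid],
                classify_rescue(singles[vid], doubles[vid], null_floor, rescue_min),
            )
        )
    df = pd.DataFrame(rows, columns=["variant_id", "single_rate", "double_rate", "call"])
    return df.set_index("variant_id")


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

MATING_COLUMNS = ["genotype", "condition", "replicate", "field", "V", "Z", "A", "S"]
REPORTER_COLUMNS = [
    "genotype",
    "peptide_conc_uM",
    "pH",
    "replicate",
    "od420",
    "od600",
    "volume_ml",
    "time_min",
]
GROWTH_COLUMNS = ["genotype", "replicate", "time_min", "od600"]


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} TSV missing columns: {missing}")


def read_mating_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, MATING_COLUMNS, "mating counts")
    return df


def mating_rate_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long-format field count table: field -> replicate ->
    genotype x condition, returning mean ± sd over replicate means."""
    _require(counts, MATING_COLUMNS, "mating counts")
    rates = counts.assign(
        rate=[
            mating_rate(MatingCounts(int(r.V), int(r.Z), int(r.A), int(r.S)))
            for r in counts.itertuples()
        ]
    )
    rep_means = (
        rates.groupby(["genotype", "condition", "replicate"])["rate"].mean().reset_index()
    )
    out = (
        rep_means.groupby(["genotype", "condition"])["rate"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan, n_replicates="count")
        .reset_index()
    )
    return out


def read_reporter_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, REPORTER_COLUMNS, "reporter")
    return df


def miller_units_table(reporter: pd.DataFrame) -> pd.DataFrame:
    """Per-measurement Miller units plus mean ± sd per genotype x pH x dose."""
    _require(reporter, REPORTER_COLUMNS, "reporter")
    mu = reporter.assign(
        miller_units=[
            miller_units(ReporterMeasurement(r.od420, r.od600, r.volume_ml, r.time_min))
            for r in reporter.itertuples()
        ]
    )
    summary = (
        mu.groupby(["genotype", "peptide_conc_uM", "pH"])["miller_units"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan, n_replicates="count")
        .reset_index()
    )
    return summary


def read_growth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, GROWTH_COLUMNS, "growth")
    return df


def lag_time_table(growth: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Lag time to the OD600 threshold per genotype x replicate (NaN when the
    curve never reaches it)."""
    _require(growth, GROWTH_COLUMNS, "growth")
    rows = []
    for (genotype, rep), grp in growth.groupby(["genotype", "replicate"]):
        grp = grp.sort_values("time_min")
        lag = lag_time(GrowthCurve(grp["time_min"].to_numpy(), grp["od600"].to_numpy()), threshold)
        rows.append((genotype, rep, np.nan if lag is None else lag))
    return pd.DataFrame(rows, columns=["genotype", "replicate", "lag_min"])
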