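"""Enrichment statistics for the pooled competition.

Counts become within-sample frequencies (library-size normalisation with a
symmetric pseudocount), selection is summarised per variant as the log2
fold-change of frequency between a later and an earlier sample within each
biological replicate, and pH effects are expressed as the same log2 ratio of a
test condition against the reference condition (pH 5.5).  Replicates — not
reads or microscope fields — are the statistical unit: Welch's unequal-variance
t test compares the per-replicate log2 frequencies of the two groups,
Benjamini-Hochberg (default) controls the FDR across variants, and variants
are classed enriched/depleted on the volcano rule |log2FC| >= 2 (a 4-fold
change) with adjusted p < 0.05.

The closed-form predictor f_i(T) ∝ f_i(0) * m_i^T links pooled outcomes to
single-strain mating efficiencies: predicting pooled frequencies from known m,
or inverting observed trajectories to infer relative m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountTable

#: the volcano rule: >= 4-fold change (|log2FC| >= 2) at adjusted p < 0.05
FC_THRESHOLD_DEFAULT = 2.0
ALPHA_DEFAULT = 0.05

_ADJUST_METHODS = {"BH": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


def to_frequencies(counts, pseudocount: float = 0.5) -> pd.DataFrame:
    """Library-size normalise counts to within-sample frequencies.

    f_ig = (count_ig + pseudocount) / sum_j (count_jg + pseudocount).  The
    symmetric pseudocount (default 0.5) keeps log ratios defined for variants
    driven to zero counts by strong depletion.
    """
    if isinstance(counts, CountTable):
        counts = counts.counts
    df = pd.DataFrame(counts).astype(float)
    if (df < 0).any().any():
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    zero = df.sum(axis=0) == 0
    if zero.any():
        raise ValueError(f"sample(s) with zero matched reads: {list(df.columns[zero])}")
    shifted = df + pseudocount
    return shifted / shifted.sum(axis=0)


def _resolve_pairing(
    num: pd.DataFrame, den: pd.DataFrame, pairing: Mapping[str, str] | None
) -> dict[str, str]:
    if pairing is None:
        if set(num.columns) != set(den.columns):
            raise ValueError(
                "no pairing given and sample names differ between the two tables; "
                "provide an explicit replicate pairing"
            )
        pairing = {c: c for c in num.columns}
    missing_num = [c for c in pairing if c not in num.columns]
    missing_den = [c for c in pairing.values() if c not in den.columns]
    if missing_num or missing_den:
        raise ValueError(f"unpaired replicates: {missing_num + missing_den}")
    return dict(pairing)


def log2_fold_change(
    freq_end: pd.DataFrame,
    freq_start: pd.DataFrame,
    pairing: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-variant, per-replicate log2(f_end / f_start).

    ``pairing`` maps each end-sample column to its start-sample column;
    replicate k is always paired with replicate k, never cross-paired.  With
    ``None``, identically named columns are paired.
    """
    pairing = _resolve_pairing(freq_end, freq_start, pairing)
    if not freq_end.index.equals(freq_start.index):
        freq_start = freq_start.reindex(freq_end.index)
        if freq_start.isna().any().any():
            raise ValueError("paired samples do not share the same genotype set")
    out = {}
    for end_col, start_col in pairing.items():
        if (freq_end[end_col] <= 0).any() or (freq_start[start_col] <= 0).any():
            raise ValueError("frequencies must be strictly positive (apply a pseudocount)")
        out[end_col] = np.log2(freq_end[end_col] / freq_start[start_col])
    return pd.DataFrame(out)


def condition_contrast(
    freq_condition: pd.DataFrame,
    freq_reference: pd.DataFrame,
    pairing: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-variant, per-replicate log2 ratio of a test condition over the
    reference condition (the reference goes in the denominator)."""
    return log2_fold_change(freq_condition, freq_reference, pairing)


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t test (unequal variances, Satterthwaite df).

    Degenerate case: when both groups have zero variance the statistic is 0
    (p = 1) for equal means and ±inf (p = 0) otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        return WelchResult(math.copysign(math.inf, a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0)
    with warnings.catch_warnings():
        # near-identical groups are an expected regime here (variants pinned at
        # the pseudocount floor); scipy's precision-loss warning is benign
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiplicity-adjust p-values (step-up Benjamini-Hochberg by default;
    "holm" and "bonferroni" are available).  Input order is preserved."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    if len(p) == 0:
        return p
    return np.clip(multipletests(p, method=_ADJUST_METHODS[method])[1], 0.0, 1.0)


def classify_volcano(
    log2fc_mean: float,
    adj_p: float,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> str:
    """Volcano call for one variant: 'enriched', 'depleted' or 'neutral'.

    A |log2FC| exactly at the threshold counts (the rule is >= 4-fold)."""
    if adj_p < alpha:
        if log2fc_mean >= fc_threshold:
            return "enriched"
        if log2fc_mean <= -fc_threshold:
            return "depleted"
    return "neutral"


def enrichment_table(
    freq_num: pd.DataFrame,
    freq_den: pd.DataFrame,
    pairing: Mapping[str, str] | None = None,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    method: str = "BH",
) -> pd.DataFrame:
    """Full per-variant enrichment summary for one contrast.

    Combines the per-replicate log2 fold-changes (mean ± sd), a Welch test of
    the per-replicate log2 frequencies of numerator vs denominator group, BH
    adjustment across variants, and the volcano class.  Columns:
    log2fc_rep1..K, log2fc_mean, log2fc_sd, p_value, adj_p, class.
    """
    pairing = _resolve_pairing(freq_num, freq_den, pairing)
    lfc = log2_fold_change(freq_num, freq_den, pairing)
    k = lfc.shape[1]
    reps = pd.DataFrame(
        lfc.to_numpy(), index=lfc.index, columns=[f"log2fc_rep{i+1}" for i in range(k)]
    )
    log_num = np.log2(freq_num[list(pairing.keys())].to_numpy())
    log_den = np.log2(freq_den[list(pairing.values())].to_numpy())
    pvals = np.array(
        [welch_t_test(log_num[i], log_den[i]).p for i in range(log_num.shape[0])]
    )
    adj = adjust_pvalues(pvals, method=method)
    out = reps.copy()
    out["log2fc_mean"] = lfc.mean(axis=1)
    out["log2fc_sd"] = lfc.std(axis=1, ddof=1)
    out["p_value"] = pvals
    out["adj_p"] = adj
    out["class"] = [
        classify_volcano(m, q, fc_threshold, alpha) for m, q in zip(out["log2fc_mean"], adj)
    ]
    out.index.name = "variant_id"
    return out


# ---------------------------------------------------------------------------
# observed vs predicted pooled outcomes
# ---------------------------------------------------------------------------


def predict_frequencies(f0: Sequence[float], m: Sequence[float], cycles: int) -> np.ndarray:
    """Closed-form pooled outcome from single-strain mating efficiencies:
    f_i(T) = f_i(0) * m_i^T / sum_j f_j(0) * m_j^T  (0^0 = 1)."""
    f0 = np.asarray(f0, dtype=float)
    m = np.asarray(m, dtype=float)
    if abs(f0.sum() - 1.0) > 1e-9 or np.any(f0 < 0):
        raise ValueError("f0 must be a frequency vector")
    if np.any(m < 0):
        raise ValueError("mating efficiencies must be >= 0")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    weight = f0 * np.power(m, cycles)
    total = weight.sum()
    if total <= 0:
        raise ValueError("all lineages have zero efficiency: predicted population extinct")
    return weight / total


def infer_efficiencies(
    f0,
    fT,
    cycles: int,
    reference_variant: str | int = "WT",
) -> pd.Series | np.ndarray:
    """Invert the closed-form predictor: m̂_i = (fT_i / f0_i)^(1/cycles),
    rescaled so the reference variant has m̂ = 1.

    Accepts pandas Series (reference by variant_id) or plain arrays
    (reference by integer position)."""
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    as_series = isinstance(f0, pd.Series) or isinstance(fT, pd.Series)
    f0_a = np.asarray(f0, dtype=float)
    fT_a = np.asarray(fT, dtype=float)
    if np.any(f0_a <= 0) or np.any(fT_a <= 0):
        raise ValueError(
            "frequencies must be strictly positive; apply a pseudocount upstream (to_frequencies)"
        )
    m_hat = np.power(fT_a / f0_a, 1.0 / cycles)
    if as_series:
        index = f0.index if isinstance(f0, pd.Series) else fT.index
        s = pd.Series(m_hat, index=index, name="m_hat")
        if reference_variant not in s.index:
            raise ValueError(f"reference variant {reference_variant!r} not present")
        return s / s[reference_variant]
    ref = int(reference_variant) if not isinstance(reference_variant, int) else reference_variant
    return m_hat / m_hat[ref]


@dataclass(frozen=True)
class PredictionComparison:
    """Agreement between observed pooled frequencies and the closed-form
    prediction from single-strain efficiencies."""

    observed: np.ndarray
    predicted: np.ndarray
    pearson_r: float
    r_squared: float


def compare_observed_predicted(observed, predicted) -> PredictionComparison:
    """Pearson's r (and r^2) between observed and predicted frequencies."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred):
        raise ValueError("observed and predicted must have equal length")
    if len(obs) < 3:
        raise ValueError("need at least 3 points")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("zero variance in observed or predicted vector")
    r = float(stats.pearsonr(obs, pred).statistic)
    return PredictionComparison(observed=obs, predicted=pred, pearson_r=r, r_squared=r * r)
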