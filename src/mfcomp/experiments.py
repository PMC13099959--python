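"""Canonical synthetic experiments of the analysis.

These are the study designs the package's validation rests on, each an
importable computation returning plain tables:

* closed-form agreement — the stochastic simulator against the analytic
  trajectory f_i(T) ∝ f_i(0) m_i^T in deterministic mode;
* demultiplexing fidelity — reads at a known error rate against the analytic
  recovery expectation (1 - e)^30;
* efficiency recovery — inferring per-variant relative mating efficiency from
  sequenced cycle-0 / cycle-5 samples of a deterministic competition;
* pH recapitulation — the full pipeline on a pool with one alkaline-activated
  and one acid-activated variant among flat competitors, checking that the
  cross-pH contrast recovers exactly those variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitness import infer_efficiencies, predict_frequencies, to_frequencies
from .library import VariantLibrary, enumerate_library
from .pipeline import contrasts_vs_reference
from .quantify import CountTable, count_samples, demux_accuracy
from .simulate import (
    Condition,
    FitnessProfile,
    PHResponse,
    SimConfig,
    profiles_from_presets,
    run_competition,
    simulate_experiment,
    simulate_reads,
)


def closed_form_agreement(n_draws: int = 100, seed: int = 0) -> float:
    """Max relative deviation between simulated (drift-free) and closed-form
    final frequencies over random small pools (N <= 10, T <= 10)."""
    rng = np.random.default_rng(seed)
    base = enumerate_library(variable_positions={2})
    worst = 0.0
    for _ in range(n_draws):
        n = int(rng.integers(2, 11))
        lib = VariantLibrary(variants=base.variants[:n], wt_peptide=base.wt_peptide)
        m = rng.uniform(0.05, 1.0, size=n)
        profiles = {
            vid: FitnessProfile(vid, PHResponse("flat", m_max=mi))
            for vid, mi in zip(lib.variant_ids, m)
        }
        T = int(rng.integers(1, 11))
        cfg = SimConfig(cycles=T, replicates=1, drift_cells=None, seed=int(rng.integers(2**31)))
        (states,) = run_competition(lib, profiles, Condition("SSA", 5.5), cfg)
        expected = predict_frequencies(np.full(n, 1 / n), m, T)
        rel = np.abs(states[-1].frequencies - expected) / expected
        worst = max(worst, float(rel.max()))
    return worst


@dataclass
class DemuxFidelity:
    error_free_accuracy: float  # fraction of error-free reads assigned to source
    error_free_exact: bool  # counts identical to the multinomial draw
    noisy_accuracy: float  # source-assignment fraction at the given error rate
    noisy_matched: float  # fraction assigned to any genotype (incl. 1-nt cross-matches)
    expected_accuracy: float  # (1 - e)^(motif + barcode length)
    n_reads: int


def demux_fidelity(
    error_rate: float = 0.01, n_reads: int = 100_000, seed: int = 0
) -> DemuxFidelity:
    """Measure demultiplexing fidelity on uniform-pool reads with and without
    sequencing error."""
    from .quantify import count_sample

    lib = enumerate_library()
    f = np.full(len(lib), 1 / len(lib))
    clean_cfg = SimConfig(reads_per_sample=n_reads, error_rate=0.0, seed=seed)
    clean = simulate_reads(f, lib, clean_cfg, "clean", rng=np.random.default_rng(seed))
    clean_counts = count_sample(clean, lib)
    noisy_cfg = SimConfig(reads_per_sample=n_reads, error_rate=error_rate, seed=seed)
    noisy = simulate_reads(f, lib, noisy_cfg, "noisy", rng=np.random.default_rng(seed + 1))
    noisy_counts = count_sample(noisy, lib)
    return DemuxFidelity(
        error_free_accuracy=demux_accuracy(clean, lib),
        error_free_exact=bool((clean_counts.counts == clean.true_counts).all())
        and clean_counts.unmatched == 0,
        noisy_accuracy=demux_accuracy(noisy, lib),
        noisy_matched=float(noisy_counts.counts.sum() / noisy_counts.total_reads),
        expected_accuracy=(1.0 - error_rate) ** 30,
        n_reads=n_reads,
    )


def efficiency_recovery_experiment(
    reads_per_sample: int = 1_000_000,
    cycles: int = 5,
    seed: int = 0,
    min_final_frequency: float = 1e-4,
) -> pd.DataFrame:
    """Recover per-variant relative mating efficiency from sequenced samples.

    All 153 genotypes get known flat profiles: most efficiencies are spread
    evenly over [0.4, 0.9] and every tenth variant is a weak mater (m = 0.2)
    that five cycles of selection push far below the reporting threshold.
    Variants are kept clear of the threshold's immediate neighbourhood, where
    read-sampling noise alone would dominate the inferred efficiency.  The
    pool competes deterministically for ``cycles`` cycles and the cycle-0 /
    final-cycle pools are sequenced and demultiplexed.  Returns a per-variant
    table with true and inferred relative m (reference WT) and the
    deterministic final frequency used for the reporting filter.
    """
    lib = enumerate_library()
    n = len(lib)
    m_true = 0.4 + 0.5 * np.arange(n) / (n - 1)
    m_true[10::10] = 0.2  # weak maters, driven below the reporting threshold
    profiles = {
        vid: FitnessProfile(vid, PHResponse("flat", m_max=mi))
        for vid, mi in zip(lib.variant_ids, m_true)
    }
    cfg = SimConfig(
        cycles=cycles, replicates=1, reads_per_sample=reads_per_sample,
        error_rate=0.0, drift_cells=None, seed=seed,
    )
    (states,) = run_competition(lib, profiles, Condition("SSA", 5.5), cfg)
    f0_true, fT_true = states[0].frequencies, states[-1].frequencies

    s0 = simulate_reads(f0_true, lib, cfg, "c0", rng=np.random.default_rng(seed + 10))
    sT = simulate_reads(fT_true, lib, cfg, "cT", rng=np.random.default_rng(seed + 11))
    table = count_samples({"c0": s0, "cT": sT}, lib)
    freqs = to_frequencies(table)
    m_hat = infer_efficiencies(freqs["c0"], freqs["cT"], cycles, reference_variant="WT")

    wt = lib.variant_ids.index("WT")
    out = pd.DataFrame(
        {
            "m_true_relative": m_true / m_true[wt],
            "m_inferred_relative": m_hat.to_numpy(),
            "final_frequency": fT_true,
        },
        index=pd.Index(lib.variant_ids, name="variant_id"),
    )
    out["reportable"] = out["final_frequency"] > min_final_frequency
    out["relative_error"] = (
        np.abs(out["m_inferred_relative"] - out["m_true_relative"]) / out["m_true_relative"]
    )
    return out


@dataclass
class Recapitulation:
    """Result of the full-pipeline pH experiment."""

    library: VariantLibrary
    count_table: CountTable
    contrasts: dict[str, pd.DataFrame]
    alkaline_variant: str
    acid_variant: str

    @property
    def flat_variants(self) -> list[str]:
        return [
            v for v in self.library.variant_ids if v not in (self.alkaline_variant, self.acid_variant)
        ]


def ph_recapitulation_experiment(
    reads_per_sample: int = 200_000,
    seed: int = 0,
    replicates: int = 3,
    cycles: int = 5,
) -> Recapitulation:
    """Simulate the pooled pH screen and run the contrast analysis.

    153 genotypes at equal starting frequency: P6H carries the
    alkaline-activated profile (near-sterile at pH 5.5), P6D the acid-shifted
    profile, and the remaining 151 the flat wild-type-like profile.  Three
    replicates compete for five cycles on SSA at pH 4.0, 5.5 and 7.0; the
    final-cycle samples are sequenced, demultiplexed and contrasted against
    the pH 5.5 reference.
    """
    lib = enumerate_library()
    profiles = profiles_from_presets(lib, {"P6H": "P6H-like", "P6D": "P6D-like"})
    conditions = [Condition("SSA", 4.0), Condition("SSA", 5.5), Condition("SSA", 7.0)]
    cfg = SimConfig(
        cycles=cycles, replicates=replicates, reads_per_sample=reads_per_sample,
        error_rate=0.0, seed=seed,
    )
    manifest, samples = simulate_experiment(
        lib, profiles, conditions, cfg, sample_cycles=[cycles]
    )
    table = count_samples(samples, lib, samples=manifest.set_index("sample"))
    contrasts = contrasts_vs_reference(table, reference_pH=5.5)
    return Recapitulation(
        library=lib,
        count_table=table,
        contrasts=contrasts,
        alkaline_variant="P6H",
        acid_variant="P6D",
    )
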