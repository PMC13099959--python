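"""Forward simulation of pooled mating-germination competition and of the
amplicon reads that quantify it.

The pooled assay mixes all genotypes at equal abundance and repeats cycles of
(i) mating and sporulation on solid medium, (ii) ethanol killing of unmated
vegetative cells, and (iii) spore outgrowth.  Because *S. pombe* cannot mate
using exogenous pheromone alone, selection is cell-autonomous: a genotype's
survival through one cycle is proportional to its own mating efficiency m
under the prevailing condition.  The per-cycle update is therefore
multiplicative,

    f'_i = f_i * m_i / sum_j f_j * m_j,

with an analogous update f'_i ∝ f_i * w_i^g for the non-mating (rich-medium
passage) control regime, where w is vegetative fitness per generation.
Germination and outgrowth between mating cycles are treated as fitness-neutral.

Mating efficiency responds to environmental pH through a logistic curve
(alkaline- or acid-activated) or is flat; presets mimic the qualitative
single-strain profiles of the panel's landmark variants.

Reads are 75-bp single-end amplicons carrying the constant AAGAAT hexamer
followed by the 24-nt genotype barcode at a random offset, padded with random
bases, with an optional uniform per-base substitution error.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library import BARCODE_LENGTH, MOTIF, VariantLibrary

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MOTIF_ARR = np.frombuffer(MOTIF.encode(), dtype=np.uint8)
_INSERT_LEN = len(MOTIF) + BARCODE_LENGTH  # 30 nt that must survive error-free


class PopulationExtinctError(RuntimeError):
    """Raised when no lineage mates and the pool cannot survive a cycle."""


@dataclass(frozen=True)
class Condition:
    """One environmental regime of the competition."""

    medium: str
    pH: float
    temperature_C: float = 30.0
    mating_permissive: bool = True

    def __post_init__(self) -> None:
        if not (3.0 <= self.pH <= 10.0):
            raise ValueError(f"pH {self.pH} outside the supported range [3, 10]")

    @property
    def label(self) -> str:
        return f"{self.medium}_pH{self.pH:g}"


@dataclass(frozen=True)
class PHResponse:
    """Parameters of a pH-response curve for mating efficiency.

    kind:
        "flat"     -> m(pH) = m_max
        "alkaline" -> m(pH) = m_max * logistic((pH - ph_mid) / scale)
        "acid"     -> m(pH) = m_max * logistic((ph_mid - pH) / scale)
    The result is clipped to [0, 1]; m_max = 0 gives a dead (sterile) profile.
    """

    kind: str = "flat"
    m_max: float = 0.5
    ph_mid: float = 6.5
    scale: float = 0.4

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "alkaline", "acid"):
            raise ValueError(f"unknown pH-response kind {self.kind!r}")
        if not (0.0 <= self.m_max <= 1.0):
            raise ValueError("m_max must lie in [0, 1]")
        if self.kind != "flat" and self.scale <= 0:
            raise ValueError("scale must be positive")


def ph_response(m_params: PHResponse, pH: float) -> float:
    """Mating efficiency of a profile at the given pH, in [0, 1]."""
    if not (3.0 <= pH <= 10.0):
        raise ValueError(f"pH {pH} outside the supported range [3, 10]")
    if m_params.kind == "flat":
        m = m_params.m_max
    else:
        z = (pH - m_params.ph_mid) / m_params.scale
        if m_params.kind == "acid":
            z = -z
        m = m_params.m_max / (1.0 + math.exp(-z))
    return float(min(1.0, max(0.0, m)))


#: qualitative single-strain pH profiles of the panel's landmark variants:
#: WT and Y7W mate well across the whole gradient; P6D is acid-activated and
#: fails above ~pH 6.5; P6H is virtually sterile at pH 5.5 but reaches ~50%
#: mating at pH 7.5-8.5; "dead" never mates.
PRESETS: dict[str, PHResponse] = {
    "WT-like": PHResponse(kind="flat", m_max=0.55),
    "Y7W-like": PHResponse(kind="flat", m_max=0.55),
    "P6D-like": PHResponse(kind="acid", m_max=0.5, ph_mid=4.8, scale=0.3),
    "P6H-like": PHResponse(kind="alkaline", m_max=0.5, ph_mid=6.5, scale=0.3),
    "dead": PHResponse(kind="flat", m_max=0.0),
}


@dataclass(frozen=True)
class FitnessProfile:
    """Ground-truth fitness of one genotype: condition-dependent mating
    efficiency m and vegetative relative fitness w per generation."""

    variant_id: str
    m_params: PHResponse = PHResponse()
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("vegetative fitness w must be > 0")

    def mating_efficiency(self, condition: Condition) -> float:
        return ph_response(self.m_params, condition.pH)


def profiles_from_presets(
    library: VariantLibrary,
    assignments: Mapping[str, str] | None = None,
    default: str = "WT-like",
    w: Mapping[str, float] | None = None,
) -> dict[str, FitnessProfile]:
    """Build a profile per library variant from preset names.

    ``assignments`` maps variant_id -> preset name for the exceptions; every
    other variant receives the ``default`` preset.  ``w`` optionally overrides
    vegetative fitness per variant.
    """
    assignments = dict(assignments or {})
    w = dict(w or {})
    unknown = set(assignments) - set(library.variant_ids)
    if unknown:
        raise ValueError(f"profile assignments for unknown variants: {sorted(unknown)}")
    out = {}
    for vid in library.variant_ids:
        preset = assignments.get(vid, default)
        out[vid] = FitnessProfile(variant_id=vid, m_params=PRESETS[preset], w=w.get(vid, 1.0))
    return out


@dataclass(frozen=True)
class PopulationState:
    """Relative genotype abundances after a given number of cycles."""

    frequencies: np.ndarray
    cycle: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if self.cycle < 0:
            raise ValueError("cycle must be >= 0")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of one simulated competition experiment.

    Defaults mirror the pooled assay: 5 mating-germination cycles, 3
    biological replicates, 75-bp reads at a depth of 400,000 reads per sample,
    and a bottleneck of ~1.5e7 cells (1e5 cells per genotype) between cycles.
    """

    cycles: int = 5
    replicates: int = 3
    reads_per_sample: int = 400_000
    error_rate: float = 0.0
    drift_cells: int | None = 15_300_000
    seed: int = 0
    read_length: int = 75

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.read_length < _INSERT_LEN:
            raise ValueError(f"read_length must be >= {_INSERT_LEN}")


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return f


def mating_cycle_update(freqs: Sequence[float], m: Sequence[float]) -> np.ndarray:
    """One mating-sporulation-ethanol cycle: only mated cells survive.

    f'_i = f_i * m_i / sum_j f_j * m_j.
    """
    f = _check_freqs(freqs)
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("mating efficiencies must lie in [0, 1]")
    mean_m = float(f @ m)
    if mean_m <= 0:
        raise PopulationExtinctError("no lineage mated; population extinct")
    return f * m / mean_m


def vegetative_passage_update(
    freqs: Sequence[float], w: Sequence[float], generations: int = 1
) -> np.ndarray:
    """One rich-medium passage without ethanol selection: f'_i ∝ f_i * w_i^g."""
    f = _check_freqs(freqs)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("vegetative fitness must be > 0")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    g = f * w**generations
    return g / g.sum()


def run_competition(
    library: VariantLibrary,
    profiles: Mapping[str, FitnessProfile],
    condition: Condition,
    config: SimConfig,
    generations_per_cycle: int = 1,
) -> list[list[PopulationState]]:
    """Simulate the pooled competition; returns one trajectory (states for
    cycles 0..config.cycles) per replicate.

    All genotypes start at equal frequency 1/N.  Each cycle applies the mating
    update under mating-permissive conditions, otherwise the vegetative
    passage update; with ``drift_cells`` set, frequencies are resampled
    multinomially at that bottleneck size after every cycle (seeded per
    replicate).
    """
    missing = [vid for vid in library.variant_ids if vid not in profiles]
    if missing:
        raise ValueError(f"profiles missing for variants: {missing[:5]}...")
    n = len(library)
    m = np.array([profiles[vid].mating_efficiency(condition) for vid in library.variant_ids])
    w = np.array([profiles[vid].w for vid in library.variant_ids])

    rep_seeds = np.random.SeedSequence(config.seed).spawn(config.replicates)
    trajectories = []
    for rep in range(config.replicates):
        rng = np.random.default_rng(rep_seeds[rep])
        f = np.full(n, 1.0 / n)
        states = [PopulationState(frequencies=f, cycle=0)]
        for cycle in range(1, config.cycles + 1):
            if condition.mating_permissive:
                f = mating_cycle_update(f, m)
            else:
                f = vegetative_passage_update(f, w, generations_per_cycle)
            if config.drift_cells is not None:
                f = rng.multinomial(config.drift_cells, f) / config.drift_cells
            states.append(PopulationState(frequencies=f, cycle=cycle))
        trajectories.append(states)
    return trajectories


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSample:
    """Amplicon reads for one sequencing sample plus its ground truth."""

    sample_name: str
    records: list[tuple[str, str, str]]  # (read id, sequence, quality)
    true_counts: pd.Series  # genotype -> number of reads drawn
    sources: list[str] | None = None  # per-read source genotype, read order

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [seq for _, seq, _ in self.records]

    def write(self, path: str | Path) -> Path:
        return write_fastq(self.records, path)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> Path:
    """Write 4-line FASTQ records; gzip-compresses when the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path


def _count_motif(row: np.ndarray) -> int:
    return row.tobytes().count(MOTIF.encode())


def simulate_reads(
    freqs: Sequence[float],
    library: VariantLibrary,
    config: SimConfig,
    sample_name: str,
    rng: np.random.Generator | None = None,
) -> SimulatedSample:
    """Draw reads for one sample.

    Genotype counts are multinomial with probabilities equal to ``freqs``.
    Each read is random padding + AAGAAT + barcode + random padding at a
    random motif offset in [0, read_length - 30]; pads are regenerated if they
    would introduce an additional AAGAAT occurrence.  Substitution errors are
    then applied uniformly at ``config.error_rate`` per base.  Quality is a
    constant 'I' string.
    """
    f = _check_freqs(freqs)
    if len(f) != len(library):
        raise ValueError("frequency vector length does not match the library")
    if config.reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_reads = config.reads_per_sample
    L = config.read_length
    counts = rng.multinomial(n_reads, f)
    variant_ids = library.variant_ids
    barcodes = [v.barcode for v in library.variants]

    offsets = rng.integers(0, L - _INSERT_LEN + 1, size=n_reads)
    reads = _BASES[rng.integers(0, 4, size=(n_reads, L))]

    # paste motif + barcode into each read at its offset
    inserts = np.empty((n_reads, _INSERT_LEN), dtype=np.uint8)
    row = 0
    source = np.empty(n_reads, dtype=object)
    for gi, c in enumerate(counts):
        if c == 0:
            continue
        ins = np.frombuffer((MOTIF + barcodes[gi]).encode(), dtype=np.uint8)
        inserts[row : row + c] = ins
        source[row : row + c] = variant_ids[gi]
        row += c
    for i in range(n_reads):
        o = offsets[i]
        reads[i, o : o + _INSERT_LEN] = inserts[i]

    # regenerate pads that created a second motif occurrence (rare)
    for i in range(n_reads):
        while _count_motif(reads[i]) > 1:
            o = offsets[i]
            if o:
                reads[i, :o] = _BASES[rng.integers(0, 4, size=o)]
            tail = L - o - _INSERT_LEN
            if tail:
                reads[i, o + _INSERT_LEN :] = _BASES[rng.integers(0, 4, size=tail)]

    if config.error_rate > 0:
        err = rng.random((n_reads, L)) < config.error_rate
        n_err = int(err.sum())
        if n_err:
            # substitute with one of the 3 other bases, uniformly
            idx = np.searchsorted(_BASES, reads[err])
            shifted = (idx + rng.integers(1, 4, size=n_err)) % 4
            flat = reads[err]
            flat[:] = _BASES[shifted]
            reads[err] = flat

    qual = "I" * L
    records = [
        (f"{sample_name}:{i:07d}", reads[i].tobytes().decode(), qual) for i in range(n_reads)
    ]
    true_counts = pd.Series(counts, index=pd.Index(variant_ids, name="variant_id"), name=sample_name)
    return SimulatedSample(
        sample_name=sample_name,
        records=records,
        true_counts=true_counts,
        sources=list(source),
    )


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "sample",
    "fastq_path",
    "medium",
    "pH",
    "temperature_C",
    "cycle",
    "replicate",
    "seed",
]


def simulate_experiment(
    library: VariantLibrary,
    profiles: Mapping[str, FitnessProfile],
    conditions: Sequence[Condition],
    config: SimConfig,
    outdir: str | Path | None = None,
    sample_cycles: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, dict[str, SimulatedSample]]:
    """Run every condition x replicate, sequence the requested cycles
    (default: cycle 0 and the final cycle), and return (manifest, samples).

    When ``outdir`` is given, FASTQ files and a ``samples.tsv`` manifest are
    written there; otherwise reads stay in memory and ``fastq_path`` is empty.
    Per-sample seeds are derived deterministically from ``config.seed`` so the
    whole experiment is reproducible from the root seed alone.
    """
    if sample_cycles is None:
        sample_cycles = [0, config.cycles]
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    samples: dict[str, SimulatedSample] = {}
    for ci, condition in enumerate(conditions):
        cond_seed = int(np.random.SeedSequence([config.seed, ci]).generate_state(1)[0] % 2**31)
        cond_cfg = replace(config, seed=cond_seed)
        trajectories = run_competition(library, profiles, condition, cond_cfg)
        for rep, states in enumerate(trajectories, start=1):
            for cycle in sample_cycles:
                name = f"{condition.label}_c{cycle}_r{rep}"
                sample_seed = int(
                    np.random.SeedSequence([config.seed, ci, rep, cycle]).generate_state(1)[0]
                    % 2**31
                )
                sample = simulate_reads(
                    states[cycle].frequencies,
                    library,
                    config,
                    name,
                    rng=np.random.default_rng(sample_seed),
                )
                samples[name] = sample
                fastq_path = ""
                if outdir is not None:
                    fastq_path = str(outdir / f"{name}.fastq")
                    sample.write(fastq_path)
                rows.append(
                    (
                        name,
                        fastq_path,
                        condition.medium,
                        condition.pH,
                        condition.temperature_C,
                        cycle,
                        rep,
                        sample_seed,
                    )
                )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if outdir is not None:
        manifest.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return manifest, samples
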