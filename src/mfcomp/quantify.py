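"""Demultiplex amplicon reads into per-genotype counts.

Each amplicon read carries the constant hexamer AAGAAT immediately upstream of
the 24-nt barcode encoding mature-peptide residues 1-8.  Quantification finds
the first motif occurrence, takes the following 24 bases, and assigns the read
by exact match against the library's barcode index.  Reads lacking the motif,
with fewer than 24 downstream bases, or with an unknown barcode are tallied as
``unmatched`` — never silently dropped, so matched + unmatched = total on
every sample.

Exact matching is the default because barcodes of single-substitution
neighbours can differ by as little as one nucleotide; an optional
Hamming-distance-1 rescue exists but its assignments are reported separately.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import BARCODE_LENGTH, MOTIF, VariantLibrary

#: total read depth the study's samples met; used as the default depth check
MIN_READS_DEFAULT = 400_000


def extract_barcode(read_sequence: str) -> str | None:
    """Return the 24 bases following the first AAGAAT occurrence, or ``None``
    if the motif is absent or fewer than 24 bases remain downstream."""
    idx = read_sequence.find(MOTIF)
    if idx < 0:
        return None
    start = idx + len(MOTIF)
    if len(read_sequence) - start < BARCODE_LENGTH:
        return None
    return read_sequence[start : start + BARCODE_LENGTH]


def _hamming1_neighbours(kmer: str) -> Iterable[str]:
    for i, base in enumerate(kmer):
        for alt in "ACGT":
            if alt != base:
                yield kmer[:i] + alt + kmer[i + 1 :]


@dataclass
class SampleCounts:
    """Demultiplexing result for one sample."""

    counts: pd.Series  # exact-match counts, indexed by variant_id
    unmatched: int
    total_reads: int
    rescued: pd.Series | None = None  # Hamming-1 assignments, kept separate

    def __post_init__(self) -> None:
        matched = int(self.counts.sum())
        rescued = 0 if self.rescued is None else int(self.rescued.sum())
        if matched + rescued + self.unmatched != self.total_reads:
            raise ValueError("count conservation violated: matched + unmatched != total")


def _iter_sequences(reads) -> Iterable[str]:
    """Yield read sequences from a FASTQ path (.gz ok) or an in-memory
    iterable of sequences / (id, seq, qual) tuples / SimulatedSample."""
    if hasattr(reads, "records"):  # SimulatedSample
        reads = reads.records
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    yield seq
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc
    else:
        for item in reads:
            yield item[1] if isinstance(item, tuple) else item


def count_sample(reads, library: VariantLibrary, hamming1_rescue: bool = False) -> SampleCounts:
    """Demultiplex one sample.

    ``reads`` may be a FASTQ path (optionally gzipped) or any iterable of read
    sequences (or (id, seq, qual) tuples, or a ``SimulatedSample``).
    """
    if not library.barcode_index:
        raise ValueError("library barcode index is empty")
    index = library.barcode_index
    tally: dict[str, int] = dict.fromkeys(library.variant_ids, 0)
    rescue_tally: dict[str, int] = dict.fromkeys(library.variant_ids, 0) if hamming1_rescue else {}
    unmatched = 0
    total = 0
    for seq in _iter_sequences(reads):
        total += 1
        barcode = extract_barcode(seq)
        vid = index.get(barcode) if barcode is not None else None
        if vid is not None:
            tally[vid] += 1
            continue
        if hamming1_rescue and barcode is not None:
            hits = {index[n] for n in _hamming1_neighbours(barcode) if n in index}
            if len(hits) == 1:  # unambiguous single-mismatch rescue only
                rescue_tally[hits.pop()] += 1
                continue
        unmatched += 1
    idx = pd.Index(library.variant_ids, name="variant_id")
    return SampleCounts(
        counts=pd.Series(tally, name="count").reindex(idx),
        unmatched=unmatched,
        total_reads=total,
        rescued=pd.Series(rescue_tally, name="rescued").reindex(idx) if hamming1_rescue else None,
    )


@dataclass
class CountTable:
    """Genotype x sample count matrix with per-sample metadata.

    Invariant: per sample, column sum of ``counts`` + ``unmatched`` equals
    ``total_reads``.
    """

    counts: pd.DataFrame  # genotypes x samples, integer
    unmatched: pd.Series  # per sample
    total_reads: pd.Series  # per sample
    samples: pd.DataFrame | None = None  # metadata indexed by sample name

    def __post_init__(self) -> None:
        matched = self.counts.sum(axis=0)
        if not ((matched + self.unmatched) == self.total_reads).all():
            raise ValueError("count conservation violated in CountTable")

    @property
    def matched_reads(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.loc["unmatched"] = self.unmatched
        out.loc["total_reads"] = self.total_reads
        out.to_csv(path, sep="\t", index_label="genotype")

    @classmethod
    def from_tsv(cls, path: str | Path, samples: pd.DataFrame | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="genotype")
        if "unmatched" not in df.index or "total_reads" not in df.index:
            raise ValueError("counts TSV must carry 'unmatched' and 'total_reads' rows")
        unmatched = df.loc["unmatched"].astype(int)
        total = df.loc["total_reads"].astype(int)
        counts = df.drop(index=["unmatched", "total_reads"]).astype(int)
        return cls(counts=counts, unmatched=unmatched, total_reads=total, samples=samples)


def count_samples(
    sample_reads: Mapping[str, object],
    library: VariantLibrary,
    samples: pd.DataFrame | None = None,
    hamming1_rescue: bool = False,
) -> CountTable:
    """Demultiplex a set of samples into one CountTable.

    ``sample_reads`` maps sample name -> FASTQ path or in-memory reads;
    ``samples`` is optional per-sample metadata (indexed by sample name).
    """
    cols, unmatched, totals = {}, {}, {}
    for name, reads in sample_reads.items():
        sc = count_sample(reads, library, hamming1_rescue=hamming1_rescue)
        cols[name] = sc.counts  # rescued assignments are never merged into exact counts
        unmatched[name] = sc.unmatched + (0 if sc.rescued is None else int(sc.rescued.sum()))
        totals[name] = sc.total_reads
    counts = pd.DataFrame(cols)
    counts.columns.name = "sample"
    return CountTable(
        counts=counts,
        unmatched=pd.Series(unmatched),
        total_reads=pd.Series(totals),
        samples=samples,
    )


def count_manifest(
    manifest: pd.DataFrame, library: VariantLibrary, hamming1_rescue: bool = False
) -> CountTable:
    """Demultiplex every FASTQ listed in a simulator-style sample manifest."""
    meta = manifest.set_index("sample")
    return count_samples(
        dict(zip(manifest["sample"], manifest["fastq_path"])),
        library,
        samples=meta,
        hamming1_rescue=hamming1_rescue,
    )


def demux_accuracy(sample, library: VariantLibrary) -> float:
    """Fraction of a simulated sample's reads assigned to their source
    genotype.

    A read is correct iff its motif and barcode survived error-free, so the
    expectation is (1 - error_rate)^30.  This is slightly below the fraction
    assigned to *any* genotype: a single barcode error can turn one genotype's
    barcode into a 1-nt-neighbour genotype's barcode (codon-derived barcodes
    necessarily have such neighbours), and those misassignments still match.
    """
    if getattr(sample, "sources", None) is None:
        raise ValueError("sample carries no per-read source annotation")
    index = library.barcode_index
    correct = 0
    for (_rid, seq, _q), src in zip(sample.records, sample.sources):
        barcode = extract_barcode(seq)
        if barcode is not None and index.get(barcode) == src:
            correct += 1
    return correct / len(sample.records)


def check_depth(count_table: CountTable, min_reads: int = MIN_READS_DEFAULT) -> pd.DataFrame:
    """Flag samples whose matched depth falls below ``min_reads``.

    Returns a per-sample table with the matched read count and a boolean
    ``passed`` column; no data are ever dropped.
    """
    matched = count_table.matched_reads
    return pd.DataFrame({"matched_reads": matched, "passed": matched >= min_reads})
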