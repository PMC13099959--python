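"""Single-substitution M-factor variant library and barcode reference.

The mature M-factor pheromone of *Schizosaccharomyces pombe* is a nine-residue
peptide (YTPKVPYMC, C-terminally farnesylated and methyl-esterified).  A deep
mutational scanning panel substitutes each of the eight non-cysteine residues
with all 19 alternative amino acids, giving 152 substitution variants plus the
wild type: 153 genotypes in total.  Each genotype is identified in amplicon
reads by the 24-nt stretch of coding sequence covering residues 1-8
(8 codons x 3 nt), which serves as its barcode.

The published barcode sequences are not distributed with the panel, so this
module derives them from a deterministic one-codon-per-amino-acid table (by
default the most common *S. pombe* codon for each amino acid, shipped as
``data/spombe_codons.tsv``).  Any injective codon table yields a collision-free
barcode set with the same combinatorial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: canonical 20 amino acids, one-letter codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: mature wild-type M-factor peptide
WT_PEPTIDE = "YTPKVPYMC"

#: constant hexamer immediately upstream of the barcode in every amplicon read
MOTIF = "AAGAAT"

#: barcode length: 8 variable residues x 3 nt
BARCODE_LENGTH = 24

#: peptide residue i corresponds to precursor (mfm1) residue i + 30
#: (e.g. peptide P6H is the mfm1-P36H allele)
PRECURSOR_OFFSET = 30

LIBRARY_COLUMNS = ["variant_id", "position", "wt_residue", "sub_residue", "peptide", "barcode"]


def default_codon_map() -> dict[str, str]:
    """Load the shipped one-codon-per-amino-acid table (most common
    *S. pombe* codon for each amino acid)."""
    with resources.files("mfcomp.data").joinpath("spombe_codons.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["amino_acid"], df["codon"]))


@dataclass(frozen=True)
class PeptideVariant:
    """One genotype of the panel: a peptide sequence and its DNA barcode.

    ``position`` is the 1-based index of the substituted residue in the mature
    peptide (0 for the wild type, which substitutes nothing).
    """

    variant_id: str
    position: int
    wt_residue: str
    sub_residue: str
    peptide: str
    barcode: str

    def __post_init__(self) -> None:
        if len(self.peptide) != 9:
            raise ValueError(f"{self.variant_id}: peptide must have 9 residues")
        if self.peptide[-1] != "C":
            raise ValueError(f"{self.variant_id}: residue 9 must be the farnesylated cysteine")
        if len(self.barcode) != BARCODE_LENGTH:
            raise ValueError(f"{self.variant_id}: barcode must be {BARCODE_LENGTH} nt")


@dataclass
class VariantLibrary:
    """Ordered variant panel plus the barcode -> variant_id index used for
    demultiplexing."""

    variants: list[PeptideVariant]
    wt_peptide: str
    barcode_index: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant_ids are not unique")
        index = {v.barcode: v.variant_id for v in self.variants}
        if len(index) != len(self.variants):
            raise ValueError("barcodes are not unique (codon map not injective?)")
        self.barcode_index = index

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def get(self, variant_id: str) -> PeptideVariant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (v.variant_id, v.position, v.wt_residue, v.sub_residue, v.peptide, v.barcode)
                for v in self.variants
            ],
            columns=LIBRARY_COLUMNS,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantLibrary":
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in LIBRARY_COLUMNS if c != "position"})
        missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"library TSV missing columns: {missing}")
        variants = [
            PeptideVariant(
                variant_id=row.variant_id,
                position=int(row.position),
                wt_residue=row.wt_residue,
                sub_residue=row.sub_residue,
                peptide=row.peptide,
                barcode=row.barcode,
            )
            for row in df.itertuples()
        ]
        wt = next((v.peptide for v in variants if v.variant_id == "WT"), variants[0].peptide)
        return cls(variants=variants, wt_peptide=wt)


def _encode(peptide_1_to_8: str, codon_map: Mapping[str, str]) -> str:
    return "".join(codon_map[aa] for aa in peptide_1_to_8)


def enumerate_library(
    wt_peptide: str = WT_PEPTIDE,
    variable_positions: Iterable[int] = range(1, 9),
    codon_map: Mapping[str, str] | None = None,
) -> VariantLibrary:
    """Enumerate WT plus every single-amino-acid substitution at the given
    positions.

    Variants are named ``<WTaa><position><SUBaa>`` on the 1-based
    mature-peptide coordinate and ordered by position, then substituted amino
    acid alphabetically, with WT first.  The barcode is the concatenated codon
    sequence of residues 1-8.

    Parameters
    ----------
    wt_peptide:
        Nine-residue mature peptide ending in the farnesylated cysteine.
    variable_positions:
        1-based residue indices to mutate; must be within 1..8 (position 9 is
        structurally required and never varied).
    codon_map:
        Injective amino-acid -> codon mapping; defaults to the shipped
        *S. pombe* table.
    """
    if len(wt_peptide) != 9:
        raise ValueError("wt_peptide must have exactly 9 residues")
    if wt_peptide[-1] != "C":
        raise ValueError("wt_peptide must end in the farnesylated cysteine (C)")
    positions = sorted(set(int(p) for p in variable_positions))
    if any(p < 1 or p > 8 for p in positions):
        raise ValueError("variable_positions must lie within 1..8")
    if codon_map is None:
        codon_map = default_codon_map()
    codons = {aa: codon_map[aa] for aa in AMINO_ACIDS}
    if len(set(codons.values())) != len(codons):
        raise ValueError("codon_map is not injective over the 20 amino acids; barcodes would collide")
    if any(len(c) != 3 or set(c) - set("ACGT") for c in codons.values()):
        raise ValueError("codon_map values must be 3-nt DNA codons")

    variants = [
        PeptideVariant(
            variant_id="WT",
            position=0,
            wt_residue="-",
            sub_residue="-",
            peptide=wt_peptide,
            barcode=_encode(wt_peptide[:8], codons),
        )
    ]
    for pos in positions:
        wt_aa = wt_peptide[pos - 1]
        for sub in AMINO_ACIDS:
            if sub == wt_aa:
                continue
            peptide = wt_peptide[: pos - 1] + sub + wt_peptide[pos:]
            variants.append(
                PeptideVariant(
                    variant_id=f"{wt_aa}{pos}{sub}",
                    position=pos,
                    wt_residue=wt_aa,
                    sub_residue=sub,
                    peptide=peptide,
                    barcode=_encode(peptide[:8], codons),
                )
            )
    return VariantLibrary(variants=variants, wt_peptide=wt_peptide)


def lookup_barcode(library: VariantLibrary, kmer: str) -> str | None:
    """Exact-match a 24-mer against the library; ``None`` when absent."""
    if len(kmer) != BARCODE_LENGTH:
        raise ValueError(f"barcode lookup requires a {BARCODE_LENGTH}-mer, got {len(kmer)} nt")
    return library.barcode_index.get(kmer)
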