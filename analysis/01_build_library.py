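#!/usr/bin/env python
"""Enumerate the M-factor single-substitution panel and write its barcode
reference.

Finding: substituting each of the eight non-cysteine residues of YTPKVPYMC
with the 19 alternative amino acids yields 152 variants; with wild type the
pooled panel has 153 genotypes, each tagged by a unique 24-nt barcode (the
codons of residues 1-8), and every barcode round-trips through the
demultiplexing index.
"""

from pathlib import Path

from mfcomp import enumerate_library, lookup_barcode

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    lib = enumerate_library()
    lib.to_tsv(OUT / "library.tsv")
    assert all(lookup_barcode(lib, v.barcode) == v.variant_id for v in lib)
    n_sub = sum(v.variant_id != "WT" for v in lib)
    print(f"panel: {n_sub} substitution variants + WT = {len(lib)} genotypes")
    print(f"barcodes: {len(lib.barcode_index)} unique 24-mers; reference -> results/library.tsv")


if __name__ == "__main__":
    main()
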