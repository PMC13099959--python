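# Methods

## The selection model

One mating–germination cycle of the pooled assay comprises mating and
sporulation on solid medium, ethanol killing of unmated vegetative cells, and
spore outgrowth in rich liquid. The model treats selection as cell-autonomous
and multiplicative: a genotype's representation among survivors of one cycle
is proportional to its own per-cell mating efficiency *m* under the prevailing
condition,

    f'_i = f_i m_i / Σ_j f_j m_j .

This rests on two biological assumptions. First, *S. pombe* cannot mate using
exogenous pheromone alone, so a variant cannot hitch-hike on competitors'
signalling — pooled outcomes should equal, and empirically do track,
predictions from single-strain efficiencies. Second, all genotypes share the
homothallic *h90* background and therefore an identical receptor context
during their pheromone-receiving phase; fitness differences are attributed to
the pheromone-producing phase only. Germination and outgrowth between cycles
are treated as fitness-neutral (all spores germinate in rich medium);
vegetative fitness *w* enters only in the non-mating control regime, where
the update is f'_i ∝ f_i w_i^g with g generations per passage (default 1).
Mating-type switching dynamics, diploid intermediates, partner choice, and
the redundancy of the three identical M-factor genes are not modelled; the
library is one barcode per genotype.

Without drift the T-cycle trajectory has the closed form
f_i(T) ∝ f_i(0) m_i^T (with 0^0 = 1), which serves three roles: an exact
oracle for the simulator (verified to 1e-12 relative), a predictor of pooled
outcomes from single-strain efficiencies, and — inverted as
m̂_i = (f_T,i/f_0,i)^(1/T), rescaled to the wild type — an estimator of
relative efficiency from sequenced pools. With `drift_cells` set, frequencies
are resampled multinomially at that bottleneck after each cycle; the default
of 1.53e7 cells mirrors the assay's inoculum of ~1e5 cells per genotype.

## pH-response profiles

Mating efficiency responds to pH as m(pH) = m_max · logistic((pH − mid)/s)
for alkaline-activated profiles, the mirrored form for acid-activated ones,
or a constant; results are clipped to [0, 1]. The shipped presets encode the
qualitative single-strain phenotypes of the panel's landmark variants:

| preset     | form                        | m(4.0) | m(5.5) | m(7.0) | m(8.5) |
|------------|-----------------------------|--------|--------|--------|--------|
| `WT-like`  | flat, m_max 0.55            | 0.55   | 0.55   | 0.55   | 0.55   |
| `Y7W-like` | flat, m_max 0.55            | 0.55   | 0.55   | 0.55   | 0.55   |
| `P6D-like` | acid, m_max 0.5, mid 4.8, s 0.3 | 0.47 | 0.044  | <0.01  | <0.01  |
| `P6H-like` | alkaline, m_max 0.5, mid 6.5, s 0.3 | <0.01 | 0.017 | 0.42 | 0.50 |
| `dead`     | flat, m_max 0               | 0      | 0      | 0      | 0      |

The alkaline preset makes the variant virtually sterile at pH 5.5 and near
its ~50% maximum above pH 7.5; the acid preset peaks at pH 4, exceeds its
pH 5.5 level several-fold, and produces essentially no mating above pH 6.5.
Both responsive presets deliberately leave the variant *near-sterile* at the
unfavourable pH rather than partially active: after five selection cycles
this pins its abundance at the pseudocount floor, where replicate log2
frequencies are nearly constant. A partially active off-state (final
frequency of order a few reads per sample) would put replicate counts in the
0–2 range, inflate the Welch variance, and make the cross-pH call
statistically unstable at realistic depth even though the fold-change is
huge — a property of low-count ratio statistics worth remembering when
choosing sequencing depth for real screens.

## Barcodes and the read model

Barcodes are the 24 nt of coding sequence covering peptide residues 1–8
(position 9, the farnesylated cysteine, is structurally fixed and never
varied). Because the published barcode sequences are not distributed, they
are derived from a deterministic one-codon-per-amino-acid table — by default
the most common *S. pombe* codon per amino acid, shipped as
`data/spombe_codons.tsv`. Any injective table reproduces the panel's
combinatorial structure; variants differing at one residue differ in exactly
one codon (1–3 nt). Variant names use 1-based mature-peptide coordinates
(P6H); the precursor (mfm1) coordinate is peptide position + 30, recorded as
`PRECURSOR_OFFSET`.

Simulated reads are 75 bp: random padding, the constant hexamer `AAGAAT`,
the barcode, more padding, with the motif at a uniformly random offset in
[0, 45] so that downstream code must search for the motif rather than slice a
fixed position. Pads are regenerated if they would introduce a second motif
occurrence. Sequencing error is substitution-only, uniform per base (default
0, study-like runs use 0.01); indels, PCR bias, paired ends and quality
modelling are out of scope, and quality strings are constant.

Demultiplexing takes the 24 bases after the *first* motif occurrence and
requires an exact barcode match; reads without motif, with a truncated
barcode, or with an unknown 24-mer increment `unmatched`, so
matched + unmatched = total on every sample. Exact matching is the default
because same-position variants can differ by a single nucleotide — no choice
of genetic-code-consistent codons can avoid this (20 codewords of length 3
over 4 letters cannot all be pairwise distance ≥ 2) — so a Hamming-1 rescue
would risk systematic misassignment; the optional rescue mode therefore
reports its assignments separately and never merges them. The same fact
shapes the error response: a read whose motif and barcode survive error-free
is always assigned to its source, giving an expected source-assignment
fraction of (1−e)^30, while the fraction assigned to *any* genotype is
slightly higher because some barcode errors land on a neighbouring
genotype's barcode (~+1.2 percentage points at e = 0.01 with the default
table). Validation therefore tracks per-read ground-truth sources and checks
the source-assignment fraction against (1−e)^30.

## Enrichment statistics

Counts are normalised to within-sample frequencies with a symmetric
pseudocount (default 0.5) so that log ratios stay defined for variants
driven to zero counts. Selection is summarised per variant as
log2(f_end/f_start) within each biological replicate — replicate k is always
paired with replicate k — and pH effects as the final-cycle log2 ratio
against the pH 5.5 reference on the same medium. Replicates (n = 3 by
default), never reads or microscope fields, are the inferential unit:
Welch's unequal-variance t (Satterthwaite df, two-sided) compares the
per-replicate log2 frequencies of the two groups, Benjamini–Hochberg
(configurable to Holm or Bonferroni) corrects across variants within one
contrast, and the volcano rule calls enriched/depleted at |log2FC| ≥ 2
(4-fold, boundary inclusive) with adjusted p < 0.05. Degenerate Welch inputs
— both groups with zero variance — return t = 0, p = 1 for equal means and
t = ±inf, p = 0 otherwise; this arises naturally when a variant sits at the
pseudocount floor in all replicates of both groups. Observed-vs-predicted
agreement is quantified by Pearson's r with r² reported.

## Single-strain calculators

The mating rate of one microscopic field is
(2Z + 2A + 0.5S)·100/(V + 2Z + 2A + 0.5S): each zygote or ascus represents
two mated cells, each free spore half a mated cell. Fields (nine per plate by
convention) are averaged within a biological replicate and only replicate
means are carried forward — never pooled fields — with sd reported absent for
a single replicate. pH profiles report per-pH mean ± sd and the argmax pH,
ties broken toward lower pH. Miller units are
(OD420 × 1000)/(V_mL · t_min · OD600); growth lag is the first crossing of
OD600 = 0.5 by linear interpolation (0 if already above at the first point,
a sentinel when never reached). For the buffering analysis no quantitative
epistasis statistic is standard; the package uses an explicit multiplicative
null for the expected double-mutant rate, m_wt·(m_a/m_wt)·(m_b/m_wt), and a
configurable rescue rule — single mutant < 1% (near-sterile) and double
mutant ≥ 3% — chosen to match the observed restoration of loss-of-function
variants to the 3–9% range by a permissive partner.

## Validation experiments and problem sizes

`mfcomp.experiments` holds the canonical synthetic studies, sized to run in
seconds to tens of seconds on one CPU:

* closed-form agreement: 100 random pools (N ≤ 10, T ≤ 10), drift off;
  max relative deviation ~1e-15.
* demultiplexing fidelity: 1e5 reads, e = 0 (exact counts, 100% source
  assignment) and e = 0.01 (source assignment vs (1−e)^30, within 3 SE).
* efficiency recovery: all 153 genotypes with known flat efficiencies — most
  spread evenly over [0.4, 0.9], every tenth variant a weak mater at 0.2 —
  5 deterministic cycles, cycle-0 and cycle-5 pools sequenced at 1e6 reads.
  Reportable variants (deterministic final frequency > 1e-4, ~400+ reads)
  are recovered within 5% relative error; the weak maters fall two orders of
  magnitude below the filter. The grid intentionally avoids the immediate
  neighbourhood of the threshold, where read-sampling noise alone puts the
  inferred efficiency's standard error near 2% and a max-error bound would
  measure sampling luck rather than estimator quality.
* pH recapitulation: the full pipeline (simulate → demultiplex → contrast) on
  the 153-genotype pool with one alkaline-activated and one acid-activated
  variant among 151 flats, 3 replicates, 5 cycles, 2e5 reads/sample, drift at
  1.53e7 cells. The contrast analysis flags exactly the two engineered
  variants (enriched at pH 7 and pH 4 respectively, adjusted p ≪ 0.05) with
  zero false enriched calls among the flats.

What passing these tests shows — and does not. The generator reproduces the
statistical structure the analysis assumes: equal starting pools,
cell-autonomous multiplicative selection, multinomial read sampling, uniform
substitution error, and replicate-level drift. It does not emulate PCR
amplification bias, indels, position-dependent error, partial mating-type
switching, frequency-dependent mating, or condition-dependent vegetative
effects; agreement on synthetic data therefore validates the inference
machinery, not the biological completeness of the model. Real-screen counts
may also carry per-variant technical bias (a multiplicative count-bias hook
exists in concept but is fixed at 1), and the reported mating efficiencies
integrate production, secretion, stability and receptor activation — the
model does not separate those steps.

## Reproducibility

All randomness flows from explicit integer seeds through numpy Generators;
per-condition and per-sample seeds are derived from the root seed via
`SeedSequence([root, condition, replicate, cycle])`, so identical
configuration and seed give byte-identical FASTQ output, and any CLI output
is reproducible from its run manifest (config echo, seed, package version,
input checksums).
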