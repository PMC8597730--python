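# Methods

This note documents the models, thresholds and numerical choices behind
`pseudonif`, and what the synthetic-data experiments do and do not show
about real data.

## Genome-context typing of nifH

A genome annotation is an ordered, stranded list of CDS records per
replicon. Nitrogenase genes are recognized by normalized lowercase gene
symbol — H-set {nifh}, D-like {nifd, vnfd, anfd}, K-like {nifk, vnfk,
anfk} — with a product-string fallback ("nitrogenase iron protein",
"nitrogenase molybdenum-iron protein alpha/beta") for rows without a
symbol. vnfH/anfH do not occur as annotation symbols; the D/K-like pooling
is what makes alternative-nitrogenase operons (nifH next to vnfD/K or
anfD/K) count as functional context.

Every nifH CDS is typed by two nested questions:

1. *Neighborhood*: does a D/K-like gene lie within `neighborhood_radius`
   (default 10) positions of nifH in the ordered sub-list of **same-strand**
   CDSs on the **same replicon**? Opposite-strand CDSs are filtered out
   before counting, so they do not consume distance; the neighborhood never
   spans replicons. Any hit ⇒ **T1**.
2. *Cooccurrence*: otherwise, does any D/K-like gene exist anywhere on the
   genome (any strand, any replicon, plasmids included)? Yes ⇒ **T2**,
   no ⇒ **T3**. Because T3 requires a genome-wide absence, T3 can never
   cooccur with T1 or T2 calls on one genome — the mutual exclusion is
   structural, and the test suite fuzzes it.

Inclusion rules: genomes need completeness ≥ `completeness_min` (0.95,
inclusive — "95% or higher"); completeness is accepted as metadata, not
estimated. Pseudogene-flagged CDSs are parsed but removed before the
census; a genome whose only nitrogenase gene is a pseudogene drops out. A
D/K-like gene within range of two nifH copies is evidence for both (nothing
forbids sharing). Percentages in reports use round-half-even at the
requested precision.

Coordinates are 1-based inclusive at both I/O boundaries (feature table and
GFF3); internally only the per-replicon ordering matters, so no conversion
is performed. The feature-table dialect is the package's own compact
tab-separated form (replicon, start, end, strand, feature, gene, locus_tag,
product, pseudo); GFF3 is parsed directly from the 9-column grammar since
only CDS rows with a handful of attributes are needed.

## Phenotype crosswalk

Diazotrophy lookup is an exact (genus, species) match or a genus-level
wildcard (empty species field), case-normalized, order-independent.
Resolution is species-level: strain suffixes are invisible to the table, so
when strains of one species land in different type rows the reported flag
is propagated to all of them and a conflict counter records the ambiguity
(within-species diversity is beyond the table's resolution — the package
flags it rather than guessing). Higher-rank wildcards (family and above)
are not supported.

## Alignment layer

All protein comparisons use exact global (Needleman–Wunsch) alignment with
affine gaps, computed by Biopython's `PairwiseAligner` (C implementation):
BLOSUM62, gap open −11, extend −1 — transparent BLAST-like parameters,
since identity thresholds rather than raw scores drive every decision. `X`
is tolerated and scored 0 against everything. The reported identity is
matches / columns, where the column count excludes terminal-gap columns but
keeps internal gap columns (`identity_denominator` can be switched to
`all_columns`). Excluding terminal gaps is what lets a 40-aa fragment reach
90–100% identity against a 300-aa reference; with the all-columns
convention short-fragment mapping would be impossible by construction.
Identity is computed with the pair in a canonical argument order, because
co-optimal tracebacks can lay out columns differently depending on argument
order; the optimal score itself is order-invariant (and is validated
against exhaustive alignment enumeration on short peptides). Threshold
conventions follow the wording they implement: "below 0.5" expected errors
is strict, "95% or higher" style identity thresholds are inclusive.

## Read QC

Pairs merge on their best ungapped overlap (fewest mismatches, ties to the
longest overlap, then the leftmost placement for determinism), accepted iff
overlap ≥ 20 bases with ≤ 5 mismatches; staggered geometries are allowed
with overhangs trimmed. Merged qualities take the higher Phred at agreeing
positions; conflicts take the higher-quality base with its own quality.
Each merged read is then cut to its longest contiguous window with total
expected errors strictly below 0.5 (two-pointer O(n), validated against the
quadratic all-substrings oracle), and reads shorter than 200 bases are
dropped; a sample is capped at its first 2.5M retained reads.

## Metagenome screen

Stage 1 six-frame translates each read, splits peptides at stop codons,
discards fragments < 20 aa (frameshift-aware alignment is out of scope; on
Illumina-type data substitutions dominate), and aligns fragments against
the nitrogenase panel; a read is a candidate iff some fragment reaches
identity ≥ `stage1_min_identity` (0.5) over ≥ `stage1_min_cols` (30)
columns. Stage 2 aligns the candidate's best stage-1 fragment against the
full panel including decoy homologs (distant NifH paralogs of the
chlorophyllide-reductase kind); the best reference's gene group wins (ties:
higher score, then ref_id) provided identity ≥ `stage2_min_identity`
(0.6). A database-wide E-value cutoff would be meaningless on a desk-scale
panel — its population statistics depend on database size — so explicit
identity/length floors replace it; both are config-exposed. Using only the
best fragment keeps the screen linear in panel size; on substitution-only
reads the best fragment is the coding-frame peptide in essentially every
case.

nifH-assigned reads are typed against T1/T2/T3-labeled references: hits
within the retention band of the maximum identity (`s ≥ 0.95·s_max`
multiplicatively by default; a subtractive `s ≥ s_max − 0.05` variant is
selectable) are retained, and the verdict is *true* (T1/T2 only — T2
references anchor "true" alongside T1), *pseudo* (T3 only) or *ambiguous*.
Raising the retention factor can only shrink the retained set, so the
ambiguous class shrinks monotonically — a property the tests fuzz.

The overestimation factor is (true+pseudo+ambiguous)/true, undefined
(reported as absent) when no true reads exist. Gene-length proportionality
uses exact Garwood Poisson CIs, `[½χ²(α/2; 2x), ½χ²(1−α/2; 2x+2)]` with a
zero lower bound at x = 0, at `ci_level` 0.99 per count; a sample deviates
iff the CI rectangle misses the line through the origin with slope
`len_b/len_a`. Under proportional Poisson sampling the empirical deviating
rate is far below the nominal 2% bound for two 99% intervals (the rectangle
test is conservative). Default gene lengths are nifD 894 bp and nifH
1497 bp (count ratio 0.597); nifK has no protocol-fixed length and defaults
to a typical 1560 bp, configurable.

## Synthetic data: what it emulates, and what it does not

*Genomes.* Five layouts (`T1_operon`, `T2_split`, `T1_plus_T2`,
`T3_standalone`, `no_nif`) are laid down with decoy CDSs drawn from a fixed
non-nif vocabulary; spacer decoys that realize a designed distance are
placed on nifH's strand (opposite-strand CDSs would not count), and extra
decoys only flank the arrangement so they can never shrink a designed gap.
The primary generator test is recovery: typing the generated genomes
reproduces the intended truth labels exactly.

*Protein families.* A two-clade star topology with divergences defined
between **leaf pairs**: `within_clade_divergence` is the expected
substitutions per site between two members of one clade,
`between_clade_divergence` between members of opposite clades (so
between ≥ within is exact, not approximate). The between-clade component is
realized by substituting a fixed number of distinct sites, making the clade
separation a design constant; leaf branches add Poisson substitutions.
Defaults (within 0.05, between 0.13, 20+20 sequences of 300 aa) were
calibrated once so the cross-clade identity (~0.88) sits just under the
0.90/0.95 mapping thresholds — the regime where short-fragment
confusability actually occurs: incorrect-mapping proportions then fall with
query length and are strictly lower at the 95% threshold than at 90%,
mirroring the behavior reported for true/pseudo NifH within *Clostridia*.
At much larger separations every rate is zero and the experiment is
uninformative. A full phylogeny is unnecessary: controlled within/between
divergence is the only property the confusability experiments consume.

*Metagenomes.* Proteins are back-translated with uniform synonymous codons
(codon bias is irrelevant to amino-acid-space comparisons), cut into
inserts (default 210 bp, read length 120, so merged reads sit just above
the 200-base retention floor with a 30-base merge overlap), strand-flipped
at random, and given substitution errors from a linear-decay Phred model
(mean 35, decay 0.03/base); no indels (Illumina-type platforms) and no
chimeras, adapter content or platform-specific error profiles. Abundances
follow the specified mix exactly rather than a realistic community
distribution, so recovered proportions test classification, not abundance
estimation. The read-classification recovery experiment uses a
well-separated family (within 0.02, between 0.50) and the mix 20% true /
10% pseudo / 70% background: under those conditions classification is
near-perfect and the overestimation factor recovers the design value 1.5.
Passing these tests shows the pipeline's logic and thresholds are
implemented correctly; it does not show that real pseudo-nifH reads are
classifiable — the confusability experiment shows the opposite regime
exists when clades are close.

## Problem sizes and determinism

Every generator and experiment is a pure function of (spec, seed); reruns
are byte-identical. Default experiment sizes (1,000 fuzzed genomes for the
typing oracle, 100 enumeration pairs for the alignment oracle, 3 seeds ×
40 clustered representatives for the confusability regime, 10,000 read
pairs for recovery, 10,000 draws for CI calibration) keep the full suite in
a few minutes on one CPU while leaving the statistical margins (3 binomial
SDs; 2-of-3 seed majorities) comfortable. `scripts/acceptance.py` uses a
4,000-pair metagenome for the same reason.

## Known limitations

- Neighborhood distance counts CDS rows only; whether non-CDS features
  should consume distance is undefined in the underlying protocol.
- The copy-balance report quantifies EQUAL, H_EXCESS (with an only-nifH
  sub-flag) and NO_H; all remaining imbalances are pooled as
  OTHER_IMBALANCE.
- The merge consensus and identity denominator follow documented, commonly
  used conventions, but the reference tools' exact arithmetic is
  unpublished; both are config-switchable where ambiguity exists.
- HMM-based reannotation, structure prediction/comparison, taxonomy-tree
  normalization and MSA construction are out of scope; aligned FASTA and
  completeness values are accepted as inputs.
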