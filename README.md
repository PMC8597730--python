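# pseudonif

**Pseudo-*nifH* detection in prokaryotic genomes, and what it does to
shotgun-metagenomic surveys of nitrogen fixers.**

The *nifH* gene (nitrogenase reductase, the Fe protein) is the standard marker
for biological nitrogen fixation, but a substantial fraction of *nifH* CDSs in
public genome databases sit on genomes that lack the catalytic nitrogenase
subunits (*nifD*/*nifK* and their vanadium/iron-only counterparts
*vnfD/K*, *anfD/K*). Such stand-alone "pseudo-*nifH*" genes cannot support
nitrogen fixation, yet their reads are nearly indistinguishable from true
*nifH* in short-read data, inflating diazotroph abundance estimates. This
package implements the genome-context logic that separates the two, and
quantifies the metagenomic consequences — with a synthetic-data generator so
every stage is testable against known ground truth.

## What it computes

**Genome census and nifH typing** (`pseudonif.genome_census`). From per-genome
CDS annotations (tab-separated feature tables or GFF3), count copies of
*nifH*, D-like (*nifD*+*vnfD*+*anfD*) and K-like (*nifK*+*vnfK*+*anfK*) genes
and type every *nifH* CDS by context:

- **T1** — a D/K-like gene lies within 10 CDSs upstream or downstream of
  *nifH*, counted along same-strand CDSs of the same replicon (operon context);
- **T2** — no such neighbor, but a D/K-like gene exists elsewhere on the
  genome (plasmids included);
- **T3** (pseudo-*nifH*) — the genome carries no D/K-like gene at all.

Genomes below 95% completeness and pseudogene CDSs are excluded first.

**Phenotype crosswalk** (`pseudonif.phenotype_crosswalk`). Match each
genome's (genus, species) against a curated diazotrophy table (genus-level
wildcards supported) and tabulate reported/unreported nitrogen fixers for the
T1 / T2-not-T1 / T3 rows.

**Confusability** (`pseudonif.confusability`). Cluster full-length NifH at
95% identity, cut random fragments (40–100 aa), map them back by global
alignment at 90%/95% identity, and measure the proportion of *incorrect*
mappings (a fragment hitting the opposite type); plus MSA-window similarity
networks that classify each partial sequence as *distinct* or *confusing*.

**Metagenome screen** (`pseudonif.metagenome_screen`). Merge read pairs
(max 5 mismatches, min 20-base overlap), trim each merged read to its longest
window with expected errors `Σ 10^(-Q/10) < 0.5`, keep reads ≥ 200 bases, cap
at 2.5M; six-frame translate and screen against a nitrogenase reference
panel; assign genes by best identity; type *nifH* reads by retaining hits
within 95% of the maximum identity — T1/T2-only ⇒ *true*, T3-only ⇒
*pseudo*, otherwise *ambiguous*. Per sample it reports the overestimation
factor (reciprocal of the true-*nifH* proportion) and an exact-Poisson 99% CI
test of whether read counts of two genes are proportional to their lengths
(for *nifD* 894 bp vs *nifH* 1497 bp the expected count ratio is 0.597).

All alignment is exact global (Needleman–Wunsch, BLOSUM62, gap open −11 /
extend −1, via Biopython's C aligner); identity excludes terminal-gap columns,
so short fragments can match full-length references at high identity.

## Worked example

```python
from pseudonif import SimGenomeSpec, gen_genomes, classify_nifh, nitrogenase_copy_counts

specs = [
    SimGenomeSpec(genome_id="operon", layout="T1_operon"),
    SimGenomeSpec(genome_id="split", layout="T2_split"),
    SimGenomeSpec(genome_id="orphan", layout="T3_standalone"),
]
genomes, truth = gen_genomes(specs, seed=11)
for gid, genome in genomes.items():
    counts = nitrogenase_copy_counts(genome)
    for call in classify_nifh(genome):
        print(f"{gid:8s} {call.locus_tag}  {call.nifh_type}  "
              f"copies(H,D-like,K-like)=({counts.n_H},{counts.n_Dlike},{counts.n_Klike})")
```

prints

```
operon   operon_0016  T1  copies(H,D-like,K-like)=(1,1,1)
split    split_0000  T2  copies(H,D-like,K-like)=(1,1,1)
orphan   orphan_0013  T3  copies(H,D-like,K-like)=(1,0,0)
```

The `operon` genome carries *nifHDK* contiguously, so its *nifH* is T1; the
`split` genome has the same genes but *nifD*/*nifK* more than 10 same-strand
CDSs away, so its *nifH* is T2; the `orphan` genome has *nifH* and no
catalytic subunit anywhere — a T3 pseudo-*nifH*.

The same analyses are available from the shell:

```sh
pseudonif simulate --n-genomes 20 --seed 3 --out genomes/
pseudonif census --annotations genomes/ --metadata genomes/metadata.tsv --out census/
pseudonif confuse --proteins nifh.fasta --labels labels.tsv --out confuse/
pseudonif screen --r1 R1.fastq --r2 R2.fastq --refs refs.fasta \
    --ref-types ref_types.tsv --out screen/
```

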