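"""Synthetic genomes, NifH protein families, phenotype tables and metagenomes.

Every downstream stage of the package is testable without any database
download because this module emulates the study's three real input
classes with known ground truth:

* **Annotated genomes** with configurable *nif* operon layouts
  (``T1_operon``, ``T2_split``, ``T1_plus_T2``, ``T3_standalone``,
  ``no_nif``), written as tab-separated CDS feature tables plus a truth
  table of intended nifH types.
* **Two-clade NifH protein families** standing for true (T1/2) and
  pseudo (T3) NifH: a random root is mutated along a two-clade star
  topology with controlled within- and between-clade divergence
  (expected substitutions per site between leaf pairs).
* **Paired-end metagenomes**: proteins are back-translated with uniform
  synonymous codons, fragmented, and "sequenced" with substitution
  errors following a simple Phred quality model; each pair's origin is
  recorded in a sidecar truth table.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .config import DEFAULT_CONFIG, AnalysisConfig
from .confusability import TypedProtein
from .genome_census import CdsRecord, GenomeAnnotation, write_feature_table
from .seqalign import QualRead, reverse_complement, write_fastq

__all__ = [
    "SimGenomeSpec",
    "SimFamilySpec",
    "SimMetagenomeSpec",
    "FamilySet",
    "gen_genomes",
    "gen_protein_family",
    "gen_metagenome",
    "gen_phenotype_table",
    "gen_unrelated_protein",
    "mutate_protein",
    "back_translate",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

LAYOUTS = ("T1_operon", "T2_split", "T1_plus_T2", "T3_standalone", "no_nif")

# fixed non-nif vocabulary for decoy CDSs; neighborhood counting must skip
# arbitrary genes, so symbols and products stay clear of nitrogenase naming
DECOY_GENES: tuple[tuple[str, str], ...] = (
    ("dnaa", "chromosomal replication initiator protein DnaA"),
    ("gyrb", "DNA gyrase subunit B"),
    ("reca", "recombinase RecA"),
    ("rpob", "DNA-directed RNA polymerase subunit beta"),
    ("ftsz", "cell division protein FtsZ"),
    ("seca", "protein translocase subunit SecA"),
    ("dnak", "molecular chaperone DnaK"),
    ("grol", "chaperonin GroEL"),
    ("rpsa", "30S ribosomal protein S1"),
    ("tufa", "elongation factor Tu"),
    ("glna", "glutamine synthetase"),
    ("metk", "S-adenosylmethionine synthase"),
)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimGenomeSpec:
    genome_id: str
    layout: str
    n_decoy_cds: int = 20
    replicons: int = 1
    taxon: tuple[str, str] = ("Clostridium", "synthetica")
    completeness: float = 1.0

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.n_decoy_cds < 0 or self.replicons < 1:
            raise ValueError("n_decoy_cds >= 0 and replicons >= 1 required")
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError("completeness must be in [0, 1]")


@dataclass(frozen=True)
class SimFamilySpec:
    """Two-clade NifH family.

    Divergences are expected substitutions per site between *leaf
    pairs*: ``within_clade_divergence`` for two members of the same
    clade, ``between_clade_divergence`` for members of opposite clades
    (hence between >= within).  Defaults are calibrated so that short
    fragments of the two clades sit just below the 0.90/0.95 mapping
    identity thresholds, the regime where true/pseudo confusability
    appears.
    """

    n_true: int = 20
    n_pseudo: int = 20
    root_length: int = 300
    within_clade_divergence: float = 0.05
    between_clade_divergence: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_clade_divergence < self.within_clade_divergence:
            raise ValueError("between_clade_divergence must be >= within")
        if self.root_length < 120:
            raise ValueError("root_length must be >= 120")
        if self.within_clade_divergence < 0:
            raise ValueError("divergences must be nonnegative")


@dataclass(frozen=True)
class SimMetagenomeSpec:
    n_read_pairs: int = 10_000
    read_length: int = 120
    mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "true_nifH": 0.2,
            "pseudo_nifH": 0.1,
            "nifD": 0.0,
            "nifK": 0.0,
            "background": 0.7,
        }
    )
    quality_model: tuple[float, float] = (35.0, 0.03)  # mean Phred, per-base decay
    insert_length: int = 210
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mix", dict(self.mix))
        unknown = set(self.mix) - {
            "true_nifH", "pseudo_nifH", "nifD", "nifK", "background"
        }
        if unknown:
            raise ValueError(f"unknown mix classes: {sorted(unknown)}")
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("mix proportions must sum to 1")
        if any(v < 0 for v in self.mix.values()):
            raise ValueError("mix proportions must be nonnegative")
        if self.read_length > self.insert_length:
            raise ValueError("read_length must not exceed insert_length")


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def _layout_tokens(
    spec: SimGenomeSpec, rng: np.random.Generator, radius: int
) -> list[tuple[str, str, str, bool]]:
    """Ordered (symbol, product, strand, movable) tokens for the layout.

    The nif arrangement is laid down with spacer decoys on the *same*
    strand as nifH where distances matter (opposite-strand CDSs do not
    consume neighborhood distance), and any extra decoys are appended
    outside the arrangement so they can never shrink a designed gap.
    Only the flanking extra decoys are movable onto plasmids.
    """
    nif_strand = "+" if rng.random() < 0.5 else "-"

    def decoy(strand: str | None = None, movable: bool = True):
        sym, product = DECOY_GENES[rng.integers(0, len(DECOY_GENES))]
        st = strand or ("+" if rng.random() < 0.5 else "-")
        return (sym, product, st, movable)

    def nif(sym: str):
        products = {
            "nifh": "nitrogenase iron protein",
            "nifd": "nitrogenase molybdenum-iron protein alpha chain",
            "nifk": "nitrogenase molybdenum-iron protein beta chain",
        }
        return (sym, products.get(sym, "nitrogenase subunit"), nif_strand, False)

    def spacer():
        return [decoy(nif_strand, movable=False) for _ in range(radius + 1)]

    core: list[tuple[str, str, str, bool]]
    if spec.layout == "T1_operon":
        core = [nif("nifh"), nif("nifd"), nif("nifk")]
    elif spec.layout == "T2_split":
        core = [nif("nifh"), *spacer(), nif("nifd"), nif("nifk")]
    elif spec.layout == "T1_plus_T2":
        core = [nif("nifh"), nif("nifd"), nif("nifk"), *spacer(), nif("nifh")]
    elif spec.layout == "T3_standalone":
        core = [nif("nifh")]
    else:  # no_nif
        core = []
    n_before = int(rng.integers(0, spec.n_decoy_cds + 1))
    before = [decoy() for _ in range(n_before)]
    after = [decoy() for _ in range(spec.n_decoy_cds - n_before)]
    return before + core + after


EXPECTED_TYPES = {
    "T1_operon": ("T1",),
    "T2_split": ("T2",),
    "T1_plus_T2": ("T1", "T2"),
    "T3_standalone": ("T3",),
    "no_nif": (),
}


def gen_genomes(
    specs: Sequence[SimGenomeSpec],
    seed: int,
    out_dir: str | Path | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[dict[str, GenomeAnnotation], pd.DataFrame]:
    """Generate annotated genomes plus a truth table of intended nifH types.

    If ``out_dir`` is given, one feature table per genome, a metadata
    TSV, the truth TSV and a run manifest are written there.
    """
    ids = [s.genome_id for s in specs]
    dupes = sorted({g for g in ids if ids.count(g) > 1})
    if dupes:
        raise ValueError(f"duplicate genome_id(s): {dupes}")
    rng = np.random.default_rng(seed)
    annotations: dict[str, GenomeAnnotation] = {}
    truth_rows = []
    meta_rows = []
    for spec in specs:
        tokens = _layout_tokens(spec, rng, config.neighborhood_radius)
        # distribute extra replicons: nif arrangement stays on replicon 1
        records: list[CdsRecord] = []
        counter = 0
        replicon_of = [0] * len(tokens)
        n_extra = spec.replicons - 1
        if n_extra and tokens:
            # move a few trailing flanking decoys onto plasmids
            movable = [i for i, tok in enumerate(tokens) if tok[3]]
            for i in movable[-min(len(movable), 3 * n_extra):]:
                replicon_of[i] = 1 + int(rng.integers(0, n_extra))
        positions = {r: 101 for r in range(spec.replicons)}
        for (sym, product, strand, _), rep in zip(tokens, replicon_of):
            length = int(rng.integers(600, 1800)) // 3 * 3
            start = positions[rep]
            rep_name = "chromosome" if rep == 0 else f"plasmid_{rep}"
            records.append(
                CdsRecord(
                    replicon_id=rep_name,
                    start=start,
                    end=start + length - 1,
                    strand=strand,
                    locus_tag=f"{spec.genome_id}_{counter:04d}",
                    gene_symbol=sym,
                    product=product,
                )
            )
            positions[rep] = start + length + int(rng.integers(50, 300))
            counter += 1
        ann = GenomeAnnotation(genome_id=spec.genome_id, records=records)
        ann.genus, ann.species = spec.taxon
        ann.completeness = spec.completeness
        annotations[spec.genome_id] = ann
        truth_rows.append(
            {
                "genome_id": spec.genome_id,
                "layout": spec.layout,
                "expected_types": ",".join(EXPECTED_TYPES[spec.layout]),
            }
        )
        meta_rows.append(
            {
                "genome_id": spec.genome_id,
                "genus": spec.taxon[0],
                "species": spec.taxon[1],
                "completeness": spec.completeness,
            }
        )
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for gid, ann in annotations.items():
            write_feature_table(ann, out_dir / f"{gid}.tsv")
        pd.DataFrame(meta_rows).to_csv(
            out_dir / "metadata.tsv", sep="\t", index=False
        )
        truth.to_csv(out_dir / "truth_genomes.tsv", sep="\t", index=False)
        _write_manifest(
            out_dir / "manifest_genomes.json",
            seed=seed,
            specs=[asdict(s) for s in specs],
        )
    return annotations, truth


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Apply ~Poisson(divergence * L) uniform substitutions to ``seq``."""
    n = len(seq)
    n_mut = rng.poisson(divergence * n)
    if n_mut == 0:
        return seq
    chars = list(seq)
    sites = rng.integers(0, n, size=n_mut)
    for site in sites:
        old = chars[site]
        choices = AA20.replace(old, "")
        chars[site] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def gen_unrelated_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=length))


@dataclass
class FamilySet:
    proteins: list[TypedProtein]
    root: str
    center_true: str
    center_pseudo: str


def _mutate_exact_sites(seq: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``k`` distinct sites of ``seq``."""
    if k == 0:
        return seq
    chars = list(seq)
    for site in rng.choice(len(seq), size=k, replace=False):
        old = chars[site]
        choices = AA20.replace(old, "")
        chars[site] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def gen_protein_family(spec: SimFamilySpec) -> FamilySet:
    """Two-clade star family with controlled leaf-pair divergences.

    The true clade is centered on the root; the pseudo clade center
    differs from it at exactly ``round((between - within) * L)``
    distinct sites, so the clade separation is a fixed design quantity
    rather than a single noisy draw.  Leaves mutate away from their
    center by ~Poisson(within/2 * L) substitutions each, giving
    expected leaf-pair divergence ``within`` inside a clade and
    ``between`` across clades.  The mean within-clade identity is
    checked to exceed the mean between-clade identity on the returned
    set (ungapped Hamming identity — sequences carry no indels).
    """
    rng = np.random.default_rng(spec.seed)
    root = gen_unrelated_protein(spec.root_length, rng)
    gap_sites = round(
        (spec.between_clade_divergence - spec.within_clade_divergence)
        * spec.root_length
    )
    center_true = root
    center_pseudo = _mutate_exact_sites(root, gap_sites, rng)
    leaf_div = spec.within_clade_divergence / 2
    proteins = [
        TypedProtein(
            seq_id=f"T12_{i:03d}",
            sequence=mutate_protein(center_true, leaf_div, rng),
            label="T12",
        )
        for i in range(spec.n_true)
    ] + [
        TypedProtein(
            seq_id=f"T3_{i:03d}",
            sequence=mutate_protein(center_pseudo, leaf_div, rng),
            label="T3",
        )
        for i in range(spec.n_pseudo)
    ]
    _check_clade_separation(proteins, spec)
    return FamilySet(
        proteins=proteins,
        root=root,
        center_true=center_true,
        center_pseudo=center_pseudo,
    )


def _hamming_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _check_clade_separation(
    proteins: Sequence[TypedProtein], spec: SimFamilySpec
) -> None:
    if spec.between_clade_divergence <= spec.within_clade_divergence:
        return  # equality: no separation to verify
    true = [p.sequence for p in proteins if p.label == "T12"]
    pseudo = [p.sequence for p in proteins if p.label == "T3"]
    if len(true) < 2 or len(pseudo) < 2:
        return
    within = [
        _hamming_identity(g[i], g[j])
        for g in (true, pseudo)
        for i in range(len(g))
        for j in range(i + 1, len(g))
    ]
    between = [_hamming_identity(a, b) for a in true for b in pseudo]
    if np.mean(within) <= np.mean(between):
        raise RuntimeError(
            "generated family does not separate clades; "
            "increase divergence contrast or change the seed"
        )


# ---------------------------------------------------------------------------
# metagenomes
# ---------------------------------------------------------------------------

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()

_BASES = "ACGT"


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly random synonymous codons."""
    parts = []
    for aa in protein:
        codons = _CODONS_BY_AA.get(aa)
        if codons is None:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _simulate_qualities(
    length: int, model: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    mean, decay = model
    q = mean - decay * np.arange(length) + rng.normal(0.0, 1.5, size=length)
    return np.clip(np.rint(q), 2, 41).astype(np.int64)


def _sequence_with_errors(
    template: str, quals: np.ndarray, rng: np.random.Generator
) -> str:
    probs = np.power(10.0, -quals / 10.0)
    err = rng.random(len(template)) < probs
    if not err.any():
        return template
    chars = list(template)
    for i in np.flatnonzero(err):
        alt = _BASES.replace(chars[i], "")
        chars[i] = alt[rng.integers(0, len(alt))]
    return "".join(chars)


def gen_metagenome(
    spec: SimMetagenomeSpec,
    sources: Mapping[str, Sequence[TypedProtein]],
    out_dir: str | Path | None = None,
) -> tuple[list[QualRead], list[QualRead], pd.DataFrame]:
    """Simulate a paired-end metagenome with known read origins.

    ``sources`` maps the gene classes of the mix (``true_nifH``,
    ``pseudo_nifH``, ``nifD``, ``nifK``) to protein sequences;
    background reads are drawn from random DNA.  Source proteins are
    back-translated once per run with uniform synonymous codons;
    inserts are cut uniformly, strand-flipped with probability 1/2, and
    sequenced with substitution errors following the quality model.
    """
    rng = np.random.default_rng(spec.seed)
    classes = ["true_nifH", "pseudo_nifH", "nifD", "nifK", "background"]
    probs = np.array([spec.mix.get(c, 0.0) for c in classes])
    for cls, p in zip(classes, probs):
        if cls == "background" or p == 0:
            continue
        if not sources.get(cls):
            raise ValueError(f"mix class {cls!r} has no source sequences")
    genes: dict[str, list[tuple[str, str]]] = {}
    for cls in classes[:-1]:
        genes[cls] = [
            (p.seq_id, back_translate(p.sequence, rng))
            for p in sources.get(cls, ())
        ]
        for sid, g in genes[cls]:
            if len(g) < spec.insert_length:
                raise ValueError(
                    f"source {sid} gene ({len(g)} nt) shorter than insert "
                    f"length {spec.insert_length}"
                )
    r1_reads: list[QualRead] = []
    r2_reads: list[QualRead] = []
    truth_rows = []
    draws = rng.choice(len(classes), size=spec.n_read_pairs, p=probs)
    for i, ci in enumerate(draws):
        cls = classes[ci]
        if cls == "background":
            insert = _random_dna(spec.insert_length, rng)
            source_id = ""
        else:
            source_id, gene = genes[cls][rng.integers(0, len(genes[cls]))]
            start = int(rng.integers(0, len(gene) - spec.insert_length + 1))
            insert = gene[start : start + spec.insert_length]
        if rng.random() < 0.5:
            insert = reverse_complement(insert)
        name = f"pair_{i:06d}"
        q1 = _simulate_qualities(spec.read_length, spec.quality_model, rng)
        q2 = _simulate_qualities(spec.read_length, spec.quality_model, rng)
        s1 = _sequence_with_errors(insert[: spec.read_length], q1, rng)
        s2 = _sequence_with_errors(
            reverse_complement(insert)[: spec.read_length], q2, rng
        )
        r1_reads.append(QualRead(name=name, sequence=s1, qualities=q1))
        r2_reads.append(QualRead(name=name, sequence=s2, qualities=q2))
        truth_rows.append({"read_id": name, "origin": cls, "source_id": source_id})
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fastq(r1_reads, out_dir / "reads_R1.fastq")
        write_fastq(r2_reads, out_dir / "reads_R2.fastq")
        truth.to_csv(out_dir / "truth_reads.tsv", sep="\t", index=False)
        _write_manifest(
            out_dir / "manifest_metagenome.json",
            seed=spec.seed,
            spec={**asdict(spec), "mix": dict(spec.mix)},
        )
    return r1_reads, r2_reads, truth


# ---------------------------------------------------------------------------
# screening scenarios
# ---------------------------------------------------------------------------

def gen_reference_panel(
    family: FamilySet,
    seed: int,
    n_decoys: int = 2,
    decoy_divergence: float = 0.7,
    other_gene_length: int = 300,
):
    """Reference panel + read sources for a metagenome screening run.

    The family's T12 members become T1/T2-typed nifH references (split
    alternately) and its T3 members T3-typed ones.  One nifD-like and
    one nifK-like protein are generated unrelated to NifH, and
    ``n_decoys`` distant NifH homologs (chlorophyllide-reductase-like
    paralogs) are derived from the family root at ``decoy_divergence``
    substitutions per site.  Returns ``(panel, sources)`` where
    ``sources`` feeds :func:`gen_metagenome`.
    """
    from .metagenome_screen import RefProtein

    rng = np.random.default_rng(seed)
    panel: list[RefProtein] = []
    true_members = [p for p in family.proteins if p.label == "T12"]
    pseudo_members = [p for p in family.proteins if p.label == "T3"]
    for i, p in enumerate(true_members):
        panel.append(
            RefProtein(p.seq_id, p.sequence, "nifH", "T1" if i % 2 == 0 else "T2")
        )
    for p in pseudo_members:
        panel.append(RefProtein(p.seq_id, p.sequence, "nifH", "T3"))
    nifd = TypedProtein("nifD_ref", gen_unrelated_protein(other_gene_length, rng), "T12")
    nifk = TypedProtein("nifK_ref", gen_unrelated_protein(other_gene_length, rng), "T12")
    panel.append(RefProtein("nifD_ref", nifd.sequence, "nifD_like"))
    panel.append(RefProtein("nifK_ref", nifk.sequence, "nifK_like"))
    for i in range(n_decoys):
        panel.append(
            RefProtein(
                f"decoy_{i}",
                mutate_protein(family.root, decoy_divergence, rng),
                "decoy",
            )
        )
    sources = {
        "true_nifH": true_members,
        "pseudo_nifH": pseudo_members,
        "nifD": [nifd],
        "nifK": [nifk],
    }
    return panel, sources


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def gen_phenotype_table(
    taxa: Sequence[tuple[str, str]],
    diazotroph_flags: Sequence[bool],
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Phenotype TSV rows from (genus, species) pairs and flags.

    Genus-level records are made by leaving species empty; they match
    every species of that genus downstream.
    """
    if len(taxa) != len(diazotroph_flags):
        raise ValueError("taxa and diazotroph_flags must have equal length")
    df = pd.DataFrame(
        {
            "genus": [g.strip().lower() for g, _ in taxa],
            "species": [s.strip().lower() for _, s in taxa],
            "diazotroph": list(diazotroph_flags),
            "source": "synthetic",
        },
        columns=["genus", "species", "diazotroph", "source"],
    )
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def _write_manifest(path: Path, **payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
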