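"""Genome annotation parsing, nitrogenase copy census, and nifH typing.

The central operation is the three-way typing of every ``nifH`` CDS by
its genomic context:

* **T1** — a catalytic-subunit gene (``nifD``/``nifK`` or their
  vanadium/iron-only counterparts ``vnfD``/``vnfK``/``anfD``/``anfK``)
  lies within 10 CDSs upstream or downstream of ``nifH`` on the same
  strand of the same replicon (operon context).
* **T2** — no such neighbor, but at least one D/K-like gene exists
  elsewhere on the genome (any replicon, plasmids included).
* **T3** ("pseudo-nifH") — the genome carries no D/K-like gene at all.
  T3 is mutually exclusive with T1/T2 by construction.

Neighborhood distance is counted in positions within the ordered
sub-list of same-strand CDSs on the same replicon, i.e. opposite-strand
CDSs do not consume distance.  Coordinates are 1-based inclusive at the
I/O boundary and left untouched internally (only ordering matters here).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import unquote

import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig, logger

__all__ = [
    "CdsRecord",
    "GenomeAnnotation",
    "CopyCounts",
    "NifhCall",
    "BalanceCategory",
    "parse_feature_table",
    "parse_gff3",
    "write_feature_table",
    "filter_genomes",
    "nitrogenase_copy_counts",
    "copy_balance_category",
    "classify_nifh",
    "genome_type_flags",
    "census_summary",
    "percentage",
]

H_GENES = frozenset({"nifh"})
D_GENES = frozenset({"nifd", "vnfd", "anfd"})
K_GENES = frozenset({"nifk", "vnfk", "anfk"})
DK_GENES = D_GENES | K_GENES
NITROGENASE_GENES = H_GENES | DK_GENES

# product-string fallback for rows without a gene symbol
_PRODUCT_PATTERNS: tuple[tuple[re.Pattern, str], ...] = (
    (re.compile(r"nitrogenase iron protein", re.I), "nifh"),
    (re.compile(r"nitrogenase molybdenum-iron protein alpha", re.I), "nifd"),
    (re.compile(r"nitrogenase molybdenum-iron protein beta", re.I), "nifk"),
)


@dataclass(frozen=True)
class CdsRecord:
    """One CDS row of a genome annotation (1-based inclusive coordinates)."""

    replicon_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    locus_tag: str
    gene_symbol: str  # normalized lowercase; may be ""
    product: str
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be + or -")


def gene_class(record: CdsRecord) -> str | None:
    """``"H"``, ``"D"``, ``"K"`` or ``None`` for a CDS record.

    Classification is by normalized gene symbol; rows without a symbol
    fall back to a product-string match.
    """
    sym = record.gene_symbol
    if not sym:
        for pat, mapped in _PRODUCT_PATTERNS:
            if pat.search(record.product):
                sym = mapped
                break
    if sym in H_GENES:
        return "H"
    if sym in D_GENES:
        return "D"
    if sym in K_GENES:
        return "K"
    return None


@dataclass
class GenomeAnnotation:
    """Ordered, stranded CDS annotations of one genome (all replicons)."""

    genome_id: str
    records: list[CdsRecord] = field(default_factory=list)
    genus: str = ""
    species: str = ""
    completeness: float | None = None

    def __post_init__(self) -> None:
        self._normalize()

    def _normalize(self) -> None:
        self.records.sort(key=lambda r: (r.replicon_id, r.start, r.end, r.locus_tag))
        tags = [r.locus_tag for r in self.records]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"{self.genome_id}: duplicate locus_tag(s) {dup}")

    def by_replicon(self) -> dict[str, list[CdsRecord]]:
        out: dict[str, list[CdsRecord]] = {}
        for r in self.records:
            out.setdefault(r.replicon_id, []).append(r)
        return out

    def without_pseudogenes(self) -> "GenomeAnnotation":
        return GenomeAnnotation(
            genome_id=self.genome_id,
            records=[r for r in self.records if not r.is_pseudo],
            genus=self.genus,
            species=self.species,
            completeness=self.completeness,
        )

    def has_nitrogenase_gene(self) -> bool:
        return any(gene_class(r) is not None for r in self.records)


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

_FT_COLUMNS = (
    "replicon", "start", "end", "strand",
    "feature", "gene", "locus_tag", "product", "pseudo",
)


def parse_feature_table(path, genome_id: str | None = None) -> GenomeAnnotation:
    """Parse a tab-separated CDS feature table.

    Columns: replicon, start, end, strand, feature, gene, locus_tag,
    product, pseudo.  Lines starting with ``#`` are comments.  Only
    rows whose feature field is ``CDS`` are retained; pseudogene rows
    are kept but flagged (filtering is a separate step).
    """
    path = Path(path)
    gid = genome_id or path.stem
    records: list[CdsRecord] = []
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_data += 1
            fields = line.split("\t")
            if len(fields) != len(_FT_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_FT_COLUMNS)} "
                    f"tab-separated fields, found {len(fields)}"
                )
            rep, start, end, strand, feature, gene, tag, product, pseudo = fields
            if feature != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            try:
                records.append(
                    CdsRecord(
                        replicon_id=rep,
                        start=start_i,
                        end=end_i,
                        strand=strand,
                        locus_tag=tag,
                        gene_symbol=gene.strip().lower(),
                        product=product,
                        is_pseudo=pseudo.strip().lower() in ("1", "true", "pseudo", "yes"),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if n_data == 0:
        warnings.warn(f"{path}: empty feature table", stacklevel=2)
    return GenomeAnnotation(genome_id=gid, records=records)


def write_feature_table(annotation: GenomeAnnotation, path) -> None:
    """Inverse of :func:`parse_feature_table`."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_FT_COLUMNS) + "\n")
        for r in annotation.records:
            fh.write(
                "\t".join(
                    [
                        r.replicon_id, str(r.start), str(r.end), r.strand,
                        "CDS", r.gene_symbol, r.locus_tag, r.product,
                        "true" if r.is_pseudo else "",
                    ]
                )
                + "\n"
            )


def _gff3_attributes(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = unquote(value.strip())
    return out


def parse_gff3(path, genome_id: str | None = None) -> GenomeAnnotation:
    """Parse CDS features from a GFF3 file into the same data model.

    Coordinates remain 1-based inclusive.  A CDS without a
    ``locus_tag`` attribute gets one synthesized from its coordinates
    (with a warning).
    """
    path = Path(path)
    gid = genome_id or path.stem
    records: list[CdsRecord] = []
    n_features = 0
    synthesized = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            n_features += 1
            if ftype != "CDS":
                continue
            a = _gff3_attributes(attrs)
            tag = a.get("locus_tag", "")
            if not tag:
                tag = f"cds_{seqid}_{start}_{end}_{strand}"
                synthesized += 1
            pseudo = a.get("pseudo", "").lower() == "true" or "pseudogene" in a
            records.append(
                CdsRecord(
                    replicon_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    locus_tag=tag,
                    gene_symbol=a.get("gene", "").strip().lower(),
                    product=a.get("product", ""),
                    is_pseudo=pseudo,
                )
            )
    if synthesized:
        warnings.warn(
            f"{path}: synthesized locus_tag for {synthesized} CDS row(s)",
            stacklevel=2,
        )
    if n_features and not records:
        warnings.warn(f"{path}: no CDS features found", stacklevel=2)
    return GenomeAnnotation(genome_id=gid, records=records)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_genomes(
    annotations: Iterable[GenomeAnnotation],
    metadata: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> list[GenomeAnnotation]:
    """Apply the census inclusion rules.

    ``metadata`` needs columns ``genome_id, genus, species,
    completeness``.  Genomes below the completeness floor (or with
    missing completeness) are excluded; pseudogene CDSs are removed
    from survivors; genomes left without any nitrogenase gene are
    excluded from the census set.
    """
    meta = metadata.set_index("genome_id")
    kept: list[GenomeAnnotation] = []
    for ann in annotations:
        if ann.genome_id not in meta.index:
            warnings.warn(
                f"{ann.genome_id}: no metadata row; genome excluded", stacklevel=2
            )
            continue
        row = meta.loc[ann.genome_id]
        completeness = row.get("completeness")
        if completeness is None or pd.isna(completeness):
            warnings.warn(
                f"{ann.genome_id}: missing completeness; genome excluded",
                stacklevel=2,
            )
            continue
        if float(completeness) < config.completeness_min:
            continue
        clean = ann.without_pseudogenes()
        clean.genus = str(row.get("genus", "") or "")
        clean.species = str(row.get("species", "") or "")
        clean.completeness = float(completeness)
        if not clean.has_nitrogenase_gene():
            continue
        kept.append(clean)
    return kept


# ---------------------------------------------------------------------------
# copy counts and balance categories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyCounts:
    """Copy numbers of nifH, D-like (nifD+vnfD+anfD) and K-like genes."""

    n_H: int
    n_Dlike: int
    n_Klike: int

    def total(self) -> int:
        return self.n_H + self.n_Dlike + self.n_Klike


def nitrogenase_copy_counts(genome: GenomeAnnotation) -> CopyCounts:
    h = d = k = 0
    for r in genome.records:
        cls = gene_class(r)
        if cls == "H":
            h += 1
        elif cls == "D":
            d += 1
        elif cls == "K":
            k += 1
    return CopyCounts(n_H=h, n_Dlike=d, n_Klike=k)


class BalanceCategory(str, Enum):
    EQUAL = "EQUAL"
    H_EXCESS = "H_EXCESS"
    NO_H = "NO_H"
    OTHER_IMBALANCE = "OTHER_IMBALANCE"


def copy_balance_category(counts: CopyCounts) -> tuple[BalanceCategory, bool]:
    """Partition a genome's copy counts; returns ``(category, only_H)``.

    ``only_H`` marks the H_EXCESS sub-case with no D/K-like gene at all.
    """
    if counts.total() == 0:
        raise ValueError("copy_balance_category requires >= 1 nitrogenase gene")
    only_h = counts.n_H >= 1 and counts.n_Dlike == 0 and counts.n_Klike == 0
    if counts.n_H == counts.n_Dlike == counts.n_Klike:
        return BalanceCategory.EQUAL, False
    if counts.n_H == 0:
        return BalanceCategory.NO_H, False
    if counts.n_H > counts.n_Dlike and counts.n_H > counts.n_Klike:
        return BalanceCategory.H_EXCESS, only_h
    return BalanceCategory.OTHER_IMBALANCE, False


# ---------------------------------------------------------------------------
# nifH typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NifhCall:
    """One nifH CDS with its context type and the evidence behind it."""

    genome_id: str
    locus_tag: str
    nifh_type: str  # "T1" | "T2" | "T3"
    neighborhood_hits: tuple[tuple[str, str, int], ...]  # (locus_tag, symbol, offset)
    genome_hits: tuple[str, ...]  # D/K-like locus_tags elsewhere on the genome


def classify_nifh(
    genome: GenomeAnnotation, config: AnalysisConfig = DEFAULT_CONFIG
) -> list[NifhCall]:
    """Type every nifH CDS of a (filtered) genome as T1, T2 or T3."""
    dk_tags_all = [r.locus_tag for r in genome.records if gene_class(r) in ("D", "K")]
    calls: list[NifhCall] = []
    for replicon, recs in genome.by_replicon().items():
        for strand in ("+", "-"):
            lane = [r for r in recs if r.strand == strand]
            classes = [gene_class(r) for r in lane]
            for i, r in enumerate(lane):
                if classes[i] != "H":
                    continue
                hits = []
                lo = max(0, i - config.neighborhood_radius)
                hi = min(len(lane), i + config.neighborhood_radius + 1)
                for j in range(lo, hi):
                    if j != i and classes[j] in ("D", "K"):
                        hits.append(
                            (lane[j].locus_tag, lane[j].gene_symbol, j - i)
                        )
                neighbor_tags = {t for t, _, _ in hits}
                genome_hits = tuple(
                    t for t in dk_tags_all if t not in neighbor_tags
                )
                if hits:
                    nifh_type = "T1"
                elif genome_hits:
                    nifh_type = "T2"
                else:
                    nifh_type = "T3"
                calls.append(
                    NifhCall(
                        genome_id=genome.genome_id,
                        locus_tag=r.locus_tag,
                        nifh_type=nifh_type,
                        neighborhood_hits=tuple(hits),
                        genome_hits=genome_hits,
                    )
                )
    calls.sort(key=lambda c: c.locus_tag)
    return calls


def genome_type_flags(calls: Sequence[NifhCall]) -> dict[str, bool]:
    types = {c.nifh_type for c in calls}
    return {
        "has_T1": "T1" in types,
        "has_T2": "T2" in types,
        "has_T3": "T3" in types,
    }


# ---------------------------------------------------------------------------
# census summary
# ---------------------------------------------------------------------------

def percentage(part: int, whole: int, digits: int = 1) -> float:
    """``100 * part / whole`` rounded half-even to ``digits`` decimals."""
    if whole <= 0:
        raise ValueError("percentage requires whole > 0")
    if not 0 <= part <= whole:
        raise ValueError("percentage requires 0 <= part <= whole")
    return round(100.0 * part / whole, digits)


def census_summary(
    genomes: Sequence[GenomeAnnotation],
    calls_by_genome: Mapping[str, Sequence[NifhCall]],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict:
    """Aggregate copy-balance categories and nifH types over a genome set.

    Returns a dict with per-category genome counts, per-type genome
    counts (T1; T2-but-not-T1; T3), a per-genus taxonomic breakdown,
    and the derived percentages.
    """
    n_total = len(genomes)
    cat_counts = {c.value: 0 for c in BalanceCategory}
    n_only_h = 0
    type_counts = {"has_T1": 0, "T2_not_T1": 0, "has_T2": 0, "has_T3": 0}
    taxa_rows = []
    for g in genomes:
        counts = nitrogenase_copy_counts(g)
        if counts.total() == 0:
            continue
        cat, only_h = copy_balance_category(counts)
        cat_counts[cat.value] += 1
        n_only_h += only_h
        flags = genome_type_flags(calls_by_genome.get(g.genome_id, ()))
        type_counts["has_T1"] += flags["has_T1"]
        type_counts["has_T2"] += flags["has_T2"]
        type_counts["T2_not_T1"] += flags["has_T2"] and not flags["has_T1"]
        type_counts["has_T3"] += flags["has_T3"]
        taxa_rows.append(
            {
                "genome_id": g.genome_id,
                "genus": g.genus,
                "species": g.species,
                "category": cat.value,
                "only_H": only_h,
                **flags,
            }
        )
    n_unbalanced = n_total - cat_counts["EQUAL"]
    summary = {
        "n_genomes": n_total,
        "categories": cat_counts,
        "n_only_H": n_only_h,
        "n_unbalanced": n_unbalanced,
        "types": type_counts,
        "percent_unbalanced": (
            percentage(n_unbalanced, n_total, 1) if n_total else None
        ),
        "per_genome": pd.DataFrame(
            taxa_rows,
            columns=[
                "genome_id", "genus", "species", "category", "only_H",
                "has_T1", "has_T2", "has_T3",
            ],
        ),
    }
    if n_unbalanced:
        summary["percent_H_excess_of_unbalanced"] = percentage(
            cat_counts["H_EXCESS"], n_unbalanced, 1
        )
        summary["percent_only_H_of_unbalanced"] = percentage(
            n_only_h, n_unbalanced, 1
        )
        summary["percent_no_H_of_unbalanced"] = percentage(
            cat_counts["NO_H"], n_unbalanced, 2
        )
    return summary


def write_calls_tsv(
    calls: Iterable[NifhCall], path, config: AnalysisConfig = DEFAULT_CONFIG
) -> None:
    with open(path, "w") as fh:
        fh.write(config.header_comment() + "\n")
        fh.write("genome_id\tlocus_tag\tnifh_type\tneighborhood_hits\tgenome_hits\n")
        for c in calls:
            nb = ",".join(f"{t}:{s}:{o:+d}" for t, s, o in c.neighborhood_hits)
            fh.write(
                f"{c.genome_id}\t{c.locus_tag}\t{c.nifh_type}\t{nb}\t"
                f"{','.join(c.genome_hits)}\n"
            )


def write_census_tsv(summary: dict, path, config: AnalysisConfig = DEFAULT_CONFIG) -> None:
    with open(path, "w") as fh:
        fh.write(config.header_comment() + "\n")
        fh.write("key\tvalue\n")
        fh.write(f"n_genomes\t{summary['n_genomes']}\n")
        for cat, n in summary["categories"].items():
            fh.write(f"category_{cat}\t{n}\n")
        fh.write(f"n_only_H\t{summary['n_only_H']}\n")
        fh.write(f"n_unbalanced\t{summary['n_unbalanced']}\n")
        for key, n in summary["types"].items():
            fh.write(f"type_{key}\t{n}\n")
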