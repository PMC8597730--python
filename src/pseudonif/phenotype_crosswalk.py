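"""Crosswalk between genome taxa and a diazotrophy phenotype table.

Emulates the FAPROTAX-style lookup: a genome's (genus, species) is
matched against a manually curated table of taxa with reported
nitrogen-fixing activity.  A record with an empty species field is a
genus-level wildcard that matches every species of that genus.
Resolution is species-level only — strain suffixes are ignored — so
strains of one species that disagree in nifH type are flagged as
conflicts rather than resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "PhenotypeRecord",
    "load_phenotype_table",
    "lookup_diazotrophy",
    "tabulate_by_type",
]

TYPE_ROWS = ("T1", "T2_not_T1", "T3")


@dataclass(frozen=True)
class PhenotypeRecord:
    genus: str
    species: str  # empty = genus-level record
    diazotroph: bool
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValueError("PhenotypeRecord requires a nonempty genus")


def _norm(name: str) -> str:
    return str(name or "").strip().lower()


def load_phenotype_table(path) -> pd.DataFrame:
    """Read a phenotype TSV (genus, species, diazotroph, source)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    required = {"genus", "species", "diazotroph"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""
    df["genus"] = df["genus"].map(_norm)
    df["species"] = df["species"].map(_norm)
    df["diazotroph"] = df["diazotroph"].str.strip().str.lower().isin(
        ("1", "true", "yes", "t")
    )
    if (df["genus"] == "").any():
        raise ValueError("phenotype table contains records with empty genus")
    return df


def lookup_diazotrophy(genus: str, species: str, table: pd.DataFrame) -> bool:
    """``True`` iff the taxon has a reported diazotrophy record.

    Reported iff an exact (genus, species) record or a genus-level
    wildcard record with ``diazotroph=True`` exists.  Independent of
    record order.
    """
    g, s = _norm(genus), _norm(species)
    if not g:
        raise ValueError("lookup_diazotrophy requires a nonempty genus")
    rows = table[table["genus"] == g]
    if rows.empty:
        return False
    match = rows["diazotroph"] & ((rows["species"] == s) | (rows["species"] == ""))
    return bool(match.any())


def tabulate_by_type(
    genome_types: pd.DataFrame, table: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate reported/unreported diazotrophs per nifH type row.

    ``genome_types`` needs columns ``genome_id, genus, species, has_T1,
    has_T2, has_T3``.  Genomes are partitioned into three disjoint rows
    — has_T1; has_T2 and not has_T1; has_T3 — covering all
    nifH-bearing genomes (T3 is mutually exclusive with T1/T2, so the
    rows cannot overlap).  The ``conflict`` column counts genomes whose
    species also occurs with a different type row, where species-level
    phenotype lookup cannot separate the strains.
    """
    df = genome_types.copy()
    df["genus_n"] = df["genus"].map(_norm)
    df["species_n"] = df["species"].map(_norm)

    def row_of(rec) -> str | None:
        if rec["has_T1"]:
            return "T1"
        if rec["has_T2"]:
            return "T2_not_T1"
        if rec["has_T3"]:
            return "T3"
        return None

    df["type_row"] = df.apply(row_of, axis=1)
    df = df[df["type_row"].notna()]
    species_rows = df.groupby(["genus_n", "species_n"])["type_row"].nunique()
    out = []
    for type_row in TYPE_ROWS:
        sub = df[df["type_row"] == type_row]
        reported = 0
        conflicts = 0
        for _, rec in sub.iterrows():
            rep = lookup_diazotrophy(rec["genus_n"], rec["species_n"], table)
            reported += rep
            if (
                rep
                and species_rows.get((rec["genus_n"], rec["species_n"]), 1) > 1
            ):
                conflicts += 1
        out.append(
            {
                "type_row": type_row,
                "n_strains": len(sub),
                "reported": reported,
                "not_reported": len(sub) - reported,
                "conflict": conflicts,
            }
        )
    return pd.DataFrame(out)
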