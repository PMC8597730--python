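"""Shotgun-metagenome screen for nitrogenase reads and nifH typing.

Pipeline, per sample:

1. **QC** — merge read pairs, trim each merged read to its longest
   window with expected errors < 0.5, keep reads of >= 200 bases, cap
   at the first 2.5M reads.
2. **Stage-1 screen** — six-frame translate every retained read, split
   peptides at stop codons, and align fragments against a small panel
   of nitrogenase reference proteins; reads with a qualifying hit are
   candidates.
3. **Gene assignment** — align each candidate's best fragment against
   the full panel (nitrogenase references plus decoy homologs); the
   best reference's gene group wins, provided it clears the
   assignment identity floor.  (This replaces a database-wide E-value
   cutoff, which is meaningless on a desk-scale panel, with explicit
   identity/length thresholds.)
4. **nifH typing** — nifH-assigned reads are aligned against typed
   (T1/T2/T3) full-length NifH references; hits within 95% of the
   maximum identity are retained; a read is *true* if retained hits
   include T1/T2 but no T3, *pseudo* if only T3, else *ambiguous*.
5. **Summary** — per-sample counts, true/pseudo/ambiguous proportions,
   the overestimation factor (reciprocal of the true proportion) and
   Poisson gene-length proportionality verdicts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .config import DEFAULT_CONFIG, AnalysisConfig, logger
from .seqalign import (
    DEFAULT_SCORING,
    QualRead,
    ScoringScheme,
    align_stats,
    expected_error_trim,
    merge_pairs,
    translate_6frames,
)

__all__ = [
    "RefProtein",
    "ClassifiedRead",
    "SampleSummary",
    "QcStats",
    "qc_reads",
    "screen_stage1",
    "assign_gene",
    "classify_from_hits",
    "classify_nifh_read",
    "overestimation_factor",
    "poisson_ci",
    "proportionality_test",
    "ProportionalityResult",
    "summarize_sample",
    "run_screen",
]

GENE_GROUPS = ("nifH", "nifD_like", "nifK_like")


@dataclass(frozen=True)
class RefProtein:
    """A full-length reference protein in the screening panel."""

    ref_id: str
    sequence: str
    gene_group: str  # "nifH" | "nifD_like" | "nifK_like" | "decoy"
    nifh_type: str | None = None  # "T1" | "T2" | "T3" for nifH refs


@dataclass
class ClassifiedRead:
    read_id: str
    assigned_gene: str = "none"  # "nifH" | "nifD_like" | "nifK_like" | "none"
    best_identity: float = 0.0
    retained_hits: tuple[tuple[str, str, float], ...] = ()
    verdict: str = "n/a"  # defined only for nifH-assigned reads


@dataclass
class QcStats:
    n_pairs: int = 0
    n_merged: int = 0
    n_retained: int = 0
    capped: bool = False
    sample_discarded: bool = False  # fewer filtered reads than the cap


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_reads(
    r1: Sequence[QualRead],
    r2: Sequence[QualRead],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[list[QualRead], QcStats]:
    """Merge, trim, length-filter and cap a paired sample."""
    if len(r1) != len(r2):
        raise ValueError(f"unequal pair counts: {len(r1)} vs {len(r2)}")
    stats = QcStats(n_pairs=len(r1))
    out: list[QualRead] = []
    for a, b in zip(r1, r2):
        merged = merge_pairs(a, b, config)
        if merged is None:
            continue
        stats.n_merged += 1
        trimmed = expected_error_trim(merged, config.max_expected_errors)
        if len(trimmed) < config.min_merged_length:
            continue
        out.append(trimmed)
        if len(out) >= config.reads_cap:
            stats.capped = True
            break
    stats.n_retained = len(out)
    stats.sample_discarded = not stats.capped and len(out) < config.reads_cap
    return out, stats


# ---------------------------------------------------------------------------
# translated search
# ---------------------------------------------------------------------------

def _peptide_fragments(read: str, min_len: int) -> list[str]:
    frags: list[str] = []
    for frame in translate_6frames(read):
        for piece in frame.split("*"):
            if len(piece) >= min_len:
                frags.append(piece)
    return frags


@dataclass
class Stage1Hit:
    read: QualRead
    best_fragment: str
    best_identity: float
    best_ref: str


def screen_stage1(
    reads: Sequence[QualRead],
    refs: Sequence[RefProtein],
    config: AnalysisConfig = DEFAULT_CONFIG,
    scoring: ScoringScheme | None = None,
) -> list[Stage1Hit]:
    """Coarse screen of translated reads against the nitrogenase panel.

    A read is a candidate iff any of its stop-free translated fragments
    (>= ``min_peptide_fragment`` aa) aligns to any panel reference with
    identity >= ``stage1_min_identity`` over >= ``stage1_min_cols``
    alignment columns.
    """
    scoring = scoring or ScoringScheme.from_config(config)
    nitro_refs = [r for r in refs if r.gene_group != "decoy"]
    hits: list[Stage1Hit] = []
    for read in reads:
        frags = _peptide_fragments(read.sequence, config.min_peptide_fragment)
        best: tuple[float, str, str] | None = None
        qualified = False
        for frag in frags:
            for ref in nitro_refs:
                ident, cols, _ = align_stats(frag, ref.sequence, scoring)
                if cols >= config.stage1_min_cols:
                    if best is None or ident > best[0]:
                        best = (ident, frag, ref.ref_id)
                    if ident >= config.stage1_min_identity:
                        qualified = True
        if qualified and best is not None:
            hits.append(
                Stage1Hit(
                    read=read,
                    best_fragment=best[1],
                    best_identity=best[0],
                    best_ref=best[2],
                )
            )
    return hits


def assign_gene(
    candidate: Stage1Hit,
    panel: Sequence[RefProtein],
    config: AnalysisConfig = DEFAULT_CONFIG,
    scoring: ScoringScheme | None = None,
) -> tuple[str, float, str | None]:
    """Assign a candidate read to a gene group via its best panel hit.

    The candidate's best stage-1 fragment is aligned against the whole
    panel (nitrogenase references and decoy homologs).  The reference
    with the highest identity wins, ties broken by higher alignment
    score then lexicographic ref_id; the assignment stands only if the
    best identity reaches ``stage2_min_identity`` and the winner is not
    a decoy.  Returns ``(gene_group or "none", best_identity, ref_id)``.
    """
    scoring = scoring or ScoringScheme.from_config(config)
    best_key: tuple[float, float, str] | None = None  # (identity, score, -id)
    best_ref: RefProtein | None = None
    for ref in panel:
        ident, cols, score = align_stats(
            candidate.best_fragment, ref.sequence, scoring
        )
        key = (ident, score, ref.ref_id)
        if best_key is None or (
            key[0] > best_key[0]
            or (key[0] == best_key[0] and key[1] > best_key[1])
            or (
                key[0] == best_key[0]
                and key[1] == best_key[1]
                and key[2] < best_key[2]
            )
        ):
            best_key, best_ref = key, ref
    if best_ref is None or best_key[0] < config.stage2_min_identity:
        return "none", best_key[0] if best_key else 0.0, None
    if best_ref.gene_group == "decoy":
        return "none", best_key[0], best_ref.ref_id
    return best_ref.gene_group, best_key[0], best_ref.ref_id


# ---------------------------------------------------------------------------
# nifH read typing
# ---------------------------------------------------------------------------

def classify_from_hits(
    hits: Sequence[tuple[str, str, float]],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[str, tuple[tuple[str, str, float], ...]]:
    """Verdict from (ref_id, nifh_type, identity) hits.

    Hits with identity within the retention band of the maximum
    (``s >= hit_retention_factor * s_max`` multiplicatively, or
    ``s >= s_max - (1 - hit_retention_factor)`` subtractively) are
    retained; the verdict is *true_nifH* if retained types include
    T1/T2 but no T3, *pseudo_nifH* if only T3, else *ambiguous*.
    """
    if not hits:
        return "n/a", ()
    s_max = max(h[2] for h in hits)
    if config.retention_mode == "multiplicative":
        floor = config.hit_retention_factor * s_max
    else:
        floor = s_max - (1.0 - config.hit_retention_factor)
    retained = tuple(h for h in hits if h[2] >= floor)
    types = {h[1] for h in retained}
    has_true = bool(types & {"T1", "T2"})
    has_pseudo = "T3" in types
    if has_true and not has_pseudo:
        return "true_nifH", retained
    if has_pseudo and not has_true:
        return "pseudo_nifH", retained
    return "ambiguous", retained


def classify_nifh_read(
    fragment: str,
    typed_refs: Sequence[RefProtein],
    config: AnalysisConfig = DEFAULT_CONFIG,
    scoring: ScoringScheme | None = None,
) -> tuple[str, tuple[tuple[str, str, float], ...], float]:
    """Type one nifH-assigned read fragment against T1/T2/T3 references.

    Returns ``(verdict, retained_hits, best_identity)``.  Hits are
    references at identity >= ``stage2_min_identity``; retention and
    the verdict trichotomy follow :func:`classify_from_hits`.
    """
    scoring = scoring or ScoringScheme.from_config(config)
    hits = []
    best = 0.0
    for ref in typed_refs:
        if ref.gene_group != "nifH" or ref.nifh_type is None:
            continue
        ident, _, _ = align_stats(fragment, ref.sequence, scoring)
        best = max(best, ident)
        if ident >= config.stage2_min_identity:
            hits.append((ref.ref_id, ref.nifh_type, ident))
    if not hits:
        warnings.warn(
            "nifH-assigned read with no typed-reference hit", stacklevel=2
        )
        return "n/a", (), best
    verdict, retained = classify_from_hits(hits, config)
    return verdict, retained, best


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def overestimation_factor(verdict_counts: Mapping[str, int]) -> float | None:
    """(true+pseudo+ambiguous)/true; ``None`` when no true reads exist."""
    t = verdict_counts.get("true_nifH", 0)
    p = verdict_counts.get("pseudo_nifH", 0)
    a = verdict_counts.get("ambiguous", 0)
    total = t + p + a
    if total == 0:
        raise ValueError("overestimation_factor requires >= 1 nifH read")
    if t == 0:
        logger.info("overestimation factor undefined: no true-nifH reads")
        return None
    return total / t


def poisson_ci(count: int, ci_level: float) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for one count."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    alpha = 1.0 - ci_level
    lower = 0.0 if count == 0 else 0.5 * chi2.ppf(alpha / 2.0, 2 * count)
    upper = 0.5 * chi2.ppf(1.0 - alpha / 2.0, 2 * count + 2)
    return float(lower), float(upper)


@dataclass(frozen=True)
class ProportionalityResult:
    consistent: bool
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    slope: float  # expected b per unit a = len_b / len_a


def proportionality_test(
    count_a: int,
    count_b: int,
    len_a: float,
    len_b: float,
    ci_level: float = DEFAULT_CONFIG.ci_level,
) -> ProportionalityResult:
    """Test whether two read counts are proportional to gene lengths.

    Each count gets an exact Poisson CI; the sample *deviates* iff the
    CI rectangle does not intersect the line through the origin with
    slope ``len_b / len_a`` in (a, b) space.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("gene lengths must be positive")
    ci_a = poisson_ci(count_a, ci_level)
    ci_b = poisson_ci(count_b, ci_level)
    slope = len_b / len_a
    intersects = slope * ci_a[0] <= ci_b[1] and slope * ci_a[1] >= ci_b[0]
    return ProportionalityResult(
        consistent=bool(intersects), ci_a=ci_a, ci_b=ci_b, slope=slope
    )


@dataclass
class SampleSummary:
    sample_id: str
    counts: dict[str, int]
    verdict_counts: dict[str, int]
    proportions: dict[str, float]
    overestimation: float | None
    proportionality: dict[str, ProportionalityResult]
    qc: QcStats | None = None

    def to_row(self) -> dict:
        row = {"sample_id": self.sample_id}
        row.update({f"n_{g}": self.counts.get(g, 0) for g in GENE_GROUPS})
        for v in ("true_nifH", "pseudo_nifH", "ambiguous"):
            row[f"n_{v}"] = self.verdict_counts.get(v, 0)
            row[f"prop_{v}"] = self.proportions.get(v, float("nan"))
        row["overestimation_factor"] = (
            self.overestimation if self.overestimation is not None else float("nan")
        )
        for name, res in self.proportionality.items():
            row[f"prop_test_{name}"] = (
                "consistent" if res.consistent else "deviating"
            )
        return row


def summarize_sample(
    sample_id: str,
    classified: Sequence[ClassifiedRead],
    config: AnalysisConfig = DEFAULT_CONFIG,
    qc: QcStats | None = None,
) -> SampleSummary:
    counts = {g: 0 for g in GENE_GROUPS}
    verdicts = {"true_nifH": 0, "pseudo_nifH": 0, "ambiguous": 0}
    for read in classified:
        if read.assigned_gene in counts:
            counts[read.assigned_gene] += 1
        if read.assigned_gene == "nifH" and read.verdict in verdicts:
            verdicts[read.verdict] += 1
    n_nifh_typed = sum(verdicts.values())
    proportions = {
        k: (v / n_nifh_typed if n_nifh_typed else float("nan"))
        for k, v in verdicts.items()
    }
    overest = overestimation_factor(verdicts) if n_nifh_typed else None
    proportionality = {
        "nifD_vs_nifH": proportionality_test(
            counts["nifD_like"], counts["nifH"],
            config.gene_length_D, config.gene_length_H, config.ci_level,
        ),
        "nifK_vs_nifH": proportionality_test(
            counts["nifK_like"], counts["nifH"],
            config.gene_length_K, config.gene_length_H, config.ci_level,
        ),
        "nifD_vs_nifK": proportionality_test(
            counts["nifD_like"], counts["nifK_like"],
            config.gene_length_D, config.gene_length_K, config.ci_level,
        ),
    }
    return SampleSummary(
        sample_id=sample_id,
        counts=counts,
        verdict_counts=verdicts,
        proportions=proportions,
        overestimation=overest,
        proportionality=proportionality,
        qc=qc,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_screen(
    r1: Sequence[QualRead],
    r2: Sequence[QualRead],
    panel: Sequence[RefProtein],
    config: AnalysisConfig = DEFAULT_CONFIG,
    sample_id: str = "sample",
) -> tuple[pd.DataFrame, SampleSummary]:
    """Full per-sample pipeline: QC -> stage-1 -> assignment -> typing.

    Returns a per-read table (one row per stage-1 candidate) and the
    sample summary.
    """
    scoring = ScoringScheme.from_config(config)
    reads, qc = qc_reads(r1, r2, config)
    stage1_refs = [p for p in panel if p.gene_group != "decoy"]
    typed_refs = [p for p in panel if p.gene_group == "nifH"]
    candidates = screen_stage1(reads, stage1_refs, config, scoring)
    rows = []
    classified: list[ClassifiedRead] = []
    for cand in candidates:
        gene, ident, ref_id = assign_gene(cand, panel, config, scoring)
        read = ClassifiedRead(
            read_id=cand.read.name, assigned_gene=gene, best_identity=ident
        )
        if gene == "nifH":
            verdict, retained, best = classify_nifh_read(
                cand.best_fragment, typed_refs, config, scoring
            )
            read.verdict = verdict
            read.retained_hits = retained
        classified.append(read)
        rows.append(
            {
                "read_id": read.read_id,
                "assigned_gene": read.assigned_gene,
                "best_identity": round(read.best_identity, 4),
                "assigned_ref": ref_id or "",
                "verdict": read.verdict,
                "retained_hits": ",".join(
                    f"{r}:{t}:{i:.3f}" for r, t, i in read.retained_hits
                ),
            }
        )
    per_read = pd.DataFrame(
        rows,
        columns=[
            "read_id", "assigned_gene", "best_identity", "assigned_ref",
            "verdict", "retained_hits",
        ],
    )
    summary = summarize_sample(sample_id, classified, config, qc)
    return per_read, summary
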