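"""Confusability of short true- vs pseudo-NifH fragments.

Two experiments quantify whether short amino-acid fragments of true
(T1/2) and pseudo (T3) NifH can be told apart:

1. **Partial-sequence mapping** — random subsequences (40/60/80/100 aa,
   spanning typical Illumina read lengths) are cut from clustered
   full-length representatives and globally aligned back against every
   representative of both labels.  A query hitting a reference of the
   opposite label at or above the identity threshold is an *incorrect*
   mapping; the incorrect-mapping proportion is tabulated per query
   length and threshold (0.90 and 0.95).

2. **MSA-window similarity networks** — 40-column windows of a NifH
   multiple sequence alignment are degapped per sequence and connected
   by edges at >= threshold identity; a node directly adjacent to the
   opposite label is *confusing*, otherwise *distinct*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .seqalign import DEFAULT_SCORING, ScoringScheme, global_identity

__all__ = [
    "TypedProtein",
    "MappingResult",
    "WindowNetwork",
    "cluster_greedy",
    "sample_subsequences",
    "map_partials",
    "incorrect_mapping_rate",
    "run_mapping_experiment",
    "msa_windows",
    "window_confusion",
]


@dataclass(frozen=True)
class TypedProtein:
    """A NifH amino-acid sequence carrying its truth label."""

    seq_id: str
    sequence: str
    label: str  # "T12" (true) or "T3" (pseudo)
    cluster_rep: bool = False

    def __post_init__(self) -> None:
        if self.label not in ("T12", "T3"):
            raise ValueError("label must be T12 or T3")
        if not self.sequence:
            raise ValueError("sequence must be nonempty")


@dataclass(frozen=True)
class MappingResult:
    query_id: str
    origin_label: str
    length: int
    hits: tuple[tuple[str, str, float], ...]  # (ref_id, ref_label, identity)
    verdict: str  # "correct" | "incorrect" | "unmapped"


@dataclass
class WindowNetwork:
    window_start: int  # 1-based MSA column of the window start
    window_end: int
    graph: nx.Graph
    confusing: dict[str, bool]  # seq_id -> confusing?
    proportions: dict[str, float]  # label -> proportion confusing


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_greedy(
    seqs: Sequence[TypedProtein],
    threshold: float = DEFAULT_CONFIG.cluster_identity,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[TypedProtein]:
    """Greedy incremental clustering; returns cluster representatives.

    Sequences are visited by decreasing length (ties by seq_id); each
    joins the first existing cluster whose representative it matches at
    >= ``threshold`` global identity, else founds a new cluster.  All
    inputs must carry the same label (true and pseudo sets are
    clustered separately).
    """
    labels = {s.label for s in seqs}
    if len(labels) > 1:
        raise ValueError("cluster_greedy expects a single label per call")
    order = sorted(seqs, key=lambda s: (-len(s.sequence), s.seq_id))
    reps: list[TypedProtein] = []
    sizes: list[int] = []
    for s in order:
        for i, rep in enumerate(reps):
            if global_identity(s.sequence, rep.sequence, scoring) >= threshold:
                sizes[i] += 1
                break
        else:
            reps.append(
                TypedProtein(s.seq_id, s.sequence, s.label, cluster_rep=True)
            )
            sizes.append(1)
    return reps


# ---------------------------------------------------------------------------
# partial-sequence mapping
# ---------------------------------------------------------------------------

def sample_subsequences(
    rep: TypedProtein,
    lengths: Sequence[int] = DEFAULT_CONFIG.subseq_lengths,
    n_per_length: int = DEFAULT_CONFIG.subseqs_per_length,
    seed: int | np.random.Generator = 0,
) -> list[TypedProtein]:
    """Random fragments of ``rep`` at each requested length.

    Start positions are uniform; lengths exceeding the sequence are
    skipped with a warning.  Deterministic under a fixed seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out: list[TypedProtein] = []
    n = len(rep.sequence)
    for length in lengths:
        if length <= 0:
            raise ValueError("fragment lengths must be positive")
        if length > n:
            warnings.warn(
                f"{rep.seq_id}: length {length} > sequence length {n}; skipped",
                stacklevel=2,
            )
            continue
        starts = rng.integers(0, n - length + 1, size=n_per_length)
        for k, st in enumerate(starts):
            out.append(
                TypedProtein(
                    seq_id=f"{rep.seq_id}|L{length}|{k}",
                    sequence=rep.sequence[st : st + length],
                    label=rep.label,
                )
            )
    return out


def map_partials(
    queries: Sequence[TypedProtein],
    references: Sequence[TypedProtein],
    threshold: float,
    scoring: ScoringScheme = DEFAULT_SCORING,
    identities: np.ndarray | None = None,
) -> list[MappingResult]:
    """Globally align every query to every reference and call verdicts.

    A hit is a reference at identity >= ``threshold``.  The verdict is
    *incorrect* iff any hit carries the opposite label, *unmapped* iff
    there are no hits, else *correct*.  ``identities`` may carry a
    precomputed (query x reference) identity matrix so several
    thresholds can reuse one alignment pass.
    """
    if identities is None:
        identities = pairwise_identity_matrix(queries, references, scoring)
    results: list[MappingResult] = []
    for qi, q in enumerate(queries):
        hits = tuple(
            (r.seq_id, r.label, float(identities[qi, ri]))
            for ri, r in enumerate(references)
            if identities[qi, ri] >= threshold
        )
        if not hits:
            verdict = "unmapped"
        elif any(lbl != q.label for _, lbl, _ in hits):
            verdict = "incorrect"
        else:
            verdict = "correct"
        results.append(
            MappingResult(
                query_id=q.seq_id,
                origin_label=q.label,
                length=len(q.sequence),
                hits=hits,
                verdict=verdict,
            )
        )
    return results


def pairwise_identity_matrix(
    queries: Sequence[TypedProtein],
    references: Sequence[TypedProtein],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> np.ndarray:
    mat = np.zeros((len(queries), len(references)))
    for qi, q in enumerate(queries):
        for ri, r in enumerate(references):
            mat[qi, ri] = global_identity(q.sequence, r.sequence, scoring)
    return mat


def incorrect_mapping_rate(
    results_by_cell: Mapping[tuple[int, float], Sequence[MappingResult]],
) -> pd.DataFrame:
    """Incorrect / (correct + incorrect) per (length, threshold) cell.

    Unmapped queries are excluded from the denominator and reported in
    their own column; a cell with no mapped queries gets a missing rate
    rather than zero.
    """
    rows = []
    for (length, threshold), results in sorted(results_by_cell.items()):
        n_inc = sum(r.verdict == "incorrect" for r in results)
        n_cor = sum(r.verdict == "correct" for r in results)
        n_unm = sum(r.verdict == "unmapped" for r in results)
        mapped = n_inc + n_cor
        rows.append(
            {
                "length": length,
                "threshold": threshold,
                "n_mapped": mapped,
                "n_unmapped": n_unm,
                "incorrect_rate": (n_inc / mapped) if mapped else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_mapping_experiment(
    t12: Sequence[TypedProtein],
    t3: Sequence[TypedProtein],
    config: AnalysisConfig = DEFAULT_CONFIG,
    seed: int = 0,
    scoring: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Full partial-sequence mapping experiment.

    Clusters each label at ``cluster_identity``, samples fragments from
    every representative, aligns each fragment to all representatives
    once, then tabulates incorrect-mapping rates at every configured
    identity threshold.
    """
    scoring = scoring or ScoringScheme.from_config(config)
    reps = cluster_greedy(t12, config.cluster_identity, scoring) + cluster_greedy(
        t3, config.cluster_identity, scoring
    )
    rng = np.random.default_rng(seed)
    queries: list[TypedProtein] = []
    for rep in reps:
        queries.extend(
            sample_subsequences(
                rep, config.subseq_lengths, config.subseqs_per_length, rng
            )
        )
    identities = pairwise_identity_matrix(queries, reps, scoring)
    cells: dict[tuple[int, float], list[MappingResult]] = {}
    for threshold in config.identity_thresholds:
        results = map_partials(queries, reps, threshold, scoring, identities)
        for res in results:
            cells.setdefault((res.length, threshold), []).append(res)
    return incorrect_mapping_rate(cells)


# ---------------------------------------------------------------------------
# MSA-window similarity networks
# ---------------------------------------------------------------------------

def msa_windows(
    msa: Mapping[str, str] | Sequence[tuple[str, str]],
    labels: Mapping[str, str],
    window: int = DEFAULT_CONFIG.msa_window,
    starts: Sequence[int] = DEFAULT_CONFIG.msa_window_starts,
    min_residues: int = DEFAULT_CONFIG.min_window_residues,
) -> dict[int, list[TypedProtein]]:
    """Cut fixed-width column windows from an MSA and degap each row.

    ``starts`` are 1-based MSA columns.  Rows whose degapped window has
    fewer than ``min_residues`` residues are excluded.  Windows that
    extend past the alignment are skipped with a warning.
    """
    items = list(msa.items()) if isinstance(msa, Mapping) else list(msa)
    if not items:
        return {}
    aln_len = len(items[0][1])
    for name, row in items:
        if len(row) != aln_len:
            raise ValueError(f"MSA row {name} has inconsistent length")
    out: dict[int, list[TypedProtein]] = {}
    for start in starts:
        end = start + window - 1
        if end > aln_len:
            warnings.warn(
                f"window {start}-{end} extends past alignment ({aln_len} cols); "
                "skipped",
                stacklevel=2,
            )
            continue
        subs: list[TypedProtein] = []
        for name, row in items:
            frag = row[start - 1 : end].replace("-", "").replace(".", "")
            if len(frag) < min_residues:
                continue
            subs.append(
                TypedProtein(
                    seq_id=f"{name}|{start}-{end}",
                    sequence=frag,
                    label=labels[name],
                )
            )
        out[start] = subs
    return out


def window_confusion(
    subseqs: Sequence[TypedProtein],
    threshold: float,
    scoring: ScoringScheme = DEFAULT_SCORING,
    window_start: int = 0,
    window_end: int = 0,
) -> WindowNetwork:
    """Similarity network over one window's subsequences.

    Nodes are subsequences; an edge connects every pair at identity >=
    ``threshold``.  A node is *confusing* iff directly adjacent to a
    node of the opposite label.  Proportions of confusing nodes are
    reported per label; with a single-label input they are defined as 0
    with a warning.
    """
    g = nx.Graph()
    for s in subseqs:
        g.add_node(s.seq_id, label=s.label)
    for i in range(len(subseqs)):
        for j in range(i + 1, len(subseqs)):
            ident = global_identity(
                subseqs[i].sequence, subseqs[j].sequence, scoring
            )
            if ident >= threshold:
                g.add_edge(subseqs[i].seq_id, subseqs[j].seq_id, identity=ident)
    labels_present = {s.label for s in subseqs}
    if len(labels_present) < 2:
        warnings.warn(
            "window_confusion: single-label input; proportions defined as 0",
            stacklevel=2,
        )
    confusing: dict[str, bool] = {}
    for s in subseqs:
        confusing[s.seq_id] = any(
            g.nodes[nb]["label"] != s.label for nb in g.neighbors(s.seq_id)
        )
    proportions: dict[str, float] = {}
    for label in ("T12", "T3"):
        members = [s for s in subseqs if s.label == label]
        if members:
            proportions[label] = sum(confusing[s.seq_id] for s in members) / len(
                members
            )
        else:
            proportions[label] = 0.0
    return WindowNetwork(
        window_start=window_start,
        window_end=window_end,
        graph=g,
        confusing=confusing,
        proportions=proportions,
    )
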