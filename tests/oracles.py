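"""Independent brute-force oracles used to validate the optimized code paths.

Everything here deliberately avoids the package's own algorithms:
alignment scores come from exhaustive enumeration of all global
alignments, trimming from an all-substrings scan, and nifH typing from
a direct pairwise distance recount.
"""

from __future__ import annotations

import numpy as np


def enumerate_global_score(a, b, matrix, gap_open, gap_extend):
    """Optimal global alignment score by exhaustive enumeration.

    Walks every monotone alignment path (match/mismatch column, gap in
    ``b``, gap in ``a``) with affine gap scoring: a gap block of length
    L costs ``gap_open + (L-1) * gap_extend``.  Exponential; only for
    tiny sequences.
    """
    best = [-np.inf]

    def walk(i, j, last, score):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):  # consume a[i] against a gap in b
            cost = gap_extend if last == "X" else gap_open
            walk(i + 1, j, "X", score + cost)
        if j < len(b):  # consume b[j] against a gap in a
            cost = gap_extend if last == "Y" else gap_open
            walk(i, j + 1, "Y", score + cost)

    walk(0, 0, "", 0.0)
    return best[0]


def brute_force_trim(probs, max_ee):
    """Longest (leftmost on ties) substring with sum(probs) < max_ee, O(n^2)."""
    n = len(probs)
    prefix = np.concatenate([[0.0], np.cumsum(probs)])
    best_len, best_start = 0, 0
    for start in range(n):
        for end in range(start + 1, n + 1):
            if prefix[end] - prefix[start] < max_ee:
                if end - start > best_len:
                    best_len, best_start = end - start, start
    return best_start, best_len


def brute_force_nifh_types(records, radius):
    """Type every nifH CDS by direct pairwise recount.

    ``records`` are objects with replicon_id / strand / start /
    locus_tag and a gene class of "H", "D", "K" or None (provided by
    the caller as ``(record, cls)`` pairs).  Distance between two CDSs
    is the difference of their ranks within the sorted same-strand,
    same-replicon subset.
    """
    dk = [(r, c) for r, c in records if c in ("D", "K")]
    out = {}
    for r, c in records:
        if c != "H":
            continue
        neighbors = 0
        for other, _ in dk:
            if (
                other.replicon_id == r.replicon_id
                and other.strand == r.strand
            ):
                lane = sorted(
                    (
                        x
                        for x, _ in records
                        if x.replicon_id == r.replicon_id
                        and x.strand == r.strand
                    ),
                    key=lambda x: (x.start, x.end, x.locus_tag),
                )
                ranks = {x.locus_tag: k for k, x in enumerate(lane)}
                if abs(ranks[other.locus_tag] - ranks[r.locus_tag]) <= radius:
                    neighbors += 1
        if neighbors:
            out[r.locus_tag] = "T1"
        elif dk:
            out[r.locus_tag] = "T2"
        else:
            out[r.locus_tag] = "T3"
    return out


def brute_force_confusing(subseqs, identities, threshold):
    """Adjacency recomputation for the window networks.

    ``identities[i][j]`` is the pairwise identity of subsequences i and
    j; a node is confusing iff some opposite-label node sits at
    identity >= threshold.
    """
    out = {}
    for i, s in enumerate(subseqs):
        out[s.seq_id] = any(
            identities[i][j] >= threshold and subseqs[j].label != s.label
            for j in range(len(subseqs))
            if j != i
        )
    return out
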