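"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible — nested loops over all
site pairs, repeated pairwise interval merging — and deliberately shares no
code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def intervals_intersect(s1, e1, s2, e2) -> bool:
    """Half-open interval intersection."""
    return s1 < e2 and s2 < e1


def brute_cooccurrence_matrix(records, tf_names, tf, window_bp):
    """O(m^2) co-occurrence matrix for one focal TF.

    ``records`` is a sequence of (chrom, start, end, tf) tuples in the same
    order as the collection's records.
    """
    tf_index = {name: i for i, name in enumerate(tf_names)}
    focal = [i for i, r in enumerate(records) if r[3] == tf]
    M = np.zeros((len(tf_names), len(focal)), dtype=np.uint8)
    for j, fi in enumerate(focal):
        chrom, start, end, _ = records[fi]
        qs, qe = start - window_bp, end + window_bp
        for gi, (c2, s2, e2, t2) in enumerate(records):
            if gi == fi or c2 != chrom:
                continue
            if intervals_intersect(qs, qe, s2, e2):
                M[tf_index[t2], j] = 1
    return M


def brute_merge(intervals):
    """Repeated pairwise merging of intersecting intervals until fixpoint."""
    work = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                a, b = work[i], work[j]
                if a[0] == b[0] and intervals_intersect(a[1], a[2], b[1], b[2]):
                    work[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    del work[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(iv) for iv in work)


def brute_recall(actual_records, retained_intervals, window_bp):
    """Fraction of actual sites with a retained interval in their window."""
    hits = 0
    for chrom, start, end, _tf in actual_records:
        qs, qe = start - window_bp, end + window_bp
        for c2, s2, e2 in retained_intervals:
            if c2 == chrom and intervals_intersect(qs, qe, s2, e2):
                hits += 1
                break
    return hits / len(actual_records)


def brute_precision(retained_intervals, actual_records, window_bp):
    """Fraction of retained intervals with an actual site in their window."""
    hits = 0
    for chrom, start, end in retained_intervals:
        qs, qe = start - window_bp, end + window_bp
        for c2, s2, e2, _tf in actual_records:
            if c2 == chrom and intervals_intersect(qs, qe, s2, e2):
                hits += 1
                break
    return hits / len(retained_intervals)
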