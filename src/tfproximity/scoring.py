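"""Co-occurrence-driven scoring and filtering of putative TFBSs.

Motif scans return putative binding sites riddled with false positives.  A
putative site of a *target* TF is more believable when the TFs that usually
co-occur with the target are found nearby — and less believable when its
window holds TFs the target is depleted near.  Each putative target site
therefore receives a *sum-score*: the sum, over every neighboring putative
TFBS instance in the window, of the signed unfiltered edge weight from the
target to that neighbor's TF.  Negative edges deliberately count against
the site.  Thresholding the scores and comparing the retained set against
experimentally determined (ChIP-seq) sites yields precision/recall/F
sweeps; a random-removal baseline and a neighbor-count ("length") score
serve as controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .collection import TFBSCollection, TFBSRecord
from .graph import DEFAULT_WINDOW_BP, CooccurrenceGraph

__all__ = [
    "ScoredSite",
    "PRCurve",
    "PRF",
    "merge_overlapping",
    "sum_scores",
    "recall",
    "precision",
    "f_score",
    "pr_sweep",
    "random_baseline",
    "length_scores",
]

Interval3 = tuple[str, int, int]

_METHOD_FIELDS = {
    "sum": "sum_score",
    "normalized_sum": "normalized_score",
    "length": "n_neighbors",
}


@dataclass
class ScoredSite:
    """One putative site of the target TF with its co-occurrence scores."""

    site: TFBSRecord
    sum_score: float
    n_neighbors: int
    normalized_score: float


class PRF(NamedTuple):
    precision: float
    recall: float
    f_score: float
    n_retained: int


@dataclass
class PRCurve:
    """Precision/recall/F as a function of the retention cutoff."""

    method: str
    cutoffs: np.ndarray
    n_retained: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray
    descending: bool = False

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.f_score))

    @property
    def best_cutoff(self) -> float:
        return float(self.cutoffs[self.best_index])

    @property
    def best(self) -> PRF:
        i = self.best_index
        return PRF(
            float(self.precision[i]),
            float(self.recall[i]),
            float(self.f_score[i]),
            int(self.n_retained[i]),
        )

    @property
    def unfiltered(self) -> PRF:
        """Metrics at the no-removal end of the sweep (first cutoff)."""
        return PRF(
            float(self.precision[0]),
            float(self.recall[0]),
            float(self.f_score[0]),
            int(self.n_retained[0]),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "n_retained": self.n_retained,
                "precision": self.precision,
                "recall": self.recall,
                "f_score": self.f_score,
            }
        )


def _as_intervals(sites: Iterable[TFBSRecord | Interval3]) -> list[Interval3]:
    out: list[Interval3] = []
    for s in sites:
        if isinstance(s, TFBSRecord):
            out.append((s.chrom, s.start, s.end))
        else:
            chrom, start, end = s
            out.append((chrom, int(start), int(end)))
    return out


def merge_overlapping(sites: Iterable[TFBSRecord | Interval3]) -> list[Interval3]:
    """Condense overlapping intervals into their union, per chromosome.

    Intervals are half-open; abutting intervals ([10,20) and [20,30)) do
    not overlap and are kept separate.  Output is sorted and disjoint.
    """
    ivs = sorted(_as_intervals(sites))
    merged: list[Interval3] = []
    for chrom, start, end in ivs:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def sum_scores(
    target: str,
    putative: TFBSCollection,
    graph: CooccurrenceGraph,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[ScoredSite]:
    """Score every putative site of the target TF with the signed graph.

    Neighbors are *all* putative TFBS instances of any TF within the window
    (other target sites included, weighted by the self-loop), excluding the
    focal site itself.  Each instance contributes the edge weight from the
    target to its TF — so multiple nearby sites of a strong partner boost
    the score, and depleted (negative-edge) TFs drag it down.

    The graph must be the *unfiltered, signed* graph built from the same
    putative collection.
    """
    t_idx = graph.tf_index(target)  # raises for unknown TF
    if target not in putative:
        raise KeyError(f"target TF {target!r} has no sites in the putative collection")
    tf_to_graph = {}
    for tf in putative.tf_names:
        try:
            tf_to_graph[tf] = graph.tf_index(tf)
        except KeyError:
            raise KeyError(
                f"TF {tf!r} present in the putative collection but absent from the "
                "graph; build the graph from the same collection"
            ) from None
    W_row = graph.W[t_idx]
    scored: list[ScoredSite] = []
    for g in putative.site_indices_of(target):
        total = 0.0
        count = 0
        for nb in putative.neighbors(int(g), window_bp):
            total += W_row[tf_to_graph[putative.records[nb].tf]]
            count += 1
        scored.append(
            ScoredSite(
                site=putative.records[int(g)],
                sum_score=float(total),
                n_neighbors=count,
                normalized_score=float(total) / count if count else 0.0,
            )
        )
    return scored


def _group_by_chrom(intervals: Sequence[Interval3]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, pairs in by.items():
        pairs.sort()
        arr = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def _any_overlap(
    qs: int, qe: int, starts: np.ndarray, max_end_prefix: np.ndarray
) -> bool:
    # a site with start < qe and end > qs exists iff the running max end
    # among sites starting before qe exceeds qs
    idx = int(np.searchsorted(starts, qe, side="left"))
    return idx > 0 and int(max_end_prefix[idx - 1]) > qs


def recall(
    actual: TFBSCollection,
    putative_retained: Iterable[TFBSRecord | Interval3],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> float:
    """Fraction of actual sites with a retained putative site in their window."""
    if actual.n_sites == 0:
        raise ValueError("recall undefined: no actual sites")
    retained = _as_intervals(putative_retained)
    if not retained:
        return 0.0
    by_chrom = {
        chrom: (starts, np.maximum.accumulate(ends))
        for chrom, (starts, ends) in _group_by_chrom(retained).items()
    }
    hits = 0
    for r in actual.records:
        qs, qe = r.window(window_bp)
        arrs = by_chrom.get(r.chrom)
        if arrs is not None and _any_overlap(qs, qe, arrs[0], arrs[1]):
            hits += 1
    return hits / actual.n_sites


def precision(
    putative_retained: Sequence[Interval3],
    actual: TFBSCollection,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> float:
    """Fraction of (merged) retained putative intervals with an actual site in-window.

    Callers should merge overlapping putatives first (``merge_overlapping``)
    so the divisor counts condensed sites and precision cannot exceed 1.
    """
    retained = _as_intervals(putative_retained)
    if not retained:
        raise ValueError("precision undefined: no retained putative sites")
    actual_by_chrom = {
        chrom: (starts, np.maximum.accumulate(ends))
        for chrom, (starts, ends) in _group_by_chrom(
            [(r.chrom, r.start, r.end) for r in actual.records]
        ).items()
    }
    hits = 0
    for chrom, s, e in retained:
        arrs = actual_by_chrom.get(chrom)
        if arrs is not None and _any_overlap(s - window_bp, e + window_bp, arrs[0], arrs[1]):
            hits += 1
    return hits / len(retained)


def f_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError(f"precision and recall must be in [0, 1]: p={p}, r={r}")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def _evaluate_retained(
    retained_sites: Sequence[TFBSRecord],
    actual: TFBSCollection,
    window_bp: int,
) -> PRF:
    merged = merge_overlapping(retained_sites)
    p = precision(merged, actual, window_bp)
    r = recall(actual, merged, window_bp)
    return PRF(p, r, f_score(p, r), len(retained_sites))


def pr_sweep(
    scored: Sequence[ScoredSite],
    actual: TFBSCollection,
    method: str = "sum",
    window_bp: int = DEFAULT_WINDOW_BP,
    descending: bool = False,
) -> PRCurve:
    """Sweep the retention cutoff over all distinct score values.

    With ``descending=False`` (the default) sites with score >= cutoff are
    retained and cutoffs ascend from -inf (no removal) to the maximum score
    (only the top-scoring sites remain).  ``descending=True`` flips the
    thresholding — sites with score <= cutoff are retained and cutoffs
    descend from +inf — which is how the neighbor-count score is swept when
    it anticorrelates with the sum-score.  The sweep stops before the
    retained set would be empty.
    """
    if not scored:
        raise ValueError("no scored sites to sweep")
    if method not in _METHOD_FIELDS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHOD_FIELDS)}")
    field = _METHOD_FIELDS[method]
    values = np.asarray([getattr(s, field) for s in scored], dtype=np.float64)
    distinct = np.unique(values)
    if descending:
        cutoffs = np.concatenate(([np.inf], distinct[::-1]))
    else:
        cutoffs = np.concatenate(([-np.inf], distinct))
    ps, rs, fs, ns, kept_cutoffs = [], [], [], [], []
    for c in cutoffs:
        keep = values <= c if descending else values >= c
        if not keep.any():
            continue
        retained = [scored[i].site for i in np.flatnonzero(keep)]
        res = _evaluate_retained(retained, actual, window_bp)
        kept_cutoffs.append(c)
        ps.append(res.precision)
        rs.append(res.recall)
        fs.append(res.f_score)
        ns.append(res.n_retained)
    return PRCurve(
        method=method,
        cutoffs=np.asarray(kept_cutoffs),
        n_retained=np.asarray(ns, dtype=np.int64),
        precision=np.asarray(ps),
        recall=np.asarray(rs),
        f_score=np.asarray(fs),
        descending=descending,
    )


def random_baseline(
    scored: Sequence[ScoredSite],
    n_remove: int,
    seed: int | None,
    actual: TFBSCollection,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> PRF:
    """Remove ``n_remove`` putative sites uniformly at random and evaluate.

    Controls for the possibility that score-based filtering helps merely by
    shrinking the retrieved set.
    """
    total = len(scored)
    if not 0 <= n_remove < total:
        raise ValueError(
            f"n_remove must be in [0, {total - 1}] (removing all {total} sites "
            "leaves nothing to evaluate)"
        )
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(total, size=total - n_remove, replace=False)
    retained = [scored[int(i)].site for i in sorted(keep_idx)]
    return _evaluate_retained(retained, actual, window_bp)


def length_scores(
    target: str,
    putative: TFBSCollection,
    window_bp: int = DEFAULT_WINDOW_BP,
    graph: CooccurrenceGraph | None = None,
) -> list[ScoredSite]:
    """Scores where the value of interest is the raw neighbor count.

    Needs no graph: the score is simply the number of neighboring putative
    TFBSs in each window (``sum_score`` is filled in too when a graph is
    supplied).  Sweep with ``method="length"``, optionally
    ``descending=True``, to threshold on neighbor count; the descending
    direction matters when the count anticorrelates with the sum-score.
    """
    if graph is not None:
        return sum_scores(target, putative, graph, window_bp)
    if target not in putative:
        raise KeyError(f"target TF {target!r} has no sites in the putative collection")
    scored: list[ScoredSite] = []
    for g in putative.site_indices_of(target):
        count = len(putative.neighbors(int(g), window_bp))
        scored.append(
            ScoredSite(
                site=putative.records[int(g)],
                sum_score=0.0,
                n_neighbors=count,
                normalized_score=0.0,
            )
        )
    return scored
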