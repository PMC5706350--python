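"""Benchmarking predicted TF–TF interactions.

Three independent checks of whether the graph's edges mean anything
biologically:

* agreement of the filtered graph's surviving edges with a reference
  protein–protein interaction table (precision/recall/F over unordered TF
  pairs, self-loops excluded);
* enrichment of the predicted interactions in individual reference evidence
  channels (one-sided rank-sum: do reference pairs our graph predicts carry
  higher channel scores than reference pairs it misses?);
* ordinary least-squares regression of edge weight on motif (PWM)
  similarity — a low R² means proximity co-occurrence carries information
  that motif similarity alone does not.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import stats

from .io import ReferenceInteractions, SimilarityTable, canonical_channel
from .scoring import f_score

__all__ = [
    "ComparisonResult",
    "EnrichmentResult",
    "RegressionResult",
    "compare_to_reference",
    "channel_enrichment",
    "rank_enrichment",
    "similarity_regression",
]


class _EdgePredictor(Protocol):
    tf_names: tuple[str, ...]

    def has_edge(self, tf1: str, tf2: str) -> bool: ...


class _WeightedGraph(Protocol):
    tf_names: tuple[str, ...]

    def weight(self, tf1: str, tf2: str) -> float: ...


@dataclass
class ComparisonResult:
    """Confusion counts and retrieval metrics against a reference table."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_score: float
    n_tfs_matched: int
    n_tfs_dropped: int


@dataclass
class EnrichmentResult:
    """One-sided rank-sum enrichment of one evidence channel."""

    channel: str
    p_value: float
    direction: str  # "greater", "less", or "none"
    n_matched: int
    n_unmatched: int


@dataclass
class RegressionResult:
    """OLS of undirected edge weight on pairwise motif similarity."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int


def compare_to_reference(
    filtered: _EdgePredictor, ref: ReferenceInteractions
) -> ComparisonResult:
    """Count TP/FP/TN/FN over unordered matched-TF pairs.

    TFs absent from the reference's protein universe are dropped (no name
    mapping is attempted).  Over the remaining pairs, self-loops excluded:
    a true positive is a surviving edge whose pair the reference also
    lists; a true negative is a pair in neither.
    """
    matched = sorted(set(filtered.tf_names) & ref.proteins)
    n_dropped = len(filtered.tf_names) - len(matched)
    if len(matched) < 2:
        raise ValueError(
            f"only {len(matched)} graph TF(s) match the reference; need >= 2"
        )
    tp = fp = tn = fn = 0
    for a, b in itertools.combinations(matched, 2):
        predicted = filtered.has_edge(a, b)
        in_ref = (a, b) in ref
        if predicted and in_ref:
            tp += 1
        elif predicted:
            fp += 1
        elif in_ref:
            fn += 1
        else:
            tn += 1
    if tp + fp == 0:
        warnings.warn(
            "no predicted edges among matched pairs; precision reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        p = 0.0
    else:
        p = tp / (tp + fp)
    r = tp / (tp + fn) if tp + fn else 0.0
    return ComparisonResult(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        precision=p,
        recall=r,
        f_score=f_score(p, r),
        n_tfs_matched=len(matched),
        n_tfs_dropped=n_dropped,
    )


def rank_enrichment(
    matched_scores: Sequence[float], unmatched_scores: Sequence[float]
) -> tuple[float, str]:
    """One-sided Mann–Whitney rank-sum: matched > unmatched.

    Channel scores are bounded, zero-inflated and non-normal, so a rank
    test is used rather than a t-test.  Fully tied inputs give p = 1.
    """
    x = np.asarray(matched_scores, dtype=float)
    y = np.asarray(unmatched_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0, "none"
    res = stats.mannwhitneyu(x, y, alternative="greater")
    mx, my = float(np.mean(x)), float(np.mean(y))
    direction = "greater" if mx > my else ("less" if mx < my else "none")
    return float(res.pvalue), direction


def channel_enrichment(
    filtered: _EdgePredictor, ref: ReferenceInteractions, channel: str
) -> EnrichmentResult:
    """Test whether predicted reference pairs are enriched in one channel.

    Reference pairs with both TFs in the graph are split into those the
    filtered graph predicts and those it does not; their channel scores are
    compared with a one-sided rank-sum test (predicted > unpredicted).
    """
    key = canonical_channel(channel)
    in_graph = set(filtered.tf_names)
    matched, unmatched = [], []
    for pair in ref.pairs:
        a, b = pair
        if a not in in_graph or b not in in_graph:
            continue
        score = ref.channel_scores[pair][key]
        (matched if filtered.has_edge(a, b) else unmatched).append(score)
    if not matched or not unmatched:
        raise ValueError(
            f"cannot test channel {channel!r}: matched group has {len(matched)} "
            f"pairs, unmatched has {len(unmatched)}"
        )
    p, direction = rank_enrichment(matched, unmatched)
    return EnrichmentResult(
        channel=key,
        p_value=p,
        direction=direction,
        n_matched=len(matched),
        n_unmatched=len(unmatched),
    )


def similarity_regression(
    graph: _WeightedGraph, sim: SimilarityTable
) -> RegressionResult:
    """OLS of undirected edge weight on PWM similarity over shared pairs.

    Pairs present in both the similarity table and the graph (self-pairs
    excluded) enter the fit; R² = 1 - SS_res/SS_tot.
    """
    names = set(graph.tf_names)
    xs, ys = [], []
    for (a, b), s in sim.items():
        if a == b or a not in names or b not in names:
            continue
        xs.append(s)
        ys.append(graph.weight(a, b))
    if len(xs) < 3:
        raise ValueError(
            f"need >= 3 TF pairs shared between graph and similarity table, got {len(xs)}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("similarity scores have zero variance; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_pairs=len(xs),
    )
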