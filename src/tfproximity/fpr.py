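"""Permutation-based false-positive-rate calibration and edge filtering.

The co-occurrence frequencies come from a non-random sample (a TF's own
sites), so a parametric null for edge weights is not defensible.  Instead,
the adjacency construction is re-run on *dummy* co-occurrence matrices whose
rows are i.i.d. Bernoulli draws at each TF's genome-wide background
frequency: overall TF prevalence is preserved while genomic order, and hence
proximity structure, is destroyed.  Every directed entry of each dummy
adjacency matrix joins a pooled null distribution; the weight threshold for
a target FPR is the smallest pooled weight exceeded by at most that fraction
of the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .collection import TFBSCollection
from .graph import BackgroundVector, CooccurrenceGraph

__all__ = [
    "DummyWeightPool",
    "ThresholdResult",
    "FilteredGraph",
    "dummy_pool",
    "threshold_for_fpr",
    "filter_graph",
]

DEFAULT_N_REPS = 25
FPR_GRID = (0.1, 0.01, 0.001, 0.0001)


@dataclass
class DummyWeightPool:
    """Null distribution of directed dummy edge weights.

    Holds ``n_reps * n**2`` weights: all directed (pre-symmetrization)
    entries of each repeat's dummy adjacency matrix.
    """

    weights: np.ndarray
    n_reps: int
    n: int
    seed: int | None

    def __len__(self) -> int:
        return len(self.weights)


class ThresholdResult(NamedTuple):
    threshold: float
    achieved_fpr: float
    pool_size: int


def dummy_pool(
    collection: TFBSCollection,
    f_all: BackgroundVector | np.ndarray,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
) -> DummyWeightPool:
    """Generate the permutation null pool of directed edge weights.

    Per repeat, each TF's co-occurrence matrix is replaced by an
    ``n x m_t`` matrix whose row *i* is i.i.d. Bernoulli(``f_all[i]``), and
    the full adjacency construction — including recomputing the background
    vector from the dummy matrices themselves — is re-run.  Only row sums
    enter the construction, so each row mean is sampled directly as
    ``Binomial(m_t, f_all[i]) / m_t`` (an exact distributional shortcut).

    Returns all ``n_reps * n**2`` directed entries of the dummy adjacency
    matrices, flattened.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    p = f_all.values if isinstance(f_all, BackgroundVector) else np.asarray(f_all, float)
    n = collection.n_tfs
    if p.shape != (n,):
        raise ValueError(f"f_all has length {p.shape}, expected ({n},)")
    m = collection.site_counts.astype(np.int64)
    w = int(m.sum())
    rng = np.random.default_rng(seed)
    weights = np.empty(n_reps * n * n, dtype=np.float64)
    for rep in range(n_reps):
        # counts[i, t] ~ Binomial(m_t, f_all[i]): row sums of dummy M_t
        counts = rng.binomial(m[None, :], p[:, None])
        F = counts / m[None, :]
        f_all_dummy = counts.sum(axis=1, dtype=np.float64) / w
        A = F - f_all_dummy[:, None]
        weights[rep * n * n : (rep + 1) * n * n] = A.ravel()
    return DummyWeightPool(weights=weights, n_reps=n_reps, n=n, seed=seed)


def threshold_for_fpr(pool: DummyWeightPool, fpr: float) -> ThresholdResult:
    """Smallest pooled weight exceeded by at most ``fpr`` of the pool.

    A dummy weight strictly greater than the threshold is a false positive;
    one at or below it is a true negative.  Returns the threshold together
    with the FPR actually achieved on the pool (<= the target, possibly
    smaller under ties).
    """
    if not 0.0 < fpr < 1.0:
        raise ValueError(f"fpr must be in (0, 1), got {fpr}")
    w = np.sort(np.asarray(pool.weights, dtype=np.float64))
    total = w.size
    if total == 0:
        raise ValueError("empty dummy pool")
    uniq = np.unique(w)
    # count of pool weights strictly greater than each candidate threshold
    above = total - np.searchsorted(w, uniq, side="right")
    ok = above <= fpr * total
    theta = uniq[np.argmax(ok)]  # smallest candidate meeting the target
    achieved = float(above[np.argmax(ok)]) / total
    return ThresholdResult(threshold=float(theta), achieved_fpr=achieved, pool_size=total)


@dataclass
class FilteredGraph:
    """A co-occurrence graph with sub-threshold edges removed.

    Surviving undirected edges (self-loops included) are exactly those with
    symmetric weight >= ``threshold``; edges strictly below are removed.
    """

    graph: CooccurrenceGraph
    threshold: float
    fpr_target: float | None = None
    achieved_fpr: float | None = None
    mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        self.mask = self.graph.W >= self.threshold

    @property
    def tf_names(self) -> tuple[str, ...]:
        return self.graph.tf_names

    @property
    def n(self) -> int:
        return self.graph.n

    @property
    def n_edges_total(self) -> int:
        return self.graph.n_edges

    @property
    def n_edges_surviving(self) -> int:
        n = self.n
        upper = np.triu(self.mask)
        return int(upper.sum())

    @property
    def n_edges_filtered(self) -> int:
        return self.n_edges_total - self.n_edges_surviving

    @property
    def pct_edges_filtered(self) -> float:
        return 100.0 * self.n_edges_filtered / self.n_edges_total

    def has_edge(self, tf1: str, tf2: str) -> bool:
        i, j = self.graph.tf_index(tf1), self.graph.tf_index(tf2)
        return bool(self.mask[i, j])

    def weight(self, tf1: str, tf2: str) -> float:
        return self.graph.weight(tf1, tf2)

    def surviving_pairs(self) -> Iterator[tuple[int, int]]:
        """Index pairs ``(i, j)`` with ``i <= j`` of surviving edges."""
        iu, ju = np.nonzero(np.triu(self.mask))
        return zip(iu.tolist(), ju.tolist())

    def weight_matrix(self) -> np.ndarray:
        """Symmetric weight matrix with removed edges zeroed."""
        return np.where(self.mask, self.graph.W, 0.0)


def filter_graph(
    graph: CooccurrenceGraph,
    threshold: float,
    fpr_target: float | None = None,
    achieved_fpr: float | None = None,
) -> FilteredGraph:
    """Remove every undirected edge (incl. self-loops) with weight < threshold."""
    return FilteredGraph(
        graph=graph,
        threshold=threshold,
        fpr_target=fpr_target,
        achieved_fpr=achieved_fpr,
    )
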