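"""Windowed TF–TF co-occurrence graphs.

For each TF *t* with sites :math:`B_t`, the co-occurrence matrix
:math:`M_t` is the :math:`n \\times m_t` binary matrix whose entry
:math:`(i, j)` is 1 iff TF *i* has at least one site within the proximity
window of the *j*-th site of *t*.  Row means give the co-occurrence
frequency vector :math:`f_t`; pooling row sums over all TFs and dividing by
the total site count *w* gives the genome-wide background vector
:math:`f_{all}`.  The normalized frequencies :math:`f'_t = f_t - f_{all}`
strip the background prevalence of each TF (frequent binders such as CTCF
would otherwise dominate every vector) and may legitimately be negative —
a TF seen *less* often near *t* than expected.

Column-stacking the :math:`f'_t` yields the directed adjacency matrix
:math:`A`; the undirected edge weight between *i* and *j* is the mean of
the two directed entries.  The graph is complete, with
:math:`n(n+1)/2` undirected edges including self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .collection import TFBSCollection

__all__ = [
    "CooccurrenceMatrix",
    "FrequencyVector",
    "BackgroundVector",
    "CooccurrenceGraph",
    "cooccurrence_matrix",
    "frequency_vector",
    "background_vector",
    "normalize",
    "build_graph",
]

DEFAULT_WINDOW_BP = 1000


@dataclass
class CooccurrenceMatrix:
    """Binary co-occurrence matrix :math:`M_t` for one focal TF.

    Rows are indexed by ``tf_names``; column *j* corresponds to the *j*-th
    site of the focal TF (record index ``site_indices[j]``).
    """

    tf: str
    tf_names: tuple[str, ...]
    matrix: np.ndarray  # (n_tfs, m_t), uint8 in {0, 1}
    site_indices: np.ndarray

    @property
    def m(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FrequencyVector:
    """Per-site co-occurrence frequencies :math:`f_t` (row means of M_t)."""

    tf: str
    tf_names: tuple[str, ...]
    values: np.ndarray


@dataclass
class BackgroundVector:
    """Genome-wide windowed binding frequencies :math:`f_{all}`."""

    tf_names: tuple[str, ...]
    values: np.ndarray


@dataclass
class CooccurrenceGraph:
    """The signed, weighted TF co-occurrence graph.

    ``A`` is the directed matrix whose column *t* is :math:`f'_t`; ``W`` is
    the symmetrized edge-weight matrix ``(A + A.T) / 2``.  Self-loops (the
    diagonal) are data-derived: how often a TF's own other sites fall in its
    windows, relative to background.
    """

    tf_names: tuple[str, ...]
    A: np.ndarray
    W: np.ndarray
    window_bp: int
    f_all: np.ndarray | None = None
    site_counts: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {tf: i for i, tf in enumerate(self.tf_names)}

    @property
    def n(self) -> int:
        return len(self.tf_names)

    @property
    def n_edges(self) -> int:
        """Undirected edge count including self-loops: n(n+1)/2."""
        return self.n * (self.n + 1) // 2

    def tf_index(self, tf: str) -> int:
        try:
            return self._index[tf]
        except KeyError:
            raise KeyError(f"TF {tf!r} not in graph") from None

    def weight(self, tf1: str, tf2: str) -> float:
        return float(self.W[self.tf_index(tf1), self.tf_index(tf2)])


def cooccurrence_matrix(
    collection: TFBSCollection, tf: str, window_bp: int = DEFAULT_WINDOW_BP
) -> CooccurrenceMatrix:
    """Build the binary co-occurrence matrix for one focal TF.

    Entry ``(i, j)`` is 1 iff TF *i* has a site intersecting
    ``[start_j - window_bp, end_j + window_bp)`` where site *j* is the
    *j*-th site of ``tf``.  The focal site itself is excluded from its own
    neighborhood, but *other* sites of the same TF do count, so the focal
    TF's own row is meaningful (it becomes the self-loop weight).
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    site_idx = collection.site_indices_of(tf)  # raises KeyError for unknown TF
    M = np.zeros((collection.n_tfs, len(site_idx)), dtype=np.uint8)
    for j, g in enumerate(site_idx):
        for nb in collection.neighbors(int(g), window_bp):
            M[collection.tf_of_site(nb), j] = 1
    return CooccurrenceMatrix(
        tf=tf, tf_names=collection.tf_names, matrix=M, site_indices=site_idx
    )


def frequency_vector(M: CooccurrenceMatrix) -> FrequencyVector:
    """Row means of :math:`M_t`: the fraction of *t*'s sites near each TF."""
    if M.m == 0:
        raise ValueError(f"TF {M.tf!r} has zero sites; frequency undefined")
    values = M.matrix.sum(axis=1, dtype=np.float64) / M.m
    return FrequencyVector(tf=M.tf, tf_names=M.tf_names, values=values)


def background_vector(matrices: Iterable[CooccurrenceMatrix]) -> BackgroundVector:
    """Row mean of all :math:`M_t` concatenated horizontally.

    Equals the per-TF frequency vectors pooled over all *w* sites, i.e. the
    ``m_t``-weighted mean of the :math:`f_t`.
    """
    total: np.ndarray | None = None
    tf_names: tuple[str, ...] | None = None
    w = 0
    for M in matrices:
        if total is None:
            total = np.zeros(M.matrix.shape[0], dtype=np.float64)
            tf_names = M.tf_names
        elif M.tf_names != tf_names:
            raise ValueError("co-occurrence matrices index different TF sets")
        total += M.matrix.sum(axis=1, dtype=np.float64)
        w += M.m
    if total is None or w == 0:
        raise ValueError("no sites: background frequency undefined")
    return BackgroundVector(tf_names=tf_names, values=total / w)


def normalize(
    f: FrequencyVector | np.ndarray, f_all: BackgroundVector | np.ndarray
) -> np.ndarray:
    """Normalized co-occurrence frequencies :math:`f'_t = f_t - f_{all}`.

    Subtraction (rather than division) penalizes background prevalence
    evenly and allows negative entries, which the TFBS sum-score exploits.
    """
    fv = f.values if isinstance(f, FrequencyVector) else np.asarray(f, dtype=float)
    bv = (
        f_all.values
        if isinstance(f_all, BackgroundVector)
        else np.asarray(f_all, dtype=float)
    )
    if fv.shape != bv.shape:
        raise ValueError(f"length mismatch: {fv.shape} vs {bv.shape}")
    return fv - bv


def build_graph(
    collection: TFBSCollection, window_bp: int = DEFAULT_WINDOW_BP
) -> CooccurrenceGraph:
    """End-to-end construction of the signed co-occurrence graph.

    Assembles A column-wise from the normalized frequency vectors and
    symmetrizes: ``W = (A + A.T) / 2``.  Requires at least two TFs.
    """
    n = collection.n_tfs
    if n < 2:
        raise ValueError("graph construction needs at least 2 TFs")
    w = collection.n_sites
    F = np.empty((n, n), dtype=np.float64)
    totals = np.zeros(n, dtype=np.float64)
    for t, tf in enumerate(collection.tf_names):
        M = cooccurrence_matrix(collection, tf, window_bp)
        row_sums = M.matrix.sum(axis=1, dtype=np.float64)
        F[:, t] = row_sums / M.m
        totals += row_sums
    f_all = totals / w
    A = F - f_all[:, None]
    W = (A + A.T) / 2.0
    return CooccurrenceGraph(
        tf_names=collection.tf_names,
        A=A,
        W=W,
        window_bp=window_bp,
        f_all=f_all,
        site_counts=collection.site_counts.copy(),
    )
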