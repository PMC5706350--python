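"""Core container for transcription-factor binding sites (TFBSs).

A :class:`TFBSRecord` is a single genomic interval bound by one TF, in BED
convention: 0-based, half-open ``[start, end)``.  A :class:`TFBSCollection`
holds the full set of sites across all TFs, sorted by genomic position and
indexed for windowed proximity queries — the only geometric primitive the
co-occurrence method needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
from intervaltree import Interval, IntervalTree

__all__ = ["TFBSRecord", "TFBSCollection"]


@dataclass(frozen=True, slots=True)
class TFBSRecord:
    """A single binding site: chromosome, 0-based half-open interval, TF name."""

    chrom: str
    start: int
    end: int
    tf: str

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("TF name must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end}) for TF {self.tf!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def window(self, window_bp: int) -> tuple[int, int]:
        """The proximity window: the site extended by ``window_bp`` on each side."""
        return self.start - window_bp, self.end + window_bp


def _sort_key(r: TFBSRecord) -> tuple[str, int, int, str]:
    return (r.chrom, r.start, r.end, r.tf)


class TFBSCollection:
    """The set of all binding sites across TFs, sorted and interval-queryable.

    Records are sorted by ``(chrom, start, end)``; duplicate identical records
    are kept (multiple experiments may report the same peak).  TF names are
    stored in sorted order and define the row/column index order of every
    matrix built downstream, so all derived quantities are invariant to the
    order in which records were supplied.

    Attributes
    ----------
    records : list of TFBSRecord
        All sites, sorted.
    tf_names : tuple of str
        Distinct TF identifiers, lexicographically sorted.
    site_counts : numpy.ndarray
        Per-TF site counts ``m_t``, aligned with ``tf_names``.
    """

    def __init__(self, records: Iterable[TFBSRecord]):
        recs = sorted(records, key=_sort_key)
        if not recs:
            raise ValueError("a TFBS collection must contain at least one record")
        self.records: list[TFBSRecord] = recs
        self.tf_names: tuple[str, ...] = tuple(sorted({r.tf for r in recs}))
        self._tf_index: dict[str, int] = {tf: i for i, tf in enumerate(self.tf_names)}
        m = len(recs)
        self._tf_idx = np.fromiter(
            (self._tf_index[r.tf] for r in recs), dtype=np.intp, count=m
        )
        self._starts = np.fromiter((r.start for r in recs), dtype=np.int64, count=m)
        self._ends = np.fromiter((r.end for r in recs), dtype=np.int64, count=m)
        self.site_counts: np.ndarray = np.bincount(
            self._tf_idx, minlength=len(self.tf_names)
        )
        self._trees: dict[str, IntervalTree] | None = None

    @classmethod
    def from_records(cls, records: Iterable[TFBSRecord]) -> "TFBSCollection":
        return cls(records)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TFBSRecord]:
        return iter(self.records)

    def __contains__(self, tf: str) -> bool:
        return tf in self._tf_index

    @property
    def n_sites(self) -> int:
        """Total site count ``w``."""
        return len(self.records)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_names)

    def tf_index(self, tf: str) -> int:
        try:
            return self._tf_index[tf]
        except KeyError:
            raise KeyError(f"unknown TF {tf!r}") from None

    def count(self, tf: str) -> int:
        """Number of sites ``m_t`` for one TF."""
        return int(self.site_counts[self.tf_index(tf)])

    def tf_of_site(self, idx: int) -> int:
        """TF index (into ``tf_names``) of record ``idx``."""
        return int(self._tf_idx[idx])

    def site_indices_of(self, tf: str) -> np.ndarray:
        """Record indices of one TF's sites, in genomic order."""
        return np.flatnonzero(self._tf_idx == self.tf_index(tf))

    def records_of(self, tf: str) -> list[TFBSRecord]:
        return [self.records[i] for i in self.site_indices_of(tf)]

    def subset_tf(self, tf: str) -> "TFBSCollection":
        """A new collection containing only one TF's sites."""
        return TFBSCollection(self.records_of(tf))

    # -- proximity queries -------------------------------------------------

    def trees(self) -> Mapping[str, IntervalTree]:
        """Per-chromosome interval trees over all sites (built lazily)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            by_chrom: dict[str, list[Interval]] = {}
            for i, r in enumerate(self.records):
                by_chrom.setdefault(r.chrom, []).append(Interval(r.start, r.end, i))
            for chrom, ivs in by_chrom.items():
                trees[chrom] = IntervalTree(ivs)
            self._trees = trees
        return self._trees

    def neighbors(self, idx: int, window_bp: int) -> list[int]:
        """Record indices of all sites intersecting the window of record ``idx``.

        A site ``s`` is a neighbor of focal site ``b`` iff ``s`` intersects
        ``[b.start - window_bp, b.end + window_bp)``.  The focal record itself
        is excluded; other sites of the same TF are not.
        """
        r = self.records[idx]
        qs, qe = r.window(window_bp)
        tree = self.trees()[r.chrom]
        return [iv.data for iv in tree.overlap(qs, qe) if iv.data != idx]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<TFBSCollection: {self.n_sites} sites, {self.n_tfs} TFs, "
            f"{len({r.chrom for r in self.records})} chromosomes>"
        )
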