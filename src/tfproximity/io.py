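"""Readers and writers for the tab-separated formats the tool touches.

* BED-like TFBS files: ``chrom  start  end  name`` (TF name in column 4 by
  default, overridable), 0-based half-open coordinates.
* Edge lists: ``tf1  tf2  weight`` for unordered pairs including self-loops.
* Cluster tables: ``tf  cluster`` with a sentinel for unclustered TFs.
* Reference interaction tables in the STRING ``protein.links.detailed``
  layout (two protein columns, seven evidence-channel scores, combined
  score; whitespace- or tab-separated).
* TF-pair PWM-similarity tables: ``tf1  tf2  score``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .collection import TFBSCollection, TFBSRecord
from .graph import CooccurrenceGraph

__all__ = [
    "FormatError",
    "ReferenceInteractions",
    "SimilarityTable",
    "GraphEdgeList",
    "CHANNELS",
    "canonical_channel",
    "read_tfbs",
    "write_tfbs",
    "read_reference",
    "read_similarity",
    "write_graph",
    "read_graph",
    "write_clusters",
    "read_clusters",
]

DEFAULT_COMBINED_SCORE_THRESHOLD = 400  # conventional "medium confidence"
UNCLUSTERED_SENTINEL = "unclustered"

# canonical channel key -> accepted column spellings (STRING writes
# "cooccurence" and "experimental")
CHANNELS: dict[str, tuple[str, ...]] = {
    "neighborhood": ("neighborhood",),
    "fusion": ("fusion",),
    "cooccurrence": ("cooccurence", "cooccurrence"),
    "coexpression": ("coexpression",),
    "experiments": ("experimental", "experiments"),
    "database": ("database",),
    "textmining": ("textmining", "text_mining"),
}


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


def canonical_channel(name: str) -> str:
    """Map a channel name or column spelling to its canonical key."""
    key = name.strip().lower().replace("-", "").replace("_", "").replace(" ", "")
    for canon, variants in CHANNELS.items():
        if key == canon.replace("_", "") or key in [v.replace("_", "") for v in variants]:
            return canon
    raise KeyError(f"unknown evidence channel {name!r}; expected one of {sorted(CHANNELS)}")


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ReferenceInteractions:
    """Unordered reference interaction pairs with per-channel scores."""

    pairs: set[tuple[str, str]]
    channel_scores: dict[tuple[str, str], dict[str, float]]
    proteins: frozenset[str]
    score_threshold: float

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _pair(*pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SimilarityTable:
    """Averaged pairwise PWM-similarity scores, symmetric in pair order."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    multiplicity: dict[tuple[str, str], int] = field(default_factory=dict)

    def get(self, tf1: str, tf2: str) -> float:
        return self.scores[_pair(tf1, tf2)]

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self.scores.items())

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class GraphEdgeList:
    """A lightweight edge container read back from an edge-list file.

    Presents the same ``has_edge``/``weight`` surface the evaluation
    functions expect from a filtered graph: every listed pair counts as a
    surviving edge.
    """

    tf_names: tuple[str, ...]
    weights: dict[tuple[str, str], float]

    def has_edge(self, tf1: str, tf2: str) -> bool:
        return _pair(tf1, tf2) in self.weights

    def weight(self, tf1: str, tf2: str) -> float:
        return self.weights[_pair(tf1, tf2)]


# ---------------------------------------------------------------------------
# TFBS BED-like files
# ---------------------------------------------------------------------------


def read_tfbs(path: str | Path, tf_column: int = 3) -> TFBSCollection:
    """Read a BED-like TFBS file into a sorted collection.

    ``tf_column`` is the 0-based index of the TF-name column (default 3,
    i.e. the BED ``name`` field).  Duplicate identical records are kept.
    Malformed records raise :class:`FormatError` naming the line number;
    an empty file is an error.
    """
    path = Path(path)
    records: list[TFBSRecord] = []
    min_cols = max(3, tf_column) + 1
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise FormatError(
                    f"{path}: line {ln}: expected >= {min_cols} tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {ln}: non-integer coordinates "
                    f"{parts[1]!r}, {parts[2]!r}"
                ) from None
            try:
                records.append(
                    TFBSRecord(chrom=parts[0], start=start, end=end, tf=parts[tf_column])
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: {exc}") from None
    if not records:
        raise FormatError(f"{path}: no TFBS records found")
    return TFBSCollection.from_records(records)


def write_tfbs(collection: TFBSCollection, path: str | Path) -> None:
    """Write a collection as 4-column BED (chrom, start, end, TF)."""
    with open(path, "w") as fh:
        for r in collection.records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.tf}\n")


# ---------------------------------------------------------------------------
# Reference interactions (STRING detailed layout)
# ---------------------------------------------------------------------------


def read_reference(
    path: str | Path,
    score_threshold: float = DEFAULT_COMBINED_SCORE_THRESHOLD,
) -> ReferenceInteractions:
    """Read a STRING-detailed-format interaction table.

    Pairs with combined score >= ``score_threshold`` are retained and
    deduplicated to unordered pairs (elementwise-max channel scores when a
    pair is listed in both orders); self-pairs are dropped.  The protein
    universe records every name seen in the file regardless of threshold,
    so downstream matching can distinguish "absent from reference" from
    "below threshold".
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty reference table") from None
    cols = {c.lower(): c for c in df.columns}
    for required in ("protein1", "protein2", "combined_score"):
        if required not in cols:
            raise FormatError(f"{path}: missing required column {required!r}")
    channel_cols: dict[str, str] = {}
    for canon, variants in CHANNELS.items():
        for v in variants:
            if v in cols:
                channel_cols[canon] = cols[v]
                break
        else:
            raise FormatError(
                f"{path}: missing evidence channel column for {canon!r} "
                f"(accepted spellings: {variants})"
            )
    proteins = frozenset(df[cols["protein1"]].astype(str)) | frozenset(
        df[cols["protein2"]].astype(str)
    )
    pairs: set[tuple[str, str]] = set()
    channel_scores: dict[tuple[str, str], dict[str, float]] = {}
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        a, b = str(rec[cols["protein1"]]), str(rec[cols["protein2"]])
        if a == b:
            continue
        if float(rec[cols["combined_score"]]) < score_threshold:
            continue
        key = _pair(a, b)
        scores = {canon: float(rec[col]) for canon, col in channel_cols.items()}
        if any(v < 0 for v in scores.values()):
            raise FormatError(f"{path}: negative channel score for pair {key}")
        if key in channel_scores:
            prev = channel_scores[key]
            channel_scores[key] = {k: max(prev[k], scores[k]) for k in scores}
        else:
            pairs.add(key)
            channel_scores[key] = scores
    return ReferenceInteractions(
        pairs=pairs,
        channel_scores=channel_scores,
        proteins=proteins,
        score_threshold=score_threshold,
    )


# ---------------------------------------------------------------------------
# Similarity tables
# ---------------------------------------------------------------------------


def read_similarity(path: str | Path) -> SimilarityTable:
    """Read a ``tf1  tf2  score`` table, averaging repeated unordered pairs.

    A TF represented by several PWMs yields several rows for the same pair;
    their scores are averaged and the multiplicity recorded.  An optional
    header line is skipped.  An empty file yields an empty table (the
    downstream regression refuses it).
    """
    path = Path(path)
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {ln}: expected 3 tab-separated columns"
                )
            try:
                score = float(parts[2])
            except ValueError:
                if ln == 1:  # tolerate a header line
                    continue
                raise FormatError(
                    f"{path}: line {ln}: non-numeric similarity score {parts[2]!r}"
                ) from None
            key = _pair(parts[0], parts[1])
            sums[key] = sums.get(key, 0.0) + score
            counts[key] = counts.get(key, 0) + 1
    return SimilarityTable(
        scores={k: sums[k] / counts[k] for k in sums},
        multiplicity=dict(counts),
    )


# ---------------------------------------------------------------------------
# Edge lists and cluster tables
# ---------------------------------------------------------------------------


def write_graph(
    graph: CooccurrenceGraph, path: str | Path, include_negative: bool = True
) -> None:
    """Write the undirected edge list (incl. self-loops), lexicographically.

    Weights are written with 17 significant digits so a read/write cycle is
    lossless for double precision.
    """
    order = sorted(range(graph.n), key=lambda i: graph.tf_names[i])
    with open(path, "w") as fh:
        fh.write("tf1\ttf2\tweight\n")
        for pos_i, i in enumerate(order):
            for j in order[pos_i:]:
                w = float(graph.W[i, j])
                if not include_negative and w < 0:
                    continue
                fh.write(f"{graph.tf_names[i]}\t{graph.tf_names[j]}\t{w:.17g}\n")


def read_graph(path: str | Path) -> GraphEdgeList:
    """Read an edge list written by :func:`write_graph`."""
    path = Path(path)
    weights: dict[tuple[str, str], float] = {}
    names: set[str] = set()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or (ln == 1 and line.startswith("tf1\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {ln}: expected 3 columns")
            try:
                w = float(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {ln}: non-numeric weight {parts[2]!r}"
                ) from None
            weights[_pair(parts[0], parts[1])] = w
            names.update(parts[:2])
    return GraphEdgeList(tf_names=tuple(sorted(names)), weights=weights)


def write_clusters(clustering, path: str | Path) -> None:
    """Write one ``tf  cluster`` line per TF, sorted by TF name.

    Cluster ids are 1-based by decreasing cluster size; unclustered TFs get
    the sentinel ``unclustered``.
    """
    labels = clustering.labels()
    with open(path, "w") as fh:
        fh.write("tf\tcluster\n")
        for tf in sorted(labels):
            lab = labels[tf]
            fh.write(f"{tf}\t{UNCLUSTERED_SENTINEL if lab is None else lab}\n")


def read_clusters(path: str | Path) -> dict[str, int | None]:
    """Read a cluster table back into a TF -> cluster-id mapping."""
    path = Path(path)
    out: dict[str, int | None] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or (ln == 1 and line.startswith("tf\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {ln}: expected 2 columns")
            tf, lab = parts
            out[tf] = None if lab == UNCLUSTERED_SENTINEL else int(lab)
    return out
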