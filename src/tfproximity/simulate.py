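"""Synthetic TFBS collections with known structure.

The clustering method assumes that interacting TFs co-bind: their sites
appear near one another more often than the genomic background.  The
generators here realize exactly that structure so every pipeline stage can
be tested against a known truth without any external downloads:

* ``generate_planted`` — TFs grouped into co-binding clusters.  Each
  cluster owns a set of *complex loci* drawn uniformly over a single
  synthetic chromosome; each member binds each locus independently with a
  participation probability, jittered by a bounded offset, on top of
  uniform background sites.
* ``generate_null`` — fully independent uniform binding; the genomic-space
  analogue of the permutation null used for FPR calibration.
* ``generate_filter_fixture`` — a putative/actual site pair for the TFBS
  filtering workflow: the target's true complex-derived sites (jittered)
  hidden among uniform decoys, alongside every other TF's putative sites.

The genome model is deliberately minimal — one chromosome, uniform
placement, no chromatin or sequence — because the method consumes only
pairwise proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .collection import TFBSCollection, TFBSRecord

__all__ = [
    "PlantedConfig",
    "PlantedTruth",
    "generate_planted",
    "generate_null",
    "generate_filter_fixture",
]

CHROM = "chr1"


def _default_assignment(
    n_clusters: int = 3, tfs_per_cluster: int = 8
) -> dict[str, int]:
    return {
        f"TF{c * tfs_per_cluster + k:03d}": c
        for c in range(n_clusters)
        for k in range(tfs_per_cluster)
    }


@dataclass(frozen=True)
class PlantedConfig:
    """Study conditions for the planted co-binding generator.

    Defaults follow the package's standard synthetic benchmark: 3 clusters
    of 8 TFs, 200 complex loci per cluster, participation probability 0.8,
    300 bp placement jitter (well inside the 1000 bp proximity window),
    300 expected background sites per TF on a 100 Mb chromosome, 12 bp
    sites.
    """

    genome_length: int = 100_000_000
    cluster_assignment: Mapping[str, int] = field(default_factory=_default_assignment)
    complexes_per_cluster: int = 200
    participation_prob: float = 0.8
    placement_jitter: int = 300
    background_rate: float = 300.0
    site_length: int = 12
    background_tfs: tuple[str, ...] = ()  # TFs with background sites only
    target_tf: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.placement_jitter < 0:
            raise ValueError("placement_jitter must be >= 0")
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must be in [0, 1]")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.site_length < 1 or self.genome_length <= self.site_length:
            raise ValueError("genome must be longer than one site")
        if not self.cluster_assignment and not self.background_tfs:
            raise ValueError("no TFs configured")
        overlap = set(self.cluster_assignment) & set(self.background_tfs)
        if overlap:
            raise ValueError(f"TFs both assigned and background-only: {sorted(overlap)}")

    @property
    def all_tfs(self) -> tuple[str, ...]:
        return tuple(sorted([*self.cluster_assignment, *self.background_tfs]))

    @property
    def cluster_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.cluster_assignment.values())))

    @property
    def n_tfs(self) -> int:
        return len(self.all_tfs)

    def expected_sites(self) -> float:
        n_assigned = len(self.cluster_assignment)
        return (
            n_assigned * self.complexes_per_cluster * self.participation_prob
            + self.n_tfs * self.background_rate
        )


@dataclass
class PlantedTruth:
    """Ground truth attached to a generated collection.

    ``site_labels`` aligns with ``collection.records`` ("complex" or
    "background"; filter fixtures add "true", "decoy" and "other").
    """

    clusters: dict[str, int]
    site_labels: tuple[str, ...]
    target_tf: str | None = None


def _uniform_starts(rng: np.random.Generator, k: int, cfg_len: int, site_len: int) -> np.ndarray:
    return rng.integers(0, cfg_len - site_len, size=k)


def generate_planted(config: PlantedConfig) -> tuple[TFBSCollection, PlantedTruth]:
    """Generate a collection with planted co-binding clusters.

    Deterministic under ``config.seed``.  Raises for configurations whose
    expected site footprint overflows the genome.
    """
    if config.expected_sites() * config.site_length > 0.5 * config.genome_length:
        raise ValueError(
            "infeasible config: expected site footprint exceeds half the genome"
        )
    rng = np.random.default_rng(config.seed)
    L, s_len, jit = config.genome_length, config.site_length, config.placement_jitter
    labelled: list[tuple[TFBSRecord, str]] = []
    members_by_cluster: dict[int, list[str]] = {}
    for tf, cid in config.cluster_assignment.items():
        members_by_cluster.setdefault(cid, []).append(tf)
    for cid in config.cluster_ids:
        loci = _uniform_starts(rng, config.complexes_per_cluster, L, s_len)
        for tf in sorted(members_by_cluster[cid]):
            binds = rng.random(config.complexes_per_cluster) < config.participation_prob
            chosen = loci[binds]
            if jit > 0:
                chosen = chosen + rng.integers(-jit, jit + 1, size=chosen.size)
            chosen = np.clip(chosen, 0, L - s_len)
            for pos in chosen:
                labelled.append(
                    (TFBSRecord(CHROM, int(pos), int(pos) + s_len, tf), "complex")
                )
    for tf in config.all_tfs:
        k = int(rng.poisson(config.background_rate))
        for pos in _uniform_starts(rng, k, L, s_len):
            labelled.append(
                (TFBSRecord(CHROM, int(pos), int(pos) + s_len, tf), "background")
            )
    labelled.sort(key=lambda pair: (pair[0].chrom, pair[0].start, pair[0].end, pair[0].tf))
    collection = TFBSCollection.from_records([r for r, _ in labelled])
    truth = PlantedTruth(
        clusters=dict(config.cluster_assignment),
        site_labels=tuple(lab for _, lab in labelled),
        target_tf=config.target_tf,
    )
    return collection, truth


def generate_null(
    n_tfs: int,
    per_tf_rates: float | Sequence[float],
    genome_length: int = 5_000_000,
    site_length: int = 12,
    seed: int | None = None,
) -> TFBSCollection:
    """Independent uniform binding for every TF (no planted structure).

    Site counts are Poisson with the given per-TF expected rates; positions
    are uniform.  This is the genomic-space analogue of the shuffled-order
    null the FPR calibration assumes, so thresholds derived from the dummy
    pool should flag about the target fraction of these edges.
    """
    rates = np.broadcast_to(np.asarray(per_tf_rates, dtype=float), (n_tfs,))
    if (rates <= 0).any():
        raise ValueError("per-TF rates must be positive")
    if rates.sum() * site_length > 0.5 * genome_length:
        raise ValueError("infeasible rates: expected footprint exceeds half the genome")
    rng = np.random.default_rng(seed)
    records: list[TFBSRecord] = []
    for i in range(n_tfs):
        tf = f"TF{i:03d}"
        k = int(rng.poisson(rates[i]))
        for pos in _uniform_starts(rng, k, genome_length, site_length):
            records.append(TFBSRecord(CHROM, int(pos), int(pos) + site_length, tf))
    return TFBSCollection.from_records(records)


def generate_filter_fixture(
    config: PlantedConfig, decoy_count: int, seed: int | None = None
) -> tuple[TFBSCollection, TFBSCollection, PlantedTruth]:
    """Putative/actual site pair for the TFBS-filtering workflow.

    * *actual* sites: the target TF's complex-derived sites — the stand-in
      for experimentally determined (ChIP-seq) truth.
    * *putative* sites: the actual sites re-jittered (motif matches near
      the truth), plus ``decoy_count`` uniformly placed decoys of the
      target, plus every other TF's generated sites.

    Returns ``(putative, actual, truth)``; ``truth.site_labels`` aligns
    with the putative collection ("true" / "decoy" for target sites,
    "other" for the rest).
    """
    target = config.target_tf
    if target is None or target not in config.cluster_assignment:
        raise ValueError("config.target_tf must name a cluster-assigned TF")
    rng = np.random.default_rng(seed)
    planted_seed = int(rng.integers(2**31))
    base, base_truth = generate_planted(replace(config, seed=planted_seed))
    L, s_len, jit = config.genome_length, config.site_length, config.placement_jitter
    actual_records = [
        r
        for r, lab in zip(base.records, base_truth.site_labels)
        if r.tf == target and lab == "complex"
    ]
    if not actual_records:
        raise ValueError("target TF produced no complex-derived sites")
    labelled: list[tuple[TFBSRecord, str]] = []
    for r in actual_records:
        pos = int(np.clip(r.start + rng.integers(-jit, jit + 1) if jit else r.start, 0, L - s_len))
        labelled.append((TFBSRecord(CHROM, pos, pos + s_len, target), "true"))
    for pos in _uniform_starts(rng, decoy_count, L, s_len):
        labelled.append((TFBSRecord(CHROM, int(pos), int(pos) + s_len, target), "decoy"))
    for r in base.records:
        if r.tf != target:
            labelled.append((r, "other"))
    labelled.sort(key=lambda pair: (pair[0].chrom, pair[0].start, pair[0].end, pair[0].tf))
    putative = TFBSCollection.from_records([r for r, _ in labelled])
    truth = PlantedTruth(
        clusters=dict(config.cluster_assignment),
        site_labels=tuple(lab for _, lab in labelled),
        target_tf=target,
    )
    return putative, TFBSCollection.from_records(actual_records), truth
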