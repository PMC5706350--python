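from __future__ import annotations

import numpy as np
import pytest

from tfproximity.collection import TFBSCollection, TFBSRecord


def random_collection(
    rng: np.random.Generator,
    n_tfs: int = 4,
    n_sites: int = 40,
    genome_length: int = 20_000,
    site_length_max: int = 60,
    n_chroms: int = 2,
) -> TFBSCollection:
    """A small random collection for oracle-equivalence checks."""
    records = []
    for _ in range(n_sites):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, genome_length))
        length = int(rng.integers(1, site_length_max + 1))
        tf = f"TF{rng.integers(n_tfs)}"
        records.append(TFBSRecord(chrom, start, start + length, tf))
    return TFBSCollection.from_records(records)


def as_tuples(collection: TFBSCollection):
    return [(r.chrom, r.start, r.end, r.tf) for r in collection.records]


@pytest.fixture
def toy_collection() -> TFBSCollection:
    """Two TFs on one chromosome with hand-computable co-occurrence.

    A: one site [0,10).  B: [5,15) (near A) and [2000,2010) (isolated).
    With window 100: f_A = [0, 1], f_B = [0.5, 0], f_all = [1/3, 1/3].
    """
    return TFBSCollection.from_records(
        [
            TFBSRecord("chr1", 0, 10, "A"),
            TFBSRecord("chr1", 5, 15, "B"),
            TFBSRecord("chr1", 2000, 2010, "B"),
        ]
    )
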