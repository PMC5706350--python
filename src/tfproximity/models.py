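"""Model/Results front-ends for the two workflows.

:class:`TFClusterModel` wraps cluster discovery: co-occurrence graph →
permutation FPR threshold → edge filtering → Markov clustering.  Its
``fit`` returns a :class:`TFClusterResults` carrying the graph, the
calibrated threshold, the partition and the summary metrics, with
``summary()`` and ``save()`` for reporting and artifacts.

:class:`TFBSFilterModel` wraps putative-TFBS filtering for one target TF:
unfiltered signed graph → per-site sum-scores → precision/recall sweeps
for the sum, normalized-sum and neighbor-count scores plus a matched
random-removal baseline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as tio
from .collection import TFBSCollection
from .fpr import (
    DEFAULT_N_REPS,
    DummyWeightPool,
    FilteredGraph,
    ThresholdResult,
    dummy_pool,
    filter_graph,
    threshold_for_fpr,
)
from .graph import DEFAULT_WINDOW_BP, CooccurrenceGraph, build_graph
from .mcl import (
    DEFAULT_INFLATION,
    DEFAULT_MAX_ITER,
    DEFAULT_PRUNE,
    Clustering,
    ClusterMetrics,
    cluster_metrics,
    mcl_cluster,
    sweep_inflation,
)
from .scoring import (
    PRF,
    PRCurve,
    ScoredSite,
    pr_sweep,
    random_baseline,
    sum_scores,
)

__all__ = [
    "TFClusterModel",
    "TFClusterResults",
    "TFBSFilterModel",
    "TFBSFilterResults",
]


def _config_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class TFClusterModel:
    """Proximity-based TF cluster discovery on a TFBS collection.

    Parameters
    ----------
    collection : TFBSCollection
        All binding sites across TFs (>= 2 TFs).
    window_bp : int
        Proximity window radius in bp around each site (default 1000).
    """

    def __init__(self, collection: TFBSCollection, window_bp: int = DEFAULT_WINDOW_BP):
        if collection.n_tfs < 2:
            raise ValueError("cluster discovery needs at least 2 TFs")
        self.collection = collection
        self.window_bp = window_bp
        self._graph: CooccurrenceGraph | None = None

    @classmethod
    def from_bed(
        cls, path, tf_column: int = 3, window_bp: int = DEFAULT_WINDOW_BP
    ) -> "TFClusterModel":
        return cls(tio.read_tfbs(path, tf_column=tf_column), window_bp=window_bp)

    @property
    def graph(self) -> CooccurrenceGraph:
        """The unfiltered signed co-occurrence graph (built lazily, cached)."""
        if self._graph is None:
            self._graph = build_graph(self.collection, self.window_bp)
        return self._graph

    def fit(
        self,
        fpr: float = 0.01,
        n_reps: int = DEFAULT_N_REPS,
        seed: int | None = None,
        inflation: float = DEFAULT_INFLATION,
        prune_below: float = DEFAULT_PRUNE,
        max_iter: int = DEFAULT_MAX_ITER,
    ) -> "TFClusterResults":
        """Calibrate the FPR threshold, filter, and Markov-cluster.

        ``seed`` drives the dummy-matrix permutations and is recorded in
        the results for exact reproducibility.
        """
        graph = self.graph
        pool = dummy_pool(self.collection, graph.f_all, n_reps=n_reps, seed=seed)
        thr = threshold_for_fpr(pool, fpr)
        filtered = filter_graph(
            graph, thr.threshold, fpr_target=fpr, achieved_fpr=thr.achieved_fpr
        )
        clustering = mcl_cluster(
            filtered, inflation=inflation, prune_below=prune_below, max_iter=max_iter
        )
        metrics = cluster_metrics(clustering, filtered)
        params = {
            "window_bp": self.window_bp,
            "fpr": fpr,
            "n_reps": n_reps,
            "seed": seed,
            "inflation": inflation,
            "prune_below": prune_below,
            "max_iter": max_iter,
        }
        return TFClusterResults(
            model=self,
            graph=graph,
            pool=pool,
            threshold=thr,
            filtered=filtered,
            clustering=clustering,
            metrics=metrics,
            params=params,
        )


@dataclass
class TFClusterResults:
    """Fitted cluster-discovery results with reporting helpers."""

    model: TFClusterModel
    graph: CooccurrenceGraph
    pool: DummyWeightPool
    threshold: ThresholdResult
    filtered: FilteredGraph
    clustering: Clustering
    metrics: ClusterMetrics
    params: dict

    @property
    def config_hash(self) -> str:
        return _config_hash(self.params)

    def sweep_inflation(self, grid: Sequence[float]):
        """Re-cluster the fitted filtered graph over an inflation grid."""
        return sweep_inflation(
            self.filtered,
            grid,
            prune_below=self.params["prune_below"],
            max_iter=self.params["max_iter"],
        )

    def summary(self) -> str:
        m = self.metrics
        conv = "converged" if self.clustering.converged else "NOT converged"
        lines = [
            "Proximity-based TF cluster discovery",
            "====================================",
            f"Nodes (TFs)              {m.n_nodes}",
            f"Sites                    {self.model.collection.n_sites}",
            f"Window (bp)              {self.params['window_bp']}",
            f"Edges (incl. self-loops) {self.graph.n_edges}",
            f"FPR target               {self.params['fpr']}"
            f"   achieved {self.threshold.achieved_fpr:.3g}",
            f"Dummy pool               {self.threshold.pool_size} weights"
            f" ({self.pool.n_reps} repeats, seed={self.params['seed']})",
            f"Weight threshold         {self.threshold.threshold:.6g}",
            f"Edges filtered           {m.n_edges_filtered}"
            f" ({m.pct_edges_filtered:.1f}%)",
            f"MCL inflation            {self.params['inflation']}"
            f"   ({self.clustering.n_iterations} iterations, {conv})",
            f"Clusters                 {m.n_clusters}",
            f"Med. nodes per cluster   {m.median_nodes_per_cluster:g}",
            f"Max. nodes per cluster   {m.max_nodes_per_cluster}",
            f"Unclustered pct.         {m.unclustered_pct:.1f}",
        ]
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, Path]:
        """Write edge list, cluster table, metrics and manifest to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": outdir / "edges.tsv",
            "clusters": outdir / "clusters.tsv",
            "metrics": outdir / "metrics.json",
            "manifest": outdir / "manifest.json",
        }
        tio.write_graph(self.graph, paths["edges"])
        tio.write_clusters(self.clustering, paths["clusters"])
        with open(paths["metrics"], "w") as fh:
            json.dump(self.metrics.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest = {
            "config": self.params,
            "config_hash": self.config_hash,
            "threshold": self.threshold.threshold,
            "achieved_fpr": self.threshold.achieved_fpr,
            "pool_size": self.threshold.pool_size,
            "n_sites": self.model.collection.n_sites,
            "n_tfs": self.model.collection.n_tfs,
            "mcl_converged": self.clustering.converged,
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


class TFBSFilterModel:
    """Co-occurrence filtering of one target TF's putative binding sites.

    Parameters
    ----------
    putative : TFBSCollection
        Putative (motif-match) sites for *all* TFs; the signed unfiltered
        graph is built from these.
    target : str
        The TF whose putative sites are scored and filtered.
    window_bp : int
        Proximity window radius in bp (default 1000).
    """

    def __init__(
        self,
        putative: TFBSCollection,
        target: str,
        window_bp: int = DEFAULT_WINDOW_BP,
    ):
        if target not in putative:
            raise KeyError(f"target TF {target!r} absent from the putative collection")
        self.putative = putative
        self.target = target
        self.window_bp = window_bp
        self._graph: CooccurrenceGraph | None = None

    @property
    def graph(self) -> CooccurrenceGraph:
        """Unfiltered signed graph from the putative sites (cached)."""
        if self._graph is None:
            self._graph = build_graph(self.putative, self.window_bp)
        return self._graph

    def fit(
        self,
        actual: TFBSCollection,
        methods: Sequence[str] = ("sum", "normalized_sum", "length"),
        length_descending: bool = True,
        n_random: int = 20,
        seed: int | None = None,
    ) -> "TFBSFilterResults":
        """Score the target's putative sites and sweep every method.

        The random baseline removes the same number of sites as the
        sum-score's best cutoff, averaged over ``n_random`` draws; a seed
        is mandatory so the baseline is reproducible.
        """
        if seed is None:
            raise ValueError(
                "a seed is required: the random-removal baseline must be reproducible"
            )
        scored = sum_scores(self.target, self.putative, self.graph, self.window_bp)
        curves: dict[str, PRCurve] = {}
        for method in methods:
            descending = length_descending and method == "length"
            curves[method] = pr_sweep(
                scored,
                actual,
                method=method,
                window_bp=self.window_bp,
                descending=descending,
            )
        reference_curve = curves.get("sum") or next(iter(curves.values()))
        unfiltered = reference_curve.unfiltered
        n_remove = len(scored) - reference_curve.best.n_retained
        rng = np.random.default_rng(seed)
        if n_remove > 0:
            draws = [
                random_baseline(
                    scored,
                    n_remove,
                    int(rng.integers(2**31)),
                    actual,
                    self.window_bp,
                )
                for _ in range(n_random)
            ]
            rand = PRF(
                float(np.mean([d.precision for d in draws])),
                float(np.mean([d.recall for d in draws])),
                float(np.mean([d.f_score for d in draws])),
                len(scored) - n_remove,
            )
        else:
            rand = unfiltered
        sums = np.asarray([s.sum_score for s in scored])
        counts = np.asarray([s.n_neighbors for s in scored], dtype=float)
        if np.ptp(sums) > 0 and np.ptp(counts) > 0:
            length_sum_corr = float(np.corrcoef(counts, sums)[0, 1])
        else:
            length_sum_corr = float("nan")
        params = {
            "target": self.target,
            "window_bp": self.window_bp,
            "methods": list(methods),
            "length_descending": length_descending,
            "n_random": n_random,
            "seed": seed,
        }
        return TFBSFilterResults(
            model=self,
            scored=scored,
            curves=curves,
            unfiltered=unfiltered,
            random_matched=rand,
            n_removed_at_best=n_remove,
            length_sum_correlation=length_sum_corr,
            params=params,
        )


@dataclass
class TFBSFilterResults:
    """Fitted TFBS-filtering results: per-site scores and PR sweeps."""

    model: TFBSFilterModel
    scored: list[ScoredSite]
    curves: dict[str, PRCurve]
    unfiltered: PRF
    random_matched: PRF
    n_removed_at_best: int
    length_sum_correlation: float
    params: dict

    @property
    def config_hash(self) -> str:
        return _config_hash(self.params)

    def summary(self) -> str:
        lines = [
            f"Putative-TFBS filtering for target {self.params['target']}",
            "=" * 54,
            f"Putative target sites    {len(self.scored)}",
            f"Window (bp)              {self.params['window_bp']}",
            f"Unfiltered               P={self.unfiltered.precision:.4f}"
            f"  R={self.unfiltered.recall:.4f}  F={self.unfiltered.f_score:.4f}",
        ]
        for method, curve in self.curves.items():
            b = curve.best
            lines.append(
                f"Max-F ({method:<15}) P={b.precision:.4f}  R={b.recall:.4f}"
                f"  F={b.f_score:.4f}  cutoff={curve.best_cutoff:.4g}"
                f"  retained={b.n_retained}"
            )
        lines.append(
            f"Random baseline          P={self.random_matched.precision:.4f}"
            f"  R={self.random_matched.recall:.4f}"
            f"  F={self.random_matched.f_score:.4f}"
            f"  (removing {self.n_removed_at_best}, "
            f"{self.params['n_random']} draws)"
        )
        lines.append(
            f"Corr(neighbor count, sum-score)  R={self.length_sum_correlation:.3f}"
        )
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, Path]:
        """Write per-site scores, PR curves, and a max-F summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        scores_path = outdir / "scores.tsv"
        with open(scores_path, "w") as fh:
            fh.write("chrom\tstart\tend\tsum_score\tn_neighbors\tnormalized_score\n")
            for s in self.scored:
                fh.write(
                    f"{s.site.chrom}\t{s.site.start}\t{s.site.end}\t"
                    f"{s.sum_score:.17g}\t{s.n_neighbors}\t{s.normalized_score:.17g}\n"
                )
        paths["scores"] = scores_path
        for method, curve in self.curves.items():
            p = outdir / f"pr_{method}.tsv"
            curve.to_frame().to_csv(p, sep="\t", index=False)
            paths[f"pr_{method}"] = p
        summary = {
            "config": self.params,
            "config_hash": self.config_hash,
            "unfiltered": self.unfiltered._asdict(),
            "random_baseline": self.random_matched._asdict(),
            "n_removed_at_best": self.n_removed_at_best,
            "length_sum_correlation": self.length_sum_correlation,
            "best": {m: c.best._asdict() for m, c in self.curves.items()},
            "best_cutoff": {m: c.best_cutoff for m, c in self.curves.items()},
        }
        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        paths["summary"] = summary_path
        return paths
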