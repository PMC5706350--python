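# tfproximity

Proximity-based discovery of transcription-factor (TF) clusters from
genomic binding-site coordinates, and co-occurrence-driven filtering of
putative binding sites.

TFs regulate transcription cooperatively: one or more "anchor" TFs bind
DNA directly and others join the complex by binding the anchors.  ChIP-seq
peaks and motif scans say *where* individual TFs bind but nothing about
*who binds together*.  Motif-similarity clustering misses exactly the
anchor–association interactions, because associating TFs need not share
sequence affinity.  `tfproximity` recovers co-binding structure from
proximity alone: TFs that work together leave binding sites near one
another more often than the genomic background.

The package is aimed at regulatory-genomics analysts with BED-like TFBS
coordinate files (ChIP-seq peaks or motif matches) who want cell-type
specific TF interaction maps, or who want to de-noise a motif scan for one
TF using the co-occurrence profile of all the others.

## Method in brief

For each TF *t* with sites B_t, an n × m_t binary co-occurrence matrix
**M**_t records which of the n TFs has a site within *w* bp (default
1000) of each site of *t*.  Row means give the co-occurrence frequency
vector **f**_t; the background vector **f**_all is the row mean of all
**M**_t concatenated; and the normalized frequencies

    f′_t = f_t − f_all

strip each TF's background prevalence (and may go negative — depletion).
Stacking the f′_t columns gives the directed adjacency matrix **A**;
undirected edge weights are W = (A + Aᵀ)/2, a complete graph with
n(n+1)/2 edges including self-loops.

Edges are filtered to a user-chosen false-positive rate: the adjacency
construction is re-run 25 times on dummy matrices whose rows are i.i.d.
Bernoulli draws at each TF's background frequency (prevalence preserved,
proximity destroyed), pooling all 25·n² directed null weights; the FPR-α
threshold is the smallest pooled weight exceeded by ≤ α of the pool.  The
filtered graph is partitioned with a native Markov Clustering (MCL)
implementation (expansion / inflation / pruning; inflation 2–5).

Separately, the *unfiltered signed* graph scores each putative site of a
target TF by the sum of edge weights from the target to every neighboring
putative TFBS in its window (the *sum-score*); thresholding the scores
trades recall for precision far better than random removal.  Evaluation
utilities compare predicted interactions to a reference table (STRING
detailed layout), test per-channel enrichment, and regress edge weight on
PWM similarity.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
details.

## Worked example

Generate a synthetic dataset with three planted co-binding clusters of 8
TFs each (200 complex loci per cluster, participation 0.8, 300 background
sites per TF on a 100 Mb chromosome), then run the full discovery
workflow:

```python
from tfproximity import TFClusterModel
from tfproximity.simulate import PlantedConfig, generate_planted

cfg = PlantedConfig(seed=7)              # 3 clusters x 8 TFs
collection, truth = generate_planted(cfg)
model = TFClusterModel(collection, window_bp=1000)
result = model.fit(fpr=0.01, n_reps=25, seed=11)
print(result.summary())
for i, members in enumerate(result.clustering.clusters, 1):
    print(f"cluster {i}: {' '.join(members)}")
```

which prints:

```
Proximity-based TF cluster discovery
====================================
Nodes (TFs)              24
Sites                    11013
Window (bp)              1000
Edges (incl. self-loops) 300
FPR target               0.01   achieved 0.01
Dummy pool               14400 weights (25 repeats, seed=11)
Weight threshold         0.03173
Edges filtered           216 (72.0%)
MCL inflation            2.5   (10 iterations, converged)
Clusters                 3
Med. nodes per cluster   8
Max. nodes per cluster   8
Unclustered pct.         0.0

cluster 1: TF000 TF001 TF002 TF003 TF004 TF005 TF006 TF007
cluster 2: TF008 TF009 TF010 TF011 TF012 TF013 TF014 TF015
cluster 3: TF016 TF017 TF018 TF019 TF020 TF021 TF022 TF023
```

Reading the output: the 24-TF graph has 24·25/2 = 300 undirected edges;
the permutation pool (25 repeats × 24² directed weights) sets the FPR-0.01
weight threshold at 0.0317, which removes 72% of edges — essentially all
between-cluster and background edges, since planted within-cluster weights
sit near 0.2.  MCL then recovers the three planted groups exactly, with no
TF left unclustered.  `result.save("outdir/")` writes the edge list,
cluster table, metrics and a manifest (seed, config hash) for exact reruns.

The same pipeline is available from the shell:

```sh
tfproximity simulate --preset planted --seed 7 -o sim
tfproximity cluster sim.bed --fpr 0.01 --seed 11 -o run/
tfproximity score-tfbs --target TF000 --putative put.bed --actual act.bed \
    --seed 3 -o filt/
```

For TFBS filtering, `TFBSFilterModel(putative, "TF000").fit(actual,
seed=...)` returns per-site scores, precision/recall sweeps for the sum,
normalized-sum and neighbor-count scores, and a matched random-removal
baseline, with `summary()` reporting each method's maximum-F operating
point.

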