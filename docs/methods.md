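# Methods

## The model

`tfproximity` operates on the single assumption that transcription factors
(TFs) which interact — directly, or as members of the same complex — leave
binding sites near one another more often than the genomic background
would produce.  Everything downstream is derived from windowed
co-occurrence counts over a set *B* of binding sites belonging to *n* TFs.

**Co-occurrence matrices.**  For each TF *t* with sites
*B_t* = {b_1, …, b_m}, the matrix **M**_t is the n × m binary matrix with

    M_t[i, j] = 1  iff TF i has at least one site intersecting
                   [start(b_j) − w, end(b_j) + w)

where *w* is the proximity window (default 1000 bp, applied as a radius on
each side of the site).  Sites are half-open BED intervals; the focal site
is excluded from its own window, but *other* sites of the same TF count,
which is what gives the graph informative self-loops.

**Frequencies and normalization.**  Row means of **M**_t give the
co-occurrence frequency vector **f**_t ∈ [0, 1]^n.  Pooling row sums over
all TFs and dividing by the total site count *w* = |B| gives the
background vector **f**_all — the row mean of all **M**_t concatenated
horizontally, i.e. each TF's overall windowed prevalence.  The normalized
vector is the difference

    f′_t = f_t − f_all.

Subtraction (not division) penalizes promiscuous binders evenly and
permits negative entries, read as *depletion*: TF *i* is seen near *t*
less often than its background prevalence predicts.  The directed
adjacency matrix **A** stacks the f′_t as columns; the undirected edge
weight is the symmetrized W = (A + Aᵀ)/2.  A is genuinely asymmetric
(each column conditions on a different TF's sites), and the arithmetic
mean is the symmetric combination that stays inside [−1, 1].  The graph is
complete: n(n+1)/2 undirected edges including self-loops (so 111 TFs give
6216 edges and 585 give 171,405).

## FPR calibration by permutation

The frequencies in f_t are means over a *non-random* sample (one TF's own
sites), so no parametric null for edge weights is defensible.  The null is
instead built by construction: each **M**_t is replaced by a dummy matrix
whose row *i* is i.i.d. Bernoulli(f_all[i]) — TF prevalences preserved,
genomic order (hence proximity) destroyed — and the *entire* adjacency
construction is re-run, including recomputing the background vector from
the dummy matrices.  All n² directed entries of each dummy **A** join a
pooled null; with the default 25 repeats the pool holds 25·n² weights
(308,025 at n = 111; 8,555,625 at n = 585).

Because the construction consumes only row sums, each dummy row mean is
sampled directly as Binomial(m_t, f_all[i]) / m_t rather than
materialising the n × m_t matrices.  This is distributionally identical
and makes large pools cheap.

The threshold for a target FPR α is the smallest pooled weight θ such
that the fraction of pooled weights strictly greater than θ is ≤ α; graph
edges with weight < θ are removed (edges exactly at θ survive).  The
achieved FPR on the pool is reported alongside.  On synthetic null data
(independent uniform binding) the fraction of real directed weights
exceeding θ matches α; the calibration test uses 30 TFs × ~200 sites on a
20 Mb chromosome.  That density (background co-occurrence ≈ 0.02) keeps
the n² real weights effectively independent, so the binomial ±3 SE band is
the right yardstick; at much higher densities the weights become
correlated through the shared background estimate and the empirical
spread of the exceedance fraction exceeds the binomial SE, although its
mean remains α.

FPR is the method's main tuning knob: lower values prune noise but orphan
weakly connected TFs; the conventional grid is {0.1, 0.01, 0.001, 0.0001}.

## Markov clustering

The filtered graph is partitioned with a native implementation of the
Markov Clustering Algorithm: normalize columns of the non-negative weight
matrix, then iterate *expansion* (matrix squaring), *inflation*
(entrywise power r followed by column renormalization) and *pruning*
(zeroing entries < 1e-5, renormalizing) until the maximum entrywise
change drops below 1e-8 or 100 iterations elapse.  Clusters are read off
as connected components of the converged matrix's nonzero support, which
also resolves overlapping attractor systems deterministically.  Singleton
components — including nodes left with no surviving edges — are reported
as *unclustered*, so every reported cluster has ≥ 2 members.

Negative weights cannot act as flow; clustering refuses them and directs
the user to FPR filtering (the calibrated thresholds are positive in
practice).  Surviving data-derived self-loops are kept as flow.  Where a
node's self-loop was filtered away, a loop equal to its **maximum incident
surviving weight** is added (1.0 for isolated nodes, which end up
unclustered regardless).  A fixed unit loop was considered and rejected:
edge weights here are frequency differences of magnitude ~0.1–0.3, and a
unit loop would dominate every column, collapsing the partition into
singletons; the column-max loop keeps loop flow on the data's own scale,
which is also how the reference MCL binary treats self-loops.

Inflation r controls granularity; defaults are r = 2.5, pruning 1e-5,
100 iterations, and results are insensitive across r ∈ [2, 5].
`sweep_inflation` tabulates metrics over a grid to support the empirical
choice.  The metrics mirror the standard reporting row: nodes, edges
filtered (count and %), clusters, median and max nodes per cluster,
unclustered %.

## TFBS filtering with the signed graph

For putative (motif-scan) sites of a *target* TF, the **unfiltered,
signed** graph built from the full putative collection supplies a
*sum-score* per site: the sum over every neighboring putative TFBS
instance in the window of W[target, TF(neighbor)].  Instances, not unique
TFs, are summed — several nearby sites of a strong partner legitimately
boost the score — and negative edges subtract, so a site surrounded by
TFs the target avoids scores below zero.  Other putative target sites
count through the self-loop weight.  The normalized variant divides by
the neighbor count (0-neighbor sites score 0); the "length" score is the
neighbor count itself.

Retention at cutoff c keeps sites with score ≥ c.  Sweeping c over the
distinct score values (prefixed by −∞ for the no-removal point) yields a
precision/recall/F curve:

* *recall* — fraction of actual (experimentally determined) target sites
  whose ±w window contains a retained putative interval;
* *precision* — fraction of retained putative intervals, **merged** into
  disjoint unions first, whose ±w window contains an actual site.  The
  merged count is used as the divisor so precision cannot exceed 1;
* *F* — harmonic mean, 0 when both are 0.

The sweep stops before the retained set would be empty (precision is
undefined there).  The neighbor-count score can be swept in the reversed
direction (retain score ≤ c, c descending) for the case where it
anticorrelates with the sum-score.  A matched random baseline removes the
same number of sites uniformly at random (averaged over seeded draws),
separating co-occurrence information from mere set shrinkage.

## Evaluation against external tables

* **Reference interactions** (STRING `protein.links.detailed` layout,
  combined-score cutoff 400 = "medium confidence" by default, exposed):
  over unordered pairs of TFs present in both the graph and the reference
  universe (self-pairs excluded, unmatched TFs dropped without name
  mapping), a surviving edge ∧ reference pair is a TP; precision, recall
  and F follow.  Zero predicted edges yield precision 0 with a warning so
  parameter sweeps stay total.
* **Channel enrichment**: reference pairs are split into graph-predicted
  vs not; their per-channel scores are compared with a one-sided
  Mann–Whitney rank-sum (predicted > unpredicted).  The rank test was
  chosen because channel scores are bounded, zero-inflated and
  non-normal; fully tied inputs return p = 1.
* **Similarity regression**: OLS of undirected edge weight on pairwise
  PWM similarity (rows for the same unordered pair averaged on input,
  multiplicities kept) over pairs present in both tables; R² = 1 −
  SS_res/SS_tot.  Fewer than 3 shared pairs or zero similarity variance
  is an error.

## Synthetic study conditions

The generators emulate only what the method consumes — pairwise
proximity on a coordinate line.  One uniform chromosome, no chromatin,
no sequence, no strand.

* **Planted clusters** (default benchmark): 3 clusters × 8 TFs, 200
  complex loci per cluster drawn uniformly on 100 Mb, participation
  probability 0.8 per member per locus, placement jitter uniform in
  ±300 bp (inside the 1000 bp window so complexes register), Poisson
  background of 300 sites/TF, 12 bp sites.  These rates give
  within-cluster normalized weights ≈ 0.2 against a null spread of
  ≈ 0.01, a regime where end-to-end recovery at FPR 0.01 is reliable
  (adjusted Rand index 1.0 in the reported runs).
* **Null**: independent Poisson site counts, uniform placement; used for
  calibration (30 TFs × 200 expected sites on 20 Mb, see above).
* **Filter fixture**: planted config with 150 complexes/cluster and 100
  background sites/TF on 30 Mb; the target's complex-derived sites are
  re-jittered to play the role of true motif matches and hidden among
  600 uniform decoys plus all other TFs' sites.  Unfiltered precision is
  then ≈ true/(true + decoys) ≈ 0.17 and the sum-score sweep separates
  true from decoy sites nearly perfectly (max F ≈ 0.99 vs random-removal
  baseline ≈ 0.17).

What passing on these fixtures shows — and what it does not: the planted
generator produces idealized, stationary co-binding with uniform
backgrounds.  Real peak sets have chromatin-driven clumping, hot regions,
copy-number artefacts and uneven mappability, all of which inflate
background co-occurrence locally and can only be partly absorbed by the
global background vector.  Recovery scores on synthetic data are
therefore upper bounds, not forecasts, for real data.

## Numerical and design notes

* TF order is lexicographic everywhere; all matrices and outputs are
  invariant to input record order.  Duplicate identical records are kept
  (per-TF presence/absence makes them harmless in counting).
* Window queries run on per-chromosome interval trees; correctness is
  pinned to brute-force O(m²) oracles in the test suite.
* Thresholding uses strict ">" for false positives and "≥ θ survives"
  for filtering; ties therefore make the achieved FPR conservative.
* The dummy pool holds *directed* (pre-symmetrization) entries — the
  pool-size convention 25·n² requires it.
* MCL convergence: max |ΔM| < 1e-8; converged nonzero columns sum to 1
  within 1e-9.  Non-convergence returns the current partition with a
  warning flag rather than failing.
* Seeds: one `numpy` Generator per stochastic operation, recorded in
  output manifests; derived child seeds stay below 2³¹.
* Problem sizes in the acceptance script (5 recovery runs, 3 filter
  fixtures, 10 baseline draws each) are the package's standard quick
  benchmark; the test suite runs the wider 20-seed versions.

## Known limitations

* No strand handling; peak summits vs full intervals is the caller's
  choice of input.
* The window is a hard cutoff; no distance decay within it.
* TF name matching against reference tables is exact string equality;
  unmatched TFs are dropped, not mapped.
* MCL is run densely (numpy); graphs beyond a few thousand TFs would
  want a sparse implementation.
* The FPR calibrates against the *independence* null only; it does not
  model confounded co-occurrence (e.g. shared open-chromatin preference).
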