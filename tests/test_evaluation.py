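import itertools

import numpy as np
import pytest

from tfproximity.evaluation import (
    channel_enrichment,
    compare_to_reference,
    rank_enrichment,
    similarity_regression,
)
from tfproximity.fpr import filter_graph
from tfproximity.graph import CooccurrenceGraph
from tfproximity.io import ReferenceInteractions, SimilarityTable


def make_filtered(names, edges, all_weight=0.5):
    """FilteredGraph whose surviving off-diagonal edges are exactly `edges`."""
    n = len(names)
    W = np.full((n, n), -1.0)
    idx = {tf: i for i, tf in enumerate(names)}
    for a, b in edges:
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = all_weight
    g = CooccurrenceGraph(tf_names=tuple(names), A=W, W=W, window_bp=1000)
    return filter_graph(g, threshold=0.0)


def make_reference(pairs, proteins=None, channel_values=None):
    norm = {tuple(sorted(p)) for p in pairs}
    channels = (
        "neighborhood fusion cooccurrence coexpression experiments database textmining"
    ).split()
    scores = {}
    for i, p in enumerate(sorted(norm)):
        base = channel_values[p] if channel_values else float(i + 1)
        scores[p] = {c: base for c in channels}
    universe = set(itertools.chain.from_iterable(norm))
    if proteins:
        universe |= set(proteins)
    return ReferenceInteractions(
        pairs=norm, channel_scores=scores, proteins=frozenset(universe),
        score_threshold=400,
    )


class TestCompareToReference:
    def test_perfect_agreement(self):
        names = ("A", "B", "C")
        edges = [("A", "B"), ("B", "C")]
        res = compare_to_reference(make_filtered(names, edges), make_reference(edges))
        assert (res.precision, res.recall, res.f_score) == (1.0, 1.0, 1.0)
        assert res.fp == res.fn == 0

    def test_no_predicted_edges_warns_and_zeroes_precision(self):
        names = ("A", "B", "C")
        fg = make_filtered(names, [])
        ref = make_reference([("A", "B")])
        with pytest.warns(RuntimeWarning, match="precision"):
            res = compare_to_reference(fg, ref)
        assert res.precision == 0.0 and res.recall == 0.0

    def test_counts_match_exhaustive_enumeration(self):
        names = ("A", "B", "C", "D")
        pred_edges = [("A", "B"), ("A", "C"), ("C", "D")]
        ref_pairs = [("A", "B"), ("B", "C"), ("C", "D")]
        fg = make_filtered(names, pred_edges)
        ref = make_reference(ref_pairs, proteins=names)
        res = compare_to_reference(fg, ref)
        pred = {tuple(sorted(e)) for e in pred_edges}
        truth = {tuple(sorted(e)) for e in ref_pairs}
        tp = fp = tn = fn = 0
        for pair in itertools.combinations(names, 2):
            p, t = pair in pred, pair in truth
            tp += p and t
            fp += p and not t
            fn += t and not p
            tn += not p and not t
        assert (res.tp, res.fp, res.tn, res.fn) == (tp, fp, tn, fn)
        assert res.tp + res.fp + res.tn + res.fn == 6

    def test_unmatched_tfs_dropped(self):
        names = ("A", "B", "X")  # X absent from the reference universe
        fg = make_filtered(names, [("A", "B"), ("A", "X")])
        ref = make_reference([("A", "B")])
        res = compare_to_reference(fg, ref)
        assert res.n_tfs_matched == 2 and res.n_tfs_dropped == 1
        assert res.tp == 1 and res.fp == 0

    def test_fewer_than_two_matches_is_error(self):
        fg = make_filtered(("X", "Y"), [("X", "Y")])
        ref = make_reference([("A", "B")])
        with pytest.raises(ValueError, match="match"):
            compare_to_reference(fg, ref)


class TestRankEnrichment:
    def test_null_calibration(self):
        """Identical distributions: rejection rate at alpha=0.05 stays within
        3 SE of 0.05 over repeated draws."""
        rng = np.random.default_rng(10)
        n_rep, n = 200, 50
        rejections = 0
        for _ in range(n_rep):
            x = rng.exponential(size=n)
            y = rng.exponential(size=n)
            p, _ = rank_enrichment(x, y)
            rejections += p < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * se

    def test_power_under_shift(self):
        """Stochastically larger matched scores are detected nearly always
        at n=200 per group."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            x = rng.exponential(size=200) + 0.5
            y = rng.exponential(size=200)
            p, direction = rank_enrichment(x, y)
            hits += (p < 0.05) and direction == "greater"
        assert hits / n_rep >= 0.95

    def test_all_tied_gives_p_one(self):
        p, direction = rank_enrichment([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and direction == "none"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_enrichment([], [1.0])


class TestChannelEnrichment:
    def test_matched_pairs_enriched(self):
        names = tuple(f"T{i}" for i in range(12))
        pairs = list(itertools.combinations(names, 2))
        predicted = set(pairs[::2])
        values = {
            tuple(sorted(p)): (5.0 if p in predicted else 1.0) for p in pairs
        }
        fg = make_filtered(names, list(predicted))
        ref = make_reference(pairs, channel_values=values)
        res = channel_enrichment(fg, ref, "coexpression")
        assert res.p_value < 0.01
        assert res.direction == "greater"
        assert res.n_matched == len(predicted)

    def test_empty_group_is_error(self):
        names = ("A", "B", "C")
        edges = [("A", "B"), ("B", "C"), ("A", "C")]
        fg = make_filtered(names, edges)  # predicts every reference pair
        ref = make_reference(edges)
        with pytest.raises(ValueError, match="unmatched"):
            channel_enrichment(fg, ref, "experiments")

    def test_channel_name_variants_accepted(self):
        names = tuple(f"T{i}" for i in range(6))
        pairs = list(itertools.combinations(names, 2))
        fg = make_filtered(names, pairs[:5])
        ref = make_reference(pairs)
        for alias in ("Co-expression", "coexpression"):
            assert channel_enrichment(fg, ref, alias).channel == "coexpression"


class TestSimilarityRegression:
    def _graph(self, names, W):
        W = np.asarray(W, float)
        return CooccurrenceGraph(tf_names=tuple(names), A=W, W=W, window_bp=1000)

    def test_perfectly_linear_gives_r2_one(self):
        names = ("A", "B", "C", "D")
        sims = {("A", "B"): 0.1, ("A", "C"): 0.4, ("B", "C"): 0.7, ("C", "D"): 0.9}
        W = np.zeros((4, 4))
        idx = {tf: i for i, tf in enumerate(names)}
        for (a, b), s in sims.items():
            W[idx[a], idx[b]] = W[idx[b], idx[a]] = 2.0 * s - 0.3
        res = similarity_regression(self._graph(names, W), SimilarityTable(scores=sims))
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(-0.3)

    def test_independent_weights_give_near_zero_r2(self):
        rng = np.random.default_rng(12)
        n = 50  # 1225 pairs
        names = tuple(f"T{i:02d}" for i in range(n))
        W = rng.normal(size=(n, n))
        W = (W + W.T) / 2
        sims = {
            (names[i], names[j]): float(rng.random())
            for i in range(n)
            for j in range(i + 1, n)
        }
        res = similarity_regression(self._graph(names, W), SimilarityTable(scores=sims))
        assert res.n_pairs == 1225
        assert res.r_squared < 0.02

    def test_five_pair_closed_form(self):
        names = ("A", "B", "C", "D", "E")
        sims = {
            ("A", "B"): 0.2, ("A", "C"): 0.5, ("B", "C"): 0.3,
            ("C", "D"): 0.8, ("D", "E"): 0.6,
        }
        rng = np.random.default_rng(13)
        W = rng.normal(size=(5, 5))
        W = (W + W.T) / 2
        g = self._graph(names, W)
        res = similarity_regression(g, SimilarityTable(scores=sims))
        x = np.array([s for _, s in sorted(sims.items())])
        y = np.array([g.weight(a, b) for (a, b), _ in sorted(sims.items())])
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = np.sum((y - (slope * x + intercept)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.r_squared == pytest.approx(1 - ss_res / ss_tot)

    def test_too_few_pairs_rejected(self):
        names = ("A", "B")
        g = self._graph(names, np.zeros((2, 2)))
        with pytest.raises(ValueError, match=">= 3"):
            similarity_regression(g, SimilarityTable(scores={("A", "B"): 0.5}))

    def test_zero_variance_rejected(self):
        names = ("A", "B", "C")
        g = self._graph(names, np.ones((3, 3)))
        sims = {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5}
        with pytest.raises(ValueError, match="variance"):
            similarity_regression(g, SimilarityTable(scores=sims))
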