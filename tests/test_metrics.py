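import itertools
import math

import numpy as np
import pytest

import scembed as se
from scembed.data import ValidationError
from scembed.zeroshot import NeighborGraph


def entropy_nmi_oracle(a, b):
    """NMI from a contingency table, arithmetic normalization."""
    a, b = list(a), list(b)
    n = len(a)
    ca, cb = sorted(set(a)), sorted(set(b))
    joint = np.zeros((len(ca), len(cb)))
    for x, y in zip(a, b):
        joint[ca.index(x), cb.index(y)] += 1
    joint /= n
    pa, pb = joint.sum(1), joint.sum(0)
    mi = sum(
        joint[i, j] * math.log(joint[i, j] / (pa[i] * pb[j]))
        for i in range(len(ca)) for j in range(len(cb)) if joint[i, j] > 0
    )
    ha = -sum(p * math.log(p) for p in pa if p > 0)
    hb = -sum(p * math.log(p) for p in pb if p > 0)
    return mi / ((ha + hb) / 2) if (ha + hb) else 1.0


def pair_count_ari_oracle(a, b):
    """ARI from pair concordance counts."""
    n = len(a)
    s11 = s00 = s10 = s01 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        s11 += same_a and same_b
        s00 += (not same_a) and (not same_b)
        s10 += same_a and not same_b
        s01 += same_b and not same_a
    total = s11 + s00 + s10 + s01
    expected = (s11 + s10) * (s11 + s01) / total
    maxi = ((s11 + s10) + (s11 + s01)) / 2
    return (s11 - expected) / (maxi - expected)


def silhouette_loop_oracle(X, labels):
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same]) if same else 0.0
        bs = []
        for lab in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            bs.append(np.mean([np.linalg.norm(X[i] - X[j]) for j in other]))
        b = min(bs)
        vals.append(0.0 if not same else (b - a) / max(a, b))
    return float(np.mean(vals))


def lisi_walk_oracle(graph, labels):
    """Literal per-cell walk: count neighbors before any label repeats."""
    totals = []
    for i in range(graph.n):
        seen, count = [], 0
        for j in graph.indices[i]:
            if labels[j] in seen:
                break
            seen.append(labels[j])
            count += 1
        totals.append(count)
    return float(np.mean(totals))


class TestNMI:
    def test_identical_is_one(self):
        assert se.nmi([1, 1, 2, 2], ["x", "x", "y", "y"]) == pytest.approx(1.0)

    def test_constant_labeling_is_zero(self):
        assert se.nmi([0, 0, 0, 0], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_matches_entropy_oracle(self, rng):
        a = rng.integers(0, 3, size=6)
        b = rng.integers(0, 2, size=6)
        assert se.nmi(a, b) == pytest.approx(entropy_nmi_oracle(a, b), abs=1e-10)

    def test_symmetric(self, rng):
        a, b = rng.integers(0, 3, 20), rng.integers(0, 4, 20)
        assert se.nmi(a, b) == pytest.approx(se.nmi(b, a), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            se.nmi([1, 2], [1, 2, 3])


class TestARI:
    def test_renamed_identical_is_one(self):
        assert se.ari([1, 1, 2, 2], ["b", "b", "a", "a"]) == pytest.approx(1.0)

    def test_crossed_pairs_minus_half(self):
        assert se.ari([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_constant_vs_two_class_is_zero(self):
        assert se.ari([0, 0, 0, 0], [1, 1, 2, 2]) == pytest.approx(0.0)

    def test_matches_pair_count_oracle(self, rng):
        a = rng.integers(0, 3, size=8).tolist()
        b = rng.integers(0, 3, size=8).tolist()
        assert se.ari(a, b) == pytest.approx(pair_count_ari_oracle(a, b), abs=1e-10)


class TestASW:
    def test_label_endpoints(self):
        # two tight, far blobs: raw silhouette -> 1, normalized -> 1
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 1e6)])
        labels = [0] * 5 + [1] * 5
        assert se.asw_label(X, labels) == pytest.approx(1.0, abs=1e-5)
        # worst case maps toward 0, mixing maps batch score toward 0.5
        assert se.asw_batch(X, labels) == pytest.approx(0.0, abs=1e-5)

    def test_normalization_formulas(self):
        # interleaved duplicated batches: raw silhouette ~ 0 -> asw_batch ~ 0.5
        rng = np.random.default_rng(1)
        X = rng.random((20, 3))
        X2 = np.vstack([X, X])
        batches = [0] * 20 + [1] * 20
        assert se.asw_batch(X2, batches) == pytest.approx(0.5, abs=0.05)

    def test_matches_loop_oracle(self, rng):
        X = rng.standard_normal((6, 2))
        labels = [0, 0, 1, 1, 2, 2]
        raw = silhouette_loop_oracle(X, labels)
        assert se.asw_label(X, labels) == pytest.approx((raw + 1) / 2, abs=1e-10)
        assert se.asw_batch(X, labels) == pytest.approx(1 - (raw + 1) / 2, abs=1e-10)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            se.asw_label(rng.random((4, 2)), [0, 0, 0, 0])


class TestLISI:
    def _chain_graph(self, labels):
        """Each cell's neighbor list = the other cells in rotation order,
        so with alternating labels every list alternates too."""
        n = len(labels)
        idx = np.array([[(i + d) % n for d in range(1, n)] for i in range(n)])
        dist = np.tile(np.arange(1, n, dtype=float), (n, 1))
        return NeighborGraph(k=n - 1, indices=idx, distances=dist)

    def test_alternating_batches_ilisi_one(self):
        labels = ["A", "B"] * 6
        g = self._chain_graph(labels)
        # each walk sees A,B (or B,A) then stops: raw 2, B=2 -> iLISI 1
        assert se.lisi(g, labels, "ilisi") == pytest.approx(1.0)

    def test_own_batch_only_ilisi_zero(self):
        labels = ["A"] * 5 + ["B"] * 5
        n = 10
        idx = []
        for i in range(n):
            mine = [j for j in range(n) if j != i and labels[j] == labels[i]]
            rest = [j for j in range(n) if j != i and labels[j] != labels[i]]
            idx.append(mine + rest)
        g = NeighborGraph(k=n - 1, indices=np.array(idx),
                          distances=np.tile(np.arange(1.0, n), (n, 1)))
        assert se.lisi(g, labels, "ilisi") == pytest.approx(0.0)

    def test_mono_typed_neighborhoods_clisi_one(self):
        labels = ["A"] * 5 + ["B"] * 5
        idx = np.array([[j for j in range(10) if j != i and labels[j] == labels[i]][:4]
                        for i in range(10)])
        g = NeighborGraph(k=4, indices=idx, distances=np.ones((10, 4)))
        assert se.lisi(g, labels, "clisi") == pytest.approx(1.0)

    def test_matches_literal_walk_oracle(self, rng):
        X = rng.standard_normal((18, 3))
        labels = rng.integers(0, 3, size=18)
        g = se.knn_graph(X, 10)
        assert se.lisi_raw(g, labels) == pytest.approx(lisi_walk_oracle(g, labels), abs=1e-12)

    def test_single_class_rejected(self):
        g = self._chain_graph(["A"] * 4)
        with pytest.raises(ValidationError):
            se.lisi(g, ["A"] * 4, "ilisi")


class TestGraphConnectivity:
    def test_fully_connected_single_type(self, rng):
        X = rng.random((10, 2))
        g = se.knn_graph(X, 9)
        assert se.graph_connectivity(g, ["T"] * 10) == pytest.approx(1.0)

    def test_split_type_half(self):
        # one type in two equal, mutually unreachable clumps
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 100.0)])
        X += np.random.default_rng(0).random((10, 2)) * 0.1
        g = se.knn_graph(X, 2)
        assert se.graph_connectivity(g, ["T"] * 10) == pytest.approx(0.5)

    def test_matches_union_find_oracle(self, rng):
        X = rng.standard_normal((25, 3))
        labels = rng.integers(0, 3, size=25)
        g = se.knn_graph(X, 3)

        parent = list(range(25))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in g.edges():
            if labels[a] == labels[b]:
                parent[find(a)] = find(b)
        scores = []
        for t in np.unique(labels):
            nodes = np.flatnonzero(labels == t)
            roots = [find(i) for i in nodes]
            largest = max(roots.count(r) for r in set(roots))
            scores.append(largest / len(nodes))
        assert se.graph_connectivity(g, labels) == pytest.approx(np.mean(scores), abs=1e-12)


class TestPCR:
    def test_random_labels_score_near_one(self, rng):
        X = rng.standard_normal((120, 10))
        batches = rng.integers(0, 2, size=120)
        assert se.pc_regression_score(X, batches, n_pcs=5) == pytest.approx(1.0, abs=0.05)

    def test_rank_structure_closed_form(self):
        # X = c v' + u w' with u orthogonal to the centered batch indicator c:
        # PCs align with v and w; R2 = 1 for the c-direction, 0 for u.
        n = 40
        batches = np.array([0, 1] * (n // 2))
        c = (batches - batches.mean()).astype(float)
        u = np.array([1.0, -1.0, -1.0, 1.0] * (n // 4))  # orthogonal to c
        v = np.array([3.0, 0.0, 0.0, 0.0])
        w = np.array([0.0, 1.0, 0.0, 0.0])
        X = np.outer(c, v) + np.outer(u, w)
        var1 = (np.linalg.norm(c) * np.linalg.norm(v)) ** 2
        var2 = (np.linalg.norm(u) * np.linalg.norm(w)) ** 2
        varfrac1 = var1 / (var1 + var2)
        assert se.pcr_batch_variance(X, batches, n_pcs=2) == pytest.approx(varfrac1, abs=1e-8)
        assert se.pc_regression_score(X, batches, n_pcs=2) == pytest.approx(1 - varfrac1, abs=1e-8)

    def test_duplicated_batches_score_one(self, rng):
        X = rng.standard_normal((30, 6))
        X2 = np.vstack([X, X])
        batches = [0] * 30 + [1] * 30
        assert se.pc_regression_score(X2, batches, n_pcs=5) == pytest.approx(1.0, abs=1e-8)

    def test_single_batch_rejected(self, rng):
        with pytest.raises(ValidationError):
            se.pc_regression_score(rng.random((10, 3)), [0] * 10)


class TestKBET:
    def test_interleaved_identical_batches_accepted(self, rng):
        X = rng.random((40, 4))
        X2 = np.vstack([X, X])
        batches = np.array([0] * 40 + [1] * 40)
        g = se.knn_graph(X2, 10)
        assert se.kbet_score(g, batches) == pytest.approx(1.0, abs=0.05)

    def test_disjoint_batches_rejected(self, rng):
        X = np.vstack([rng.random((30, 3)), rng.random((30, 3)) + 50.0])
        batches = np.array([0] * 30 + [1] * 30)
        g = se.knn_graph(X, 15)
        assert se.kbet_score(g, batches) == pytest.approx(0.0, abs=0.05)

    def test_alpha_one_rejects_everything(self, rng):
        X = rng.random((20, 3))
        g = se.knn_graph(X, 5)
        batches = rng.integers(0, 2, size=20)
        assert se.kbet_score(g, batches, alpha=1.0) == 0.0


class TestComposites:
    def test_unit_components_mean(self):
        rep = se.IntegrationReport(
            asw_label=1, nmi=1, ari=1, clisi=1, asw_batch=1, pcr=1, gc=1,
            kbet=1, ilisi=1, s_batch=1.0, s_bio=1.0,
        )
        assert rep.s_batch == 1.0

    def test_report_internally_consistent(self, zero_shot_dataset):
        spec, feats, _, x, truth = zero_shot_dataset
        import dataclasses

        spec2 = dataclasses.replace(spec, n_batches=2, batch_shift=2.0)
        x2, truth2 = se.synth_expression(spec2)
        emb = se.cell_embeddings(x2, feats, "wa")
        rep = se.integration_report(emb, truth2["cell_types"], truth2["batches"], seed=0)
        assert rep.s_batch == pytest.approx(
            np.mean([rep.asw_batch, rep.pcr, rep.gc, rep.kbet, rep.ilisi]), abs=1e-12
        )
        assert rep.s_bio == pytest.approx(
            np.mean([rep.asw_label, rep.nmi, max(rep.ari, 0.0), rep.clisi]), abs=1e-12
        )
        for name, v in rep.to_dict().items():
            if name != "ari":
                assert 0.0 <= v <= 1.0, name


class TestBLEU:
    def test_identity_is_one(self):
        assert se.bleu_n("the quick brown fox", "the quick brown fox", 2) == 1.0

    def test_disjoint_is_zero(self):
        assert se.bleu_n("alpha beta", "gamma delta", 1) == 0.0

    def test_clipping_hand_count(self):
        assert se.bleu_n("the the the", "the cat", 1) == pytest.approx(1 / 3)

    def test_short_candidate_zero(self):
        assert se.bleu_n("one", "one two", 2) == 0.0

    def test_token_renaming_invariance(self, rng):
        cand = ["a", "b", "a", "c"]
        ref = ["a", "c", "b"]
        ren = {"a": "x", "b": "y", "c": "z"}
        for n in (1, 2):
            assert se.bleu_n(cand, ref, n) == se.bleu_n(
                [ren[t] for t in cand], [ren[t] for t in ref], n
            )

    def test_invalid_n(self):
        with pytest.raises(ValidationError):
            se.bleu_n("a", "a", 0)


class TestClassificationScores:
    def test_perfect_prediction(self):
        s = se.classification_scores(["a", "b", "a"], ["a", "b", "a"])
        assert all(v == 1.0 for v in s.values())

    def test_two_class_confusion_hand_values(self):
        # confusion [[2,1],[0,3]]: true a: pred a,a,b; true b: pred b,b,b
        true = ["a"] * 3 + ["b"] * 3
        pred = ["a", "a", "b", "b", "b", "b"]
        s = se.classification_scores(pred, true)
        prec_a, prec_b = 2 / 2, 3 / 4
        rec_a, rec_b = 2 / 3, 3 / 3
        f1_a = 2 * prec_a * rec_a / (prec_a + rec_a)
        f1_b = 2 * prec_b * rec_b / (prec_b + rec_b)
        assert s["accuracy"] == pytest.approx(5 / 6)
        assert s["precision"] == pytest.approx((prec_a + prec_b) / 2)
        assert s["recall"] == pytest.approx((rec_a + rec_b) / 2)
        assert s["f1"] == pytest.approx((f1_a + f1_b) / 2)

    def test_constant_prediction_macro_recall(self):
        true = ["a", "a", "b", "c", "c", "c"]
        pred = ["c"] * 6
        s = se.classification_scores(pred, true)
        assert s["accuracy"] == pytest.approx(3 / 6)
        assert s["recall"] == pytest.approx((0 + 0 + 1) / 3)


class TestRegressionScores:
    def test_r2_endpoints(self, rng):
        y = rng.random(10)
        assert se.r2(y, y) == 1.0
        assert se.r2(y, np.full(10, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_sum_of_squares_oracle(self):
        y = np.array([1.0, 2.0, 4.0, 7.0])
        f = np.array([1.5, 2.0, 3.0, 8.0])
        ss_res = sum((a - b) ** 2 for a, b in zip(y, f))
        ss_tot = sum((a - y.mean()) ** 2 for a in y)
        assert se.r2(y, f) == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_r2_constant_truth_rejected(self):
        with pytest.raises(ValidationError):
            se.r2([1.0, 1.0], [1.0, 2.0])

    def test_pcc_endpoints(self, rng):
        y = rng.random((10, 5))
        assert se.pcc_genes(y, y) == pytest.approx(1.0)
        assert se.pcc_genes(y, -y) == pytest.approx(-1.0)

    def test_pcc_matches_loop_oracle(self, rng):
        y, f = rng.random((10, 5)), rng.random((10, 5))
        vals = []
        for j in range(5):
            a, b = y[:, j], f[:, j]
            vals.append(((a - a.mean()) * (b - b.mean())).mean() / (a.std() * b.std()))
        assert se.pcc_genes(y, f) == pytest.approx(np.mean(vals), abs=1e-10)

    def test_mse(self, rng):
        y = rng.random((6, 4))
        assert se.mse_genes(y, y) == 0.0
        assert se.mse_genes(y, y + 0.5) == pytest.approx(0.25, abs=1e-12)
        f = rng.random((6, 4))
        loop = np.mean([(y[i, j] - f[i, j]) ** 2 for i in range(6) for j in range(4)])
        assert se.mse_genes(y, f) == pytest.approx(loop, abs=1e-12)
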