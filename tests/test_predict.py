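"""Pair datasets, classifiers, and ranking/threshold evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kglit import (
    ClassifierSpec,
    EmbeddingTable,
    PairDataset,
    build_pair_dataset,
    evaluate,
    load_benchmark_pairs,
    make_features,
    rank_candidates,
    select_entity_pool,
    train_classifier,
)


# -- oracles ----------------------------------------------------------


def auroc_concordance_oracle(y, scores):
    """O(n^2) concordant-pair count with half credit for ties."""
    pos = [s for s, label in zip(scores, y) if label == 1]
    neg = [s for s, label in zip(scores, y) if label == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_step_oracle(y, scores):
    """Step-wise precision-recall integration (sum of dR * precision).

    The PR curve is defined per score threshold, so tied scores enter as one
    step.
    """
    y = np.asarray(y)
    scores = np.asarray(scores)
    area = 0.0
    prev_r = 0.0
    n_pos = y.sum()
    for threshold in sorted(set(scores), reverse=True):
        kept = scores >= threshold
        precision = y[kept].sum() / kept.sum()
        recall = y[kept].sum() / n_pos
        area += (recall - prev_r) * precision
        prev_r = recall
    return area


# -- fixtures ---------------------------------------------------------


def _separable_embeddings(n_drugs=12, n_cands=12, dim=8, seed=0):
    """Embeddings where positives are (same-cluster) pairs: trivially separable."""
    rng = np.random.Generator(np.random.PCG64(seed))
    tokens, vecs = [], []
    for i in range(n_drugs):
        v = np.zeros(dim)
        v[i % 2] = 1.0
        tokens.append(f"stitch:{i}")
        vecs.append(v + 0.01 * rng.normal(size=dim))
    for j in range(n_cands):
        v = np.zeros(dim)
        v[j % 2] = 1.0
        tokens.append(f"entrez:{j}")
        vecs.append(v + 0.01 * rng.normal(size=dim))
    return EmbeddingTable(tokens, np.array(vecs))


def _separable_dataset(n_drugs=12, n_cands=12, labels="same_cluster"):
    """Cleanly learnable pair labels over the clustered embeddings.

    ``same_cluster`` labels are a symmetric interaction (learnable by models
    that can compare the two entity blocks: ann, rf, siamese); ``and_cluster``
    labels (both entities in cluster 0) are linearly separable in the
    concatenated feature space, which is what logistic regression can fit.
    """
    pairs = []
    for i in range(n_drugs):
        for j in range(n_cands):
            if labels == "same_cluster":
                y = int(i % 2 == j % 2)
            else:
                y = int(i % 2 == 0 and j % 2 == 0)
            pairs.append((f"stitch:{i}", f"entrez:{j}", y))
    return PairDataset(pairs, "train")


class TestSelectEntityPool:
    def test_set_algebra(self):
        kg = {"a", "b", "c"}
        text = {"b", "c", "d"}
        assert select_entity_pool(kg, text, "overlap") == {"b", "c"}
        assert select_entity_pool(kg, text, "union") == {"a", "b", "c", "d"}
        assert select_entity_pool(kg, text, "kg_only") == kg
        assert select_entity_pool(kg, text, "text_only") == text
        assert select_entity_pool(kg, text, "overlap") <= select_entity_pool(kg, text, "union")

    def test_restriction_and_fixture_oracle(self):
        rng = np.random.Generator(np.random.PCG64(1))
        kg = {f"e{i}" for i in rng.choice(200, 80, replace=False)}
        text = {f"e{i}" for i in rng.choice(200, 80, replace=False)}
        types = {e for e in kg | text if int(e[1:]) % 2 == 0}
        got = select_entity_pool(kg, text, "overlap", restrict_to=types)
        assert got == (kg & text) & types

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="pool mode"):
            select_entity_pool(set(), set(), "bogus")


class TestBuildPairDataset:
    def test_balanced_and_disjoint(self):
        positives = {(f"d{i}", f"g{i}") for i in range(10)}
        train, test = build_pair_dataset(
            positives, [f"d{i}" for i in range(10)], [f"g{i}" for i in range(10)], seed=0
        )
        all_pairs = train.pairs + test.pairs
        assert sum(1 for *_, y in all_pairs if y == 1) == 10
        assert sum(1 for *_, y in all_pairs if y == 0) == 10
        neg = {(d, c) for d, c, y in all_pairs if y == 0}
        assert neg.isdisjoint(positives)

    def test_split_fractions(self):
        positives = {(f"d{i}", f"g{j}") for i in range(20) for j in range(5)}
        train, test = build_pair_dataset(
            positives, [f"d{i}" for i in range(20)], [f"g{j}" for j in range(40)], seed=1
        )
        assert len(test) == round(0.2 * (len(train) + len(test)))
        assert train.split == "train" and test.split == "test"

    def test_all_pairs_positive_rejected(self):
        positives = {("d0", "g0"), ("d0", "g1")}
        with pytest.raises(ValueError, match="negative space"):
            build_pair_dataset(positives, ["d0"], ["g0", "g1"], seed=0)

    def test_large_fixture_no_overlap_or_collision(self):
        rng = np.random.Generator(np.random.PCG64(3))
        drugs = [f"d{i}" for i in range(100)]
        genes = [f"g{i}" for i in range(100)]
        flat = rng.choice(10_000, size=5_000, replace=False)
        positives = {(drugs[f // 100], genes[f % 100]) for f in flat}
        train, test = build_pair_dataset(positives, drugs, genes, seed=4)
        train_set = {(d, c) for d, c, _ in train.pairs}
        test_set = {(d, c) for d, c, _ in test.pairs}
        assert train_set.isdisjoint(test_set)  # membership oracle
        negs = {(d, c) for d, c, y in train.pairs + test.pairs if y == 0}
        assert negs.isdisjoint(positives)
        assert len(negs) == len(positives)

    def test_deterministic(self):
        positives = {(f"d{i}", f"g{i}") for i in range(15)}
        drugs = [f"d{i}" for i in range(15)]
        genes = [f"g{i}" for i in range(30)]
        a = build_pair_dataset(positives, drugs, genes, seed=7)
        b = build_pair_dataset(positives, drugs, genes, seed=7)
        assert a[0].pairs == b[0].pairs and a[1].pairs == b[1].pairs

    def test_conflicting_labels_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            PairDataset([("d", "g", 0), ("d", "g", 1)])


class TestMakeFeatures:
    def test_concatenation_drug_first(self):
        emb = _separable_embeddings()
        f = make_features(("stitch:0", "entrez:3"), emb)
        assert f.shape == (16,)
        np.testing.assert_array_equal(f[:8], emb["stitch:0"])
        np.testing.assert_array_equal(f[8:], emb["entrez:3"])

    def test_zero_fill_for_missing_entity(self):
        emb = _separable_embeddings()
        with pytest.raises(KeyError):
            make_features(("stitch:0", "missing"), emb)
        f = make_features(("stitch:0", "missing"), emb, zero_fill=True)
        np.testing.assert_array_equal(f[8:], np.zeros(8))


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["ann", "rf", "lr", "siamese"])
    def test_separable_data_fit_perfectly(self, kind):
        emb = _separable_embeddings()
        train = _separable_dataset(labels="and_cluster" if kind == "lr" else "same_cluster")
        spec = ClassifierSpec(kind=kind, seed=0)
        model = train_classifier(spec, train, emb)
        scores = model.score_pairs([(d, c) for d, c, _ in train.pairs])
        preds = (scores >= 0.5).astype(int)
        assert (preds == train.labels()).mean() == 1.0
        assert np.all((scores >= 0) & (scores <= 1))

    def test_ann_hidden_width_is_twice_input(self):
        emb = _separable_embeddings()
        model = train_classifier(ClassifierSpec("ann", seed=0, ann_epochs=2), _separable_dataset(), emb)
        assert model.hidden_width == 2 * (2 * emb.dim)

    def test_rf_and_lr_published_settings(self):
        emb = _separable_embeddings()
        rf = train_classifier(ClassifierSpec("rf", seed=0), _separable_dataset(), emb)
        assert rf.model.n_estimators == 50
        assert rf.model.criterion == "gini"
        assert rf.model.min_samples_leaf == 1
        lr = train_classifier(
            ClassifierSpec("lr", seed=0), _separable_dataset(labels="and_cluster"), emb
        )
        assert lr.model.C == 10.0
        assert lr.model.l1_ratio == 0.0  # pure L2 penalty

    def test_single_class_rejected(self):
        emb = _separable_embeddings()
        ds = PairDataset([("stitch:0", "entrez:0", 1), ("stitch:1", "entrez:1", 1)])
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(ClassifierSpec("lr"), ds, emb)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="classifier kind"):
            ClassifierSpec("svm")


class _FixedScores:
    """Stand-in fitted model returning scripted scores (for metric tests)."""

    def __init__(self, mapping):
        self.mapping = mapping

    def score_pairs(self, pairs):
        return np.array([self.mapping[p] for p in pairs])


def _dataset_from(scores_labels):
    pairs, mapping = [], {}
    for i, (s, y) in enumerate(scores_labels):
        pair = (f"d{i % 3}", f"g{i}")
        pairs.append((*pair, y))
        mapping[pair] = s
    return PairDataset(pairs, "test"), _FixedScores(mapping)


class TestEvaluate:
    def test_perfect_and_inverted(self):
        test, model = _dataset_from([(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)])
        report = evaluate(model, test)
        assert report.auroc == 1.0 and report.aupr == 1.0
        test_inv, model_inv = _dataset_from([(0.9, 0), (0.8, 0), (0.2, 1), (0.1, 1)])
        assert evaluate(model_inv, test_inv).auroc == 0.0

    def test_matches_quadratic_oracles(self):
        rng = np.random.Generator(np.random.PCG64(5))
        scores = rng.random(200).round(2)  # rounding forces ties
        labels = (rng.random(200) < 0.4).astype(int)
        labels[:2] = [0, 1]  # both classes present
        test, model = _dataset_from(zip(scores, labels))
        report = evaluate(model, test)
        y = test.labels()
        s = model.score_pairs([(d, c) for d, c, _ in test.pairs])
        assert report.auroc == pytest.approx(auroc_concordance_oracle(y, s), abs=1e-9)
        assert report.aupr == pytest.approx(aupr_step_oracle(y, s), abs=1e-9)

    def test_constant_scores_give_exactly_half(self):
        test, model = _dataset_from([(0.5, y) for y in (1, 1, 0, 0, 1, 0)])
        assert evaluate(model, test).auroc == 0.5

    def test_single_class_rejected(self):
        test, model = _dataset_from([(0.9, 1), (0.8, 1)])
        with pytest.raises(ValueError, match="both classes"):
            evaluate(model, test)

    def test_per_drug_recall_threshold_and_topk(self):
        pairs = [
            ("dA", "g1", 1),
            ("dA", "g2", 1),
            ("dA", "g3", 0),
            ("dB", "g4", 1),
            ("dB", "g5", 0),
        ]
        mapping = {("dA", "g1"): 0.9, ("dA", "g2"): 0.3, ("dA", "g3"): 0.1,
                   ("dB", "g4"): 0.2, ("dB", "g5"): 0.8}
        test = PairDataset(pairs, "test")
        model = _FixedScores(mapping)
        report = evaluate(model, test)
        assert report.per_drug_recall == {"dA": 0.5, "dB": 0.0}
        assert report.macro_recall == pytest.approx(0.25)
        # recall@1: dA's top-1 is g1 (one of two positives), dB's is g5 (negative)
        topk = evaluate(model, test, recall_at_k=1)
        assert topk.per_drug_recall == {"dA": 0.5, "dB": 0.0}

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=6, max_size=40))
    def test_auroc_invariant_under_monotone_transform(self, grid):
        # grid-valued scores keep ties exact under the strictly monotone map
        raw = [g / 50 for g in grid]
        labels = [i % 2 for i in range(len(raw))]
        test, model = _dataset_from(zip(raw, labels))
        base = evaluate(model, test).auroc
        transformed, model2 = _dataset_from(
            zip([np.exp(3 * s) / 50 for s in raw], labels)
        )
        assert evaluate(model2, transformed).auroc == pytest.approx(base, abs=1e-12)


class TestRankCandidates:
    def test_planted_top_candidate_and_permutation(self):
        mapping = {("d", f"g{i}"): i / 10 for i in range(8)}
        model = _FixedScores(mapping)
        candidates = [f"g{i}" for i in range(8)]
        ranked, pos_ranks = rank_candidates(model, "d", candidates, known_positives=["g7", "g0"])
        assert ranked[0][0] == "g7"
        assert sorted(c for c, _ in ranked) == sorted(candidates)
        assert pos_ranks == {"g7": 1, "g0": 8}
        # brute-force sort oracle
        oracle = sorted(candidates, key=lambda c: (-mapping[("d", c)], c))
        assert [c for c, _ in ranked] == oracle

    def test_ties_break_lexicographically(self):
        mapping = {("d", c): 0.5 for c in ("gB", "gA", "gC")}
        ranked, _ = rank_candidates(_FixedScores(mapping), "d", ["gB", "gA", "gC"])
        assert [c for c, _ in ranked] == ["gA", "gB", "gC"]


class TestLoadBenchmarkPairs:
    def test_duplicates_collapse(self, tmp_path):
        p = tmp_path / "bench.tsv"
        p.write_text("D00002\thsa:10\nD00002\thsa:10\nD00448\thsa:190\n")
        pairs, unmapped = load_benchmark_pairs(p)
        assert pairs == {("D00002", "hsa:10"), ("D00448", "hsa:190")}
        assert unmapped == 0

    def test_unmappable_rows_excluded_and_counted(self, tmp_path):
        p = tmp_path / "bench.tsv"
        p.write_text("D1\tg1\nD2\tg2\nD3\tg3\n")
        with pytest.warns(UserWarning, match="2 rows"):
            pairs, unmapped = load_benchmark_pairs(p, id_map={"D1": "stitch:1"})
        assert pairs == {("stitch:1", "g1")}
        assert unmapped == 2

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bench.tsv"
        p.write_text("a\tb\nbroken-row\n")
        with pytest.raises(ValueError, match="line 2"):
            load_benchmark_pairs(p)
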