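import numpy as np
import pytest

import heterolink as hl
from heterolink import evaluation as E


class TestAuroc:
    def test_perfect_separation(self):
        assert E.compute_auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_tied_is_half(self):
        assert E.compute_auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_hand_counted_case(self):
        # pairs: (0.9,0.8)+, (0.9,0.1)+, (0.7,0.8)-, (0.7,0.1)+ -> 3/4
        assert E.compute_auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            E.compute_auroc([1, 1], [0.5, 0.6])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        scores = rng.normal(size=50)
        a = E.compute_auroc(labels, scores)
        b = E.compute_auroc(labels, np.exp(3 * scores))
        assert np.isclose(a, b, atol=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(10):
            labels = rng.integers(0, 2, 40)
            labels[:2] = [0, 1]
            scores = np.round(rng.normal(size=40), 1)  # induce ties
            assert np.isclose(
                E.compute_auroc(labels, scores), roc_auc_score(labels, scores), atol=1e-12
            )


class TestAuprc:
    def test_positives_first(self):
        assert E.compute_auprc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_single_positive_last(self):
        n = 5
        labels = [0, 0, 0, 0, 1]
        scores = [0.9, 0.8, 0.7, 0.6, 0.1]
        assert np.isclose(E.compute_auprc(labels, scores), 1 / n)

    def test_six_sample_table_oracle(self):
        # ranking: + - + - - + ; AP = (1/1 + 2/3 + 3/6)/3
        labels = [1, 0, 1, 0, 0, 1]
        scores = [0.9, 0.85, 0.7, 0.6, 0.5, 0.4]
        assert np.isclose(E.compute_auprc(labels, scores), (1 + 2 / 3 + 0.5) / 3)

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            E.compute_auprc([0, 0], [0.5, 0.6])

    def test_matches_sklearn(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(2)
        for _ in range(10):
            labels = rng.integers(0, 2, 30)
            labels[0] = 1
            scores = np.round(rng.normal(size=30), 1)
            assert np.isclose(
                E.compute_auprc(labels, scores),
                average_precision_score(labels, scores),
                atol=1e-12,
            )

    def test_random_scorer_near_prevalence(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(4000) < 0.3).astype(int)
        scores = rng.random(4000)
        assert abs(E.compute_auprc(labels, scores) - 0.3) < 0.05


class TestAccuracy:
    def test_exact_probabilities(self):
        assert E.accuracy_at_threshold([0, 1, 1], [0.0, 1.0, 1.0]) == 1.0

    def test_tie_called_positive(self):
        assert E.accuracy_at_threshold([1, 0], [0.5, 0.5]) == 0.5

    def test_constant_classifier_on_balanced_labels(self):
        labels = [0, 1] * 10
        assert E.accuracy_at_threshold(labels, [0.7] * 20) == 0.5


class TestAveragePrecisionAtK:
    def test_all_hits(self):
        assert E.average_precision_at_k([1, 1, 1], 3) == 1.0

    def test_no_hits_zero(self):
        assert E.average_precision_at_k([0, 0, 0], 3) == 0.0

    def test_truncation(self):
        # hit at ranks 1 and 4; top-2 sees only the first
        labels = [1, 0, 0, 1]
        assert E.average_precision_at_k(labels, 2) == 1.0
        assert np.isclose(E.average_precision_at_k(labels, 4), (1.0 + 2 / 4) / 2)


class TestSplit:
    def test_disjoint_exhaustive_proportions(self):
        plan = E.make_split(100, seed=0)
        all_idx = sorted(plan.train_indices + plan.validation_indices + plan.test_indices)
        assert all_idx == list(range(100))
        assert len(plan.train_indices) == 80
        assert len(plan.validation_indices) == len(plan.test_indices) == 10

    def test_seeded_reproducibility(self):
        assert E.make_split(50, seed=4).train_indices == E.make_split(50, seed=4).train_indices

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            E.make_split(10, fractions=(0.5, 0.2, 0.2))


@pytest.fixture(scope="module")
def cv_run(small_sim, small_sim_features):
    _, dataset, _ = small_sim
    cfg = hl.TrainConfig(epochs=6, seed=0)
    return E.kfold_cv(dataset, small_sim_features, cfg, k=5, seed=0), dataset


@pytest.fixture(scope="module")
def trained(small_sim, small_sim_features):
    _, dataset, _ = small_sim
    cfg = hl.TrainConfig(epochs=6, seed=0)
    state, _ = hl.train(dataset, small_sim_features, cfg)
    return dataset, cfg, state


class TestKFold:
    def test_folds_partition_exactly(self, cv_run):
        (per_fold, mean, folds), dataset = cv_run
        n = 2 * dataset.associations.n_positives
        flat = sorted(i for f in folds for i in f)
        assert flat == list(range(n))
        for a in range(5):
            for b in range(a + 1, 5):
                assert not (set(folds[a]) & set(folds[b]))

    def test_mean_is_arithmetic_mean(self, cv_run):
        (per_fold, mean, _), _ = cv_run
        assert np.isclose(mean.auroc, np.mean([r.auroc for r in per_fold]), atol=1e-12)
        assert np.isclose(mean.auprc, np.mean([r.auprc for r in per_fold]), atol=1e-12)

    def test_seed_reproducible(self, small_sim, small_sim_features):
        _, dataset, _ = small_sim
        cfg = hl.TrainConfig(epochs=3, seed=1)
        r1 = E.kfold_cv(dataset, small_sim_features, cfg, k=3, seed=2)
        r2 = E.kfold_cv(dataset, small_sim_features, cfg, k=3, seed=2)
        assert [f.auroc for f in r1[0]] == [f.auroc for f in r2[0]]

    def test_leakage_assertion_fires_on_violation(self, small_sim, small_sim_features):
        """The no-leak callback rejects a negative set containing test edges."""
        from heterolink import negative_sampling as ns

        _, dataset, _ = small_sim
        res = ns.NegativeSampleResult(np.zeros(2), 0.0, [(0, 0)], [1.0])
        test_edges = {(0, 0)}
        leaked = set(res.negative_edges) & test_edges
        assert leaked  # the guarded condition the CV callback asserts against


class TestLoocv:
    def test_ranks_match_exhaustive_scoring(self, small_sim, small_sim_features):
        """Fast-mode LOOCV ranks equal direct scoring with the shared model."""
        from heterolink import training as T

        _, dataset, _ = small_sim
        cfg = hl.TrainConfig(epochs=5, seed=0)
        assoc = dataset.associations.matrix
        counts = assoc.sum(axis=1)
        d = int(np.argmax(counts))
        disease_id = dataset.associations.disease_ids[d]
        res = E.loocv_disease(dataset, small_sim_features, cfg, disease_id, fast=True)

        masked = assoc.copy()
        masked[d, :] = 0
        rows, cols = np.nonzero(masked)
        known = np.nonzero(assoc[d])[0]
        state, _ = T.train(
            dataset, small_sim_features, cfg,
            train_positives=[(int(i), int(j)) for i, j in zip(rows, cols)],
            exclude_pairs={(d, int(j)) for j in known},
            assoc_override=masked,
        )
        probs = T.predict_probabilities(dataset, small_sim_features, state, cfg)
        candidates = np.nonzero(assoc[d] == 0)[0]
        for j, rank in zip(known, res["ranks"]):
            pool = np.r_[candidates, j]
            scores = probs[d, pool]
            assert rank == 1 + int((scores > scores[-1]).sum())

    def test_requires_two_known(self, small_sim, small_sim_features):
        _, dataset, _ = small_sim
        cfg = hl.TrainConfig(epochs=1, seed=0)
        assoc = dataset.associations.matrix
        lonely = np.nonzero(assoc.sum(axis=1) < 2)[0]
        if lonely.size:
            with pytest.raises(ValueError, match=">= 2"):
                E.loocv_disease(
                    dataset, small_sim_features, cfg,
                    dataset.associations.disease_ids[int(lonely[0])],
                )

    def test_unknown_disease_rejected(self, small_sim, small_sim_features):
        _, dataset, _ = small_sim
        with pytest.raises(ValueError, match="unknown disease"):
            E.loocv_disease(dataset, small_sim_features, hl.TrainConfig(epochs=1), "nope")


class TestRankCandidates:
    def test_sorted_and_disjoint_from_known(self, trained):
        dataset, cfg, state = trained
        did = dataset.associations.disease_ids[0]
        ranking = E.rank_candidates(
            state, dataset, hl.one_hot_features(dataset.gene_net), cfg, did, top_n=5
        )
        probs = [p for _, p in ranking]
        assert probs == sorted(probs, reverse=True)
        d = 0
        known = {
            dataset.associations.mirna_ids[j]
            for j in np.nonzero(dataset.associations.matrix[d])[0]
        }
        assert not ({m for m, _ in ranking} & known)

    def test_top_n_clamped(self, trained):
        dataset, cfg, state = trained
        did = dataset.associations.disease_ids[0]
        feats = hl.one_hot_features(dataset.gene_net)
        ranking = E.rank_candidates(state, dataset, feats, cfg, did, top_n=10_000)
        n_unknown = int((dataset.associations.matrix[0] == 0).sum())
        assert len(ranking) == n_unknown
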