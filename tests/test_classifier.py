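import itertools

import numpy as np
import pytest

from dolphyn import synthetic
from dolphyn.classifier import (
    LabeledPeptide,
    build_training_set,
    compute_auc,
    oob_auc,
    score_long_peptide,
    split_by_wildtype,
    train,
)
from dolphyn.core_io import ReactivityTable, ValidationError
from dolphyn.synthetic import make_labeled_peptides


def pairwise_auc(scores, labels):
    """Independent oracle: P(random positive outranks random negative), ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestComputeAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_small_example_matches_pair_counting(self):
        scores, labels = [0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]
        assert compute_auc(scores, labels) == pytest.approx(0.75)
        assert pairwise_auc(scores, labels) == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(123)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        assert compute_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_matches_oracle_on_random_instances_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores = rng.integers(0, 5, 30) / 4.0  # forces ties
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            assert compute_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels))

    def test_complement_symmetry(self):
        rng = np.random.default_rng(11)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert compute_auc(scores, labels) + compute_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            compute_auc([0.1, 0.2], [1, 1])


def _scan_table(n_pos=4, n_neg=10):
    """Tiny hand-built scan reactivity table keyed by sequence."""
    rng = np.random.default_rng(5)
    pos = [synthetic._motif_15mer(rng, (5, 8)) for _ in range(n_pos)]
    neg = [synthetic._random_seq(rng, 15) for _ in range(n_neg)]
    # one peptide reactive in exactly ONE sample -> excluded from both classes
    lone = synthetic._motif_15mer(rng, (5, 8))
    peptides = pos + neg + [lone]
    samples = ["s1", "s2", "s3", "b1", "b2"]
    hfc = np.zeros((len(peptides), 5))
    hfc[:n_pos, :2] = 2.0  # positives reactive in exactly 2 serum samples
    hfc[-1, 0] = 2.0  # lone single-sample reactivity
    counts = np.zeros((len(peptides), 5))
    counts[:, 3:] = np.arange(len(peptides))[:, None] + 1  # bead ranking signal
    table = ReactivityTable(peptide_ids=peptides, sample_ids=samples,
                            counts=counts, log_hfc=hfc)
    wt = {p: f"wt{i % 3}" for i, p in enumerate(peptides)}
    return table, wt, pos, neg, lone


class TestBuildTrainingSet:
    def test_two_sample_rule_and_balance(self):
        table, wt, pos, neg, lone = _scan_table()
        data = build_training_set(table, wt, ["b1", "b2"])
        labels = {d.seq: d.label for d in data}
        assert all(labels[p] == 1 for p in pos)
        assert lone not in labels  # reactive in only 1 sample: neither class
        assert sum(d.label for d in data) == len(data) - sum(d.label for d in data)

    def test_negatives_ranked_by_bead_count(self):
        table, wt, pos, neg, _ = _scan_table(n_pos=2, n_neg=10)
        data = build_training_set(table, wt, ["b1", "b2"])
        chosen_negs = [d.seq for d in data if d.label == 0]
        # the bead counts rise with row index, so the last negatives win
        assert set(chosen_negs) == set(neg[-2:])

    def test_too_few_negatives_errors(self):
        table, wt, *_ = _scan_table(n_pos=6, n_neg=2)
        with pytest.raises(ValidationError, match="negative"):
            build_training_set(table, wt, ["b1", "b2"])


class TestSplitByWildtype:
    def _data(self, n_wt=20, per_wt=10):
        return [
            LabeledPeptide(f"{'ACDEFGHIKLMNPQR'}", f"wt{w}", w % 2)
            for w in range(n_wt)
            for _ in range(per_wt)
        ]

    def test_disjoint_and_sized(self):
        data = self._data()
        train_set, test_set = split_by_wildtype(data, test_frac=0.05, seed=1)
        assert {d.wildtype_id for d in train_set}.isdisjoint(
            {d.wildtype_id for d in test_set})
        assert len(test_set) == 10  # one whole wildtype reaches the 5% target
        assert len(train_set) + len(test_set) == len(data)

    def test_deterministic_under_seed(self):
        data = self._data()
        a = split_by_wildtype(data, seed=7)
        b = split_by_wildtype(data, seed=7)
        assert a == b

    def test_disjoint_for_any_seed(self):
        data = self._data(n_wt=7, per_wt=3)
        for seed in range(20):
            tr, te = split_by_wildtype(data, test_frac=0.3, seed=seed)
            assert {d.wildtype_id for d in tr}.isdisjoint({d.wildtype_id for d in te})
            assert te  # target > 0 peptides

    def test_single_wildtype_rejected(self):
        data = [LabeledPeptide("A" * 15, "wt0", i % 2) for i in range(10)]
        with pytest.raises(ValidationError):
            split_by_wildtype(data)


class TestTrainPredict:
    def test_separable_fixture_high_auc(self, small_model):
        data = make_labeled_peptides(150, seed=11)
        assert oob_auc(small_model, [d.label for d in data]) > 0.9

    def test_training_set_auc_near_one_when_separable(self, small_model):
        data = make_labeled_peptides(150, seed=11)
        scores = small_model.predict_proba_many([d.seq for d in data])
        assert compute_auc(scores, [d.label for d in data]) > 0.95

    def test_permuted_labels_null_auc(self):
        data = make_labeled_peptides(300, seed=21)
        rng = np.random.default_rng(42)
        labels = rng.permutation([d.label for d in data])
        shuffled = [LabeledPeptide(d.seq, d.wildtype_id, int(l))
                    for d, l in zip(data, labels)]
        model = train(shuffled, n_trees=50, seed=42)
        assert oob_auc(model, [d.label for d in shuffled]) == pytest.approx(0.5, abs=0.07)

    def test_retrain_same_seed_identical(self):
        data = make_labeled_peptides(60, seed=3)
        m1 = train(data, n_trees=30, seed=42)
        m2 = train(data, n_trees=30, seed=42)
        probe = [d.seq for d in data[:10]]
        assert np.array_equal(m1.predict_proba_many(probe), m2.predict_proba_many(probe))

    def test_positive_sidechain_importance_top3(self, small_model):
        top3 = [name for name, _ in small_model.importances()[:3]]
        assert "sc_positive" in top3

    def test_probability_range_and_batch_consistency(self, small_model):
        seqs = [d.seq for d in make_labeled_peptides(10, seed=9)][:10]
        batch = small_model.predict_proba_many(seqs)
        assert ((batch >= 0) & (batch <= 1)).all()
        assert batch[0] == pytest.approx(small_model.predict_proba(seqs[0]))

    def test_single_class_rejected(self):
        data = [LabeledPeptide("K" * 15, "wt0", 1), LabeledPeptide("R" * 15, "wt1", 1)]
        with pytest.raises(ValidationError):
            train(data)

    def test_wrong_length_rejected(self, small_model):
        with pytest.raises(ValidationError):
            small_model.predict_proba("A" * 16)

    def test_save_load_round_trip(self, tmp_path, small_model):
        p = tmp_path / "model.joblib"
        small_model.save(p)
        from dolphyn.classifier import EpitopeModel

        loaded = EpitopeModel.load(p)
        seq = "K" * 8 + "A" * 7
        assert loaded.predict_proba(seq) == small_model.predict_proba(seq)


class TestScoreLongPeptide:
    def test_single_window_identity(self, small_model):
        seq = "KRHKRAAAAAAAAAA"
        assert score_long_peptide(small_model, seq) == pytest.approx(
            small_model.predict_proba(seq))

    def test_mean_over_42_windows_for_56mer(self, small_model):
        rng = np.random.default_rng(0)
        seq = synthetic._random_seq(rng, 56)
        windows = [seq[i : i + 15] for i in range(42)]
        expected = float(np.mean(small_model.predict_proba_many(windows)))
        assert score_long_peptide(small_model, seq) == pytest.approx(expected)

    def test_constant_stub_model(self):
        class Stub:
            peptide_length = 15

            def predict_proba_many(self, seqs):
                return np.full(len(seqs), 0.3)

        for L in (15, 30, 56):
            assert score_long_peptide(Stub(), "A" * L) == pytest.approx(0.3)

    def test_too_short_rejected(self, small_model):
        with pytest.raises(ValidationError):
            score_long_peptide(small_model, "A" * 14)
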