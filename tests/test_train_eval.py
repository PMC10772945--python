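"""Training loop, AUC, and the cross-validation harnesses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanoselect as ns
from nanoselect.errors import DatasetImbalanceError, InvalidArgumentError
from nanoselect.train_eval import evaluate_scores, stratified_fold_assignments

from conftest import make_separable_dataset


def auc_by_pair_enumeration(scores, labels):
    """Independent oracle: count correctly ordered positive-negative pairs,
    ties worth one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_worked_example(self):
        # 3 of the 4 positive-negative pairs correctly ordered
        assert ns.auc_mann_whitney([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert ns.auc_mann_whitney([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert ns.auc_mann_whitney([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ns.auc_mann_whitney([0.1, 0.2], [1, 1])

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_equals_pair_enumeration(self, data):
        n = data.draw(st.integers(4, 25))
        labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        # coarse grid scores so ties actually occur
        scores = np.array(data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))) / 5.0
        assert ns.auc_mann_whitney(scores, labels) == pytest.approx(
            auc_by_pair_enumeration(scores, labels), abs=1e-12
        )

    def test_equals_trapezoid_roc_area(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(6, 40)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = rng.choice(np.linspace(0, 1, 7), n)  # with ties
            report = evaluate_scores(scores, labels)
            assert ns.auc_mann_whitney(scores, labels) == pytest.approx(report.auc, abs=1e-9)


class TestEvalReport:
    def test_roc_monotone_and_anchored(self):
        rng = np.random.default_rng(1)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        rep = evaluate_scores(scores, labels)
        pts = rep.roc_points
        assert np.array_equal(pts[0], [0, 0]) and np.array_equal(pts[-1], [1, 1])
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_confusion_and_precision(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2, 0.7, 0.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        rep = evaluate_scores(scores, labels)
        # predicted target: 0.9, 0.8, 0.7; of those two are true targets
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.confusion.tolist() == [[2, 1], [1, 2]]
        assert rep.accuracy == pytest.approx(4 / 6)

    def test_per_species_recall(self):
        scores = np.array([0.9, 0.1, 0.8, 0.2])
        labels = np.array([1, 0, 1, 0])
        species = ["a", "human", "b", "human"]
        rep = evaluate_scores(scores, labels, species=species)
        assert rep.per_species_recall == {"a": 1.0, "b": 1.0, "human": 1.0}


class TestStratifiedFolds:
    @given(
        n0=st.integers(5, 60),
        n1=st.integers(5, 60),
        k=st.integers(2, 7),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_partition_laws(self, n0, n1, k, seed):
        if min(n0, n1) < k:
            return
        labels = np.array([0] * n0 + [1] * n1)
        folds = stratified_fold_assignments(labels, k, seed)
        # disjoint and covering by construction of the assignment vector
        assert folds.min() >= 0 and folds.max() < k
        sizes = np.bincount(folds, minlength=k)
        assert sizes.max() - sizes.min() <= 1  # balanced overall
        for cls in (0, 1):
            cls_sizes = np.bincount(folds[labels == cls], minlength=k)
            assert cls_sizes.max() - cls_sizes.min() <= 1  # stratified

    def test_deterministic(self):
        labels = np.array([0, 1] * 50)
        a = stratified_fold_assignments(labels, 5, seed=3)
        b = stratified_fold_assignments(labels, 5, seed=3)
        assert np.array_equal(a, b)


class TestTrain:
    def test_loss_decreases_on_separable_data(self, tiny_spec):
        ds = make_separable_dataset(100, length=300, seed=0)
        model = ns.train(tiny_spec, ds, ns.TrainConfig(epochs=2, batch_size=32, seed=0))
        assert model.history["loss"][-1] < model.history["loss"][0]

    def test_same_seed_reproduces_final_loss(self, tiny_spec):
        ds = make_separable_dataset(30, length=300, seed=1)
        cfg = ns.TrainConfig(epochs=1, batch_size=16, seed=5)
        a = ns.train(tiny_spec, ds, cfg)
        b = ns.train(tiny_spec, ds, cfg)
        assert abs(a.training_meta["final_loss"] - b.training_meta["final_loss"]) < 1e-6

    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_spec):
        ds = make_separable_dataset(16, length=300, seed=2)
        init = ns.SquiggleClassifier(tiny_spec, seed=7)
        before = [p.value.copy() for p in init.params()]
        model = ns.train(tiny_spec, ds, ns.TrainConfig(epochs=1, batch_size=8, learning_rate=0.0, seed=7))
        for p, b in zip(model.params(), before):
            assert np.array_equal(p.value, b)

    def test_single_class_rejected(self, tiny_spec):
        ds = make_separable_dataset(10, length=300, seed=3)
        host_only = ds.subset(np.flatnonzero(ds.y == 0))
        with pytest.raises(DatasetImbalanceError):
            ns.train(tiny_spec, host_only, ns.TrainConfig(epochs=1))


class TestKFold:
    def test_every_chunk_validated_exactly_once(self, tiny_spec):
        ds = make_separable_dataset(50, length=300, seed=4)  # 100 chunks
        seen = []

        def oracle(train_set, val_set):
            seen.extend(val_set.read_ids)
            return val_set.y.astype(float)

        reports, plan = ns.kfold_cv(ds, k=5, cfg=ns.TrainConfig(seed=0), score_fn=oracle)
        assert sorted(seen) == sorted(ds.read_ids)  # union = all, disjoint
        assert len(seen) == len(set(seen))
        assert all(len(r.roc_points) for r in reports)
        sizes = [sum(1 for f in plan.assignments.values() if f == i) for i in range(5)]
        assert sizes == [20] * 5

    def test_oracle_scores_give_unit_auc(self):
        ds = make_separable_dataset(25, length=300, seed=5)
        reports, _ = ns.kfold_cv(ds, k=5, score_fn=lambda tr, va: va.y.astype(float))
        assert all(r.auc == 1.0 for r in reports)

    def test_too_few_chunks_rejected(self, tiny_spec):
        ds = make_separable_dataset(3, length=300, seed=6)
        with pytest.raises(InvalidArgumentError):
            ns.kfold_cv(ds, k=5, score_fn=lambda tr, va: va.y.astype(float))

    def test_fold_assignments_deterministic(self):
        ds = make_separable_dataset(20, length=300, seed=7)
        _, plan_a = ns.kfold_cv(ds, k=4, cfg=ns.TrainConfig(seed=9), score_fn=lambda tr, va: va.y.astype(float))
        _, plan_b = ns.kfold_cv(ds, k=4, cfg=ns.TrainConfig(seed=9), score_fn=lambda tr, va: va.y.astype(float))
        assert plan_a.assignments == plan_b.assignments

    def test_kfold_learns_on_separable_data(self, tiny_spec):
        # end-to-end: tiny model, 2 folds, real training
        ds = make_separable_dataset(60, length=300, seed=8)
        reports, _ = ns.kfold_cv(
            ds, k=2, spec=tiny_spec, cfg=ns.TrainConfig(epochs=10, batch_size=8, seed=0)
        )
        assert np.mean([r.auc for r in reports]) > 0.9


class TestLeaveOneSpeciesOut:
    @staticmethod
    def _multispecies_dataset(n_per_species=30, n_species=3, length=300, seed=0, twin=False):
        """Host chunks vs several microbial species; species differ by wave
        frequency unless twin=True (then all species are identical)."""
        rng = np.random.default_rng(seed)
        X, y, species = [], [], []
        n_host = n_per_species * n_species
        X.append(rng.standard_normal((n_host, length)))
        y += [0] * n_host
        species += ["human"] * n_host
        for s in range(n_species):
            freq = 10 if twin else 8 + 2 * s
            wave = np.sin(np.linspace(0, freq * np.pi, length))
            X.append(rng.standard_normal((n_per_species, length)) + 2.0 * wave)
            y += [1] * n_per_species
            species += [f"microbe_{s}"] * n_per_species
        X = np.vstack(X).astype(np.float32)
        y = np.array(y)
        order = rng.permutation(len(y))
        return ns.ChunkDataset(
            X=X[order],
            y=y[order],
            read_ids=[f"r{i}" for i in order],
            species=[species[i] for i in order],
        )

    def test_one_report_per_species_each_excluding_its_own(self):
        ds = self._multispecies_dataset()
        trained_species = {}

        def oracle(train_set, val_set):
            key = sorted(set(s for s, lab in zip(val_set.species, val_set.y) if lab == 1))[0]
            trained_species[key] = set(train_set.species)
            return val_set.y.astype(float)

        reports, plan = ns.leave_one_species_out_cv(ds, score_fn=oracle)
        assert sorted(reports) == ["microbe_0", "microbe_1", "microbe_2"]
        for sp, seen in trained_species.items():
            assert sp not in seen  # held-out species absent from training
            assert "human" in seen

    def test_evaluation_mixes_unseen_host_chunks(self):
        ds = self._multispecies_dataset()
        def oracle(train_set, val_set):
            counts = {0: int((val_set.y == 0).sum()), 1: int((val_set.y == 1).sum())}
            assert counts[0] == counts[1]  # equal-sized host sample
            assert not (set(val_set.read_ids) & set(train_set.read_ids))
            return val_set.y.astype(float)

        ns.leave_one_species_out_cv(ds, score_fn=oracle)

    def test_unknown_species_skipped_with_warning(self):
        ds = self._multispecies_dataset()
        with pytest.warns(UserWarning, match="zero chunks"):
            reports, _ = ns.leave_one_species_out_cv(
                ds,
                species=["microbe_0", "microbe_1", "ghost"],
                score_fn=lambda tr, va: va.y.astype(float),
            )
        assert sorted(reports) == ["microbe_0", "microbe_1"]

    def test_twin_species_generalize(self, tiny_spec):
        # a held-out species identical in composition to a trained one is
        # classified about as well as in-training data
        ds = self._multispecies_dataset(n_per_species=40, n_species=2, seed=1, twin=True)
        cfg = ns.TrainConfig(epochs=3, batch_size=16, seed=0)
        reports, _ = ns.leave_one_species_out_cv(ds, spec=tiny_spec, cfg=cfg)
        for rep in reports.values():
            assert rep.auc > 0.9

    def test_mislabelled_host_control_is_chance_level(self, tiny_spec):
        # a "species" actually drawn from the host pool scores near AUC 0.5
        ds = self._multispecies_dataset(n_per_species=40, n_species=2, seed=2)
        rng = np.random.default_rng(3)
        imposter = rng.standard_normal((40, 300)).astype(np.float32)  # host-like
        X = np.vstack([ds.X, imposter])
        y = np.concatenate([ds.y, np.ones(40, int)])
        species = ds.species + ["imposter"] * 40
        read_ids = ds.read_ids + [f"imp{i}" for i in range(40)]
        ds2 = ns.ChunkDataset(X=X, y=y, read_ids=read_ids, species=species)
        cfg = ns.TrainConfig(epochs=3, batch_size=16, seed=0)
        reports, _ = ns.leave_one_species_out_cv(
            ds2, spec=tiny_spec, cfg=cfg, species=["imposter"]
        )
        assert 0.3 < reports["imposter"].auc < 0.7
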