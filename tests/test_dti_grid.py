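import numpy as np
import pytest

from cholarray.fingerprints import FingerprintConfig, LabeledFingerprintSet
from cholarray.dti_grid import (
    ALGORITHMS,
    BaseModelGrid,
    BaseModelSpec,
    SplitSpec,
    StratificationError,
    cross_validate,
    ensemble_auc,
    ensemble_auc_table,
    make_grid_specs,
    select_best,
    split,
    train_grid,
    train_one,
)


def balanced_set(n=100, n_bits=64, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, n_bits)).astype(np.uint8)
    labels = np.arange(n) % 2
    if separable:
        X[:, 0] = labels  # one perfectly informative bit
    return LabeledFingerprintSet(
        compound_ids=[f"c{i}" for i in range(n)],
        bit_matrix=X,
        labels=labels.astype(np.uint8),
        config=FingerprintConfig(n_bits=n_bits),
    )


class TestSplit:
    def test_stratified_70_30_arithmetic(self):
        train, test = split(balanced_set(100), SplitSpec(seed=3))
        assert len(train) == 70 and len(test) == 30
        assert train.labels.sum() == 35 and test.labels.sum() == 15

    def test_same_seed_identical_partitions(self):
        ds = balanced_set(80)
        t1, e1 = split(ds, SplitSpec(seed=5))
        t2, e2 = split(ds, SplitSpec(seed=5))
        assert t1.compound_ids == t2.compound_ids
        assert e1.compound_ids == e2.compound_ids

    def test_disjoint_union(self):
        ds = balanced_set(90)
        train, test = split(ds, SplitSpec(seed=1))
        ids = set(train.compound_ids) | set(test.compound_ids)
        assert not set(train.compound_ids) & set(test.compound_ids)
        assert ids == set(ds.compound_ids)

    def test_single_positive_raises(self):
        ds = balanced_set(10)
        ds.labels = np.array([1] + [0] * 9, dtype=np.uint8)
        with pytest.raises(StratificationError):
            split(ds, SplitSpec(seed=0))

    def test_split_spec_validation(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)
        with pytest.raises(ValueError):
            SplitSpec(cv_folds=1)


class TestCrossValidate:
    def test_each_sample_validated_once(self):
        # fold bookkeeping mirrors StratifiedKFold: k folds of size n/k
        ds = balanced_set(100)
        spec = BaseModelSpec(target="AChE", algorithm="DT", seed=1)
        summary = cross_validate(spec, ds, k=10)
        assert summary.k == 10
        assert summary.degenerate_folds == 0

    def test_k_larger_than_n_raises(self):
        ds = balanced_set(8)
        spec = BaseModelSpec(target="AChE", algorithm="DT", seed=1)
        with pytest.raises(ValueError):
            cross_validate(spec, ds, k=20)

    def test_separable_data_near_perfect(self):
        ds = balanced_set(100, separable=True)
        spec = BaseModelSpec(target="AChE", algorithm="DT", seed=1)
        summary = cross_validate(spec, ds, k=5)
        assert summary.mean["accuracy"] == pytest.approx(1.0, abs=0.02)

    def test_mean_sd_reported_for_all_metrics(self):
        ds = balanced_set(60)
        spec = BaseModelSpec(target="AChE", algorithm="KNN", seed=2)
        summary = cross_validate(spec, ds, k=3)
        assert set(summary.mean) == set(summary.sd)
        assert summary.mean["auc_roc"] is not None


class TestTrainGrid:
    def test_grid_size_is_cross_product(self, dti_fixture):
        specs = make_grid_specs(("AChE", "BuChE"), algorithms=("DT", "KNN"),
                                seeds=(1, 2, 3))
        assert len(specs) == 2 * 2 * 3
        models = train_grid(
            {t: dti_fixture.datasets[t] for t in ("AChE", "BuChE")}, specs
        )
        assert len(models) == len(specs)

    def test_default_spec_count_is_200(self):
        specs = make_grid_specs(("T1", "T2", "T3", "T4", "T5"))
        assert len(specs) == 200

    def test_one_target_one_algorithm_three_seeds(self, dti_fixture):
        specs = make_grid_specs(("AChE",), algorithms=("DT",), seeds=(1, 2, 3))
        models = train_grid({"AChE": dti_fixture.datasets["AChE"]}, specs)
        assert len(models) == 3

    def test_missing_target_dataset_raises(self, dti_fixture):
        specs = make_grid_specs(("AChE", "VAChT"), algorithms=("DT",), seeds=(1,))
        with pytest.raises(ValueError, match="VAChT"):
            train_grid({"AChE": dti_fixture.datasets["AChE"]}, specs)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_score_contract_in_unit_interval(self, algorithm):
        ds = balanced_set(60)
        model = train_one(
            BaseModelSpec(target="AChE", algorithm=algorithm, seed=1), ds
        )
        scores = model.score(ds.bit_matrix)
        assert scores.shape == (60,)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_planted_signal_rf_high_auc(self):
        ds = balanced_set(300, seed=4)
        model = train_one(BaseModelSpec(target="AChE", algorithm="RF", seed=1), ds)
        assert model.test_report.auc_roc > 0.9

    def test_deterministic_reruns(self):
        ds = balanced_set(120, seed=9, separable=False)
        for algorithm in ("DT", "KNN", "RF"):
            spec = BaseModelSpec(target="AChE", algorithm=algorithm, seed=3)
            m1 = train_one(spec, ds)
            m2 = train_one(spec, ds)
            assert m1.test_report.as_dict() == m2.test_report.as_dict()

    def test_test_metrics_on_heldout_30(self):
        ds = balanced_set(100)
        model = train_one(BaseModelSpec(target="AChE", algorithm="DT", seed=1), ds)
        assert model.test_report.counts.n == 30
        assert model.train_report.counts.n == 70


class TestEnsembleAuc:
    def _grid_models(self, n_seeds=4, seed0=0):
        ds = balanced_set(150, seed=8)
        return [
            train_one(BaseModelSpec(target="AChE", algorithm="DT", seed=s), ds)
            for s in range(seed0 + 1, seed0 + 1 + n_seeds)
        ]

    def test_mean_of_seed_aucs(self):
        models = self._grid_models()
        expected = np.mean([m.test_report.auc_roc for m in models])
        assert ensemble_auc(models) == pytest.approx(expected)

    def test_two_known_aucs_average(self):
        models = self._grid_models(n_seeds=2)
        models[0].test_report.auc_roc = 0.9
        models[1].test_report.auc_roc = 0.8
        assert ensemble_auc(models) == pytest.approx(0.85)

    def test_within_min_max_of_members(self, rng):
        models = self._grid_models(n_seeds=5)
        aucs = [m.test_report.auc_roc for m in models]
        value = ensemble_auc(models)
        assert min(aucs) <= value <= max(aucs)

    def test_single_model_warns_and_reduces(self):
        models = self._grid_models(n_seeds=1)
        with pytest.warns(UserWarning):
            value = ensemble_auc(models)
        assert value == pytest.approx(models[0].test_report.auc_roc)

    def test_mixed_cells_rejected(self):
        ds = balanced_set(80)
        m1 = train_one(BaseModelSpec(target="AChE", algorithm="DT", seed=1), ds)
        m2 = train_one(BaseModelSpec(target="AChE", algorithm="KNN", seed=1), ds)
        with pytest.raises(ValueError):
            ensemble_auc([m1, m2])

    def test_avg_prob_definition(self):
        models = self._grid_models(n_seeds=3)
        ds = balanced_set(50, seed=11)
        value = ensemble_auc(models, method="avg_prob",
                             eval_X=ds.bit_matrix, eval_labels=ds.labels)
        assert 0 <= value <= 1


class TestSelectBest:
    def test_single_candidate_selected(self, dti_fixture):
        specs = make_grid_specs(("AChE",), algorithms=("DT",), seeds=(1,))
        models = train_grid({"AChE": dti_fixture.datasets["AChE"]}, specs)
        best = select_best(models)
        assert best["AChE"].spec.key == ("AChE", "DT", 1)

    def test_matches_brute_force_scan(self, dti_fixture):
        targets = ("AChE", "BuChE")
        specs = make_grid_specs(targets, algorithms=("DT", "KNN"), seeds=(1, 2))
        models = train_grid(
            {t: dti_fixture.datasets[t] for t in targets}, specs
        )
        best = select_best(models)
        table = ensemble_auc_table(models)
        for target in targets:
            # oracle: max ensemble-AUC algorithm, then max (auc, mcc, -seed)
            best_algo = max(
                (a for (t, a) in table if t == target),
                key=lambda a: table[(target, a)],
            )
            pool = [m for m in models
                    if m.spec.target == target and m.spec.algorithm == best_algo]
            oracle = max(pool, key=lambda m: (m.test_report.auc_roc,
                                              m.test_report.mcc, -m.spec.seed))
            assert best[target].spec.key == oracle.spec.key

    def test_tie_broken_by_mcc(self):
        ds = balanced_set(100, seed=5)
        m1 = train_one(BaseModelSpec(target="AChE", algorithm="DT", seed=1), ds)
        m2 = train_one(BaseModelSpec(target="AChE", algorithm="DT", seed=2), ds)
        m1.test_report.auc_roc = m2.test_report.auc_roc = 0.9
        m1.test_report.mcc = 0.5
        m2.test_report.mcc = 0.7
        best = select_best([m1, m2])
        assert best["AChE"].spec.seed == 2


class TestBaseModelGrid:
    def test_slot_order_target_seed_algorithm(self, small_grid):
        keys = small_grid.slot_keys()
        assert len(keys) == len(small_grid)
        # fast axis: algorithm cycles first
        algs = [k[1] for k in keys[: len(small_grid.algorithms)]]
        assert algs == list(small_grid.algorithms)
        for i, key in enumerate(keys):
            assert small_grid.slot_index(key[0], key[1], key[2]) == i

    def test_incomplete_grid_rejected(self, dti_fixture):
        targets = ("AChE", "BuChE")
        specs = make_grid_specs(targets, algorithms=("DT",), seeds=(1, 2))
        models = train_grid(
            {t: dti_fixture.datasets[t] for t in targets}, specs
        )
        with pytest.raises(ValueError, match="incomplete"):
            BaseModelGrid(models[:3])  # 3 models for a 2x1x2 grid
        with pytest.raises(ValueError, match="duplicate"):
            BaseModelGrid(models + models)

    def test_roundtrip_persistence(self, small_grid, tmp_path):
        small_grid.save(tmp_path / "grid")
        loaded = BaseModelGrid.load(tmp_path / "grid")
        assert loaded.slot_keys() == small_grid.slot_keys()
        assert loaded.fingerprint_config == small_grid.fingerprint_config
        key = small_grid.slot_keys()[0]
        X = np.zeros((3, 1024), dtype=np.uint8)
        assert np.allclose(loaded[key].score(X), small_grid[key].score(X))
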