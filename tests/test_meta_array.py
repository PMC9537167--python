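import numpy as np
import pytest

from cholarray import synthetic_data as sd
from cholarray.meta_array import (
    VALID_SHAPES,
    ArrayDataset,
    MetaArray,
    apply_sampling,
    dedup_arrays,
    flatten,
    load_dataset,
    predict_meta,
    reshape,
    save_dataset,
    smote_oversample,
)


def make_array(values, cid="c0", **kw):
    return MetaArray(compound_id=cid, values=np.asarray(values, dtype=float), **kw)


def make_dataset(matrix, labels, **kw):
    arrays = [make_array(row, cid=f"c{i}") for i, row in enumerate(matrix)]
    return ArrayDataset(arrays=arrays, class_labels=list(labels), **kw)


class TestMetaArray:
    def test_shape_must_hold_all_slots(self):
        with pytest.raises(ValueError):
            make_array(np.zeros(200), shape=(7, 7))

    def test_canonical_shapes_accepted(self):
        for shape in VALID_SHAPES:
            arr = make_array(np.zeros(200), shape=shape)
            assert arr.as_array().shape == shape

    def test_bad_encoding_rejected(self):
        with pytest.raises(ValueError):
            make_array(np.zeros(200), encoding="onehot")


class TestReshape:
    def test_roundtrip_through_3d(self, rng):
        values = rng.random(200)
        arr = make_array(values, shape=(50, 4))
        back = flatten(reshape(reshape(arr, (10, 5, 4)), (50, 4)))
        assert np.array_equal(back.values, values)

    def test_row_major_index_arithmetic(self, rng):
        # oracle: element (0, 4) of [40x5] = flat index 4 = element (1, 0) of [50x4]
        values = rng.random(200)
        a50 = make_array(values, shape=(50, 4)).as_array()
        a40 = reshape(make_array(values, shape=(50, 4)), (40, 5)).as_array()
        assert a40[0, 4] == a50[1, 0]
        # exhaustive index oracle over every slot
        for flat_idx in range(200):
            r50, c50 = divmod(flat_idx, 4)
            r40, c40 = divmod(flat_idx, 5)
            assert a50[r50, c50] == a40[r40, c40]

    def test_dim_product_mismatch_raises(self, rng):
        arr = make_array(rng.random(200))
        with pytest.raises(ValueError):
            reshape(arr, (7, 7))

    def test_reshape_lossless_over_all_shapes(self, rng):
        for shape in VALID_SHAPES:
            values = rng.random(200)
            arr = reshape(make_array(values), shape)
            assert np.array_equal(flatten(arr).values, values)
            assert np.array_equal(arr.as_array().ravel(), values)  # row-major


class TestPredictMeta:
    def test_one_array_per_compound(self, small_grid, rng):
        X = rng.integers(0, 2, size=(33, 1024)).astype(np.uint8)
        arrays = predict_meta(small_grid, [f"m{i}" for i in range(33)], X=X)
        assert len(arrays) == 33
        assert all(a.values.size == len(small_grid) for a in arrays)

    def test_binary_encoding_thresholds_at_half(self, small_grid, rng):
        X = rng.integers(0, 2, size=(5, 1024)).astype(np.uint8)
        ids = [f"m{i}" for i in range(5)]
        binary = predict_meta(small_grid, ids, X=X, encoding="binary01")
        proba = predict_meta(small_grid, ids, X=X, encoding="probability")
        for b, p in zip(binary, proba):
            assert np.array_equal(b.values, (p.values >= 0.5).astype(float))

    def test_binary12_is_affine_shift(self, small_grid, rng):
        X = rng.integers(0, 2, size=(4, 1024)).astype(np.uint8)
        ids = [f"m{i}" for i in range(4)]
        b01 = predict_meta(small_grid, ids, X=X, encoding="binary01")
        b12 = predict_meta(small_grid, ids, X=X, encoding="binary12")
        for a, b in zip(b01, b12):
            assert np.array_equal(b.values, a.values + 1.0)
            assert set(np.unique(b.values)) <= {1.0, 2.0}

    def test_planted_activity_fills_target_block(self, small_grid, dti_fixture):
        # compound active on AChE only: AChE-block slots majority-active
        spec = sd.SyntheticSpec(n_per_target=150, seed=7)
        rng = np.random.default_rng(0)
        X = (rng.random((1, 1024)) < 0.05).astype(np.uint8)
        X[0, dti_fixture.planted_bits["AChE"]] = 1
        X[0, dti_fixture.planted_bits["BuChE"]] = 0
        arrays = predict_meta(small_grid, ["probe"], X=X)
        values = arrays[0].values
        n_alg, n_seed = len(small_grid.algorithms), len(small_grid.seeds)
        block = n_alg * n_seed
        t_idx = {t: i for i, t in enumerate(small_grid.targets)}
        ache = values[t_idx["AChE"] * block : (t_idx["AChE"] + 1) * block]
        buche = values[t_idx["BuChE"] * block : (t_idx["BuChE"] + 1) * block]
        assert ache.mean() > 0.5
        assert buche.mean() < 0.5

    def test_feature_width_mismatch_raises(self, small_grid):
        with pytest.raises(ValueError, match="n_bits"):
            predict_meta(small_grid, ["m0"], X=np.zeros((1, 512)))

    def test_fingerprint_config_mismatch_raises(self, small_grid):
        from cholarray.fingerprints import FingerprintConfig

        with pytest.raises(ValueError, match="mismatch"):
            predict_meta(
                small_grid, ["m0"], X=np.zeros((1, 1024)),
                fingerprint_config=FingerprintConfig(family="FCFP"),
            )


class TestDedupArrays:
    def test_duplicate_same_label_dropped(self):
        row = np.zeros(200)
        ds = make_dataset([row, row, np.ones(200)],
                          ["nonCWA", "nonCWA", "CWA"])
        out = dedup_arrays(ds)
        assert len(out) == 2
        assert out.sampling_model == "Model02"
        assert out.arrays[0].compound_id == "c0"

    def test_label_collision_kept_and_flagged(self):
        row = np.zeros(200)
        ds = make_dataset([row, row], ["CWA", "nonCWA"])
        out = dedup_arrays(ds)
        assert len(out) == 2
        assert out.collisions

    def test_all_distinct_unchanged(self, rng):
        ds = make_dataset(rng.random((10, 200)), ["nonCWA"] * 9 + ["CWA"])
        assert len(dedup_arrays(ds)) == 10

    def test_idempotent(self, rng):
        M = rng.integers(0, 2, size=(20, 200)).astype(float)
        M[5] = M[3]
        M[7] = M[3]
        labels = ["nonCWA"] * 15 + ["CWA"] * 5
        once = dedup_arrays(make_dataset(M, labels))
        twice = dedup_arrays(once)
        assert [a.compound_id for a in once.arrays] == [
            a.compound_id for a in twice.arrays
        ]

    def test_subset_of_input(self, rng):
        M = rng.integers(0, 2, size=(15, 200)).astype(float)
        M[4] = M[1]
        ds = make_dataset(M, ["nonCWA"] * 12 + ["CWA"] * 3)
        out = dedup_arrays(ds)
        in_ids = {a.compound_id for a in ds.arrays}
        assert {a.compound_id for a in out.arrays} <= in_ids


class TestSmote:
    def _imbalanced(self, rng, n_min=10, n_maj=90):
        M = np.vstack([
            rng.random((n_min, 200)) * 0.3 + 0.7,  # minority cluster
            rng.random((n_maj, 200)) * 0.3,
        ])
        labels = ["CWA"] * n_min + ["nonCWA"] * n_maj
        return make_dataset(M, labels)

    def test_exact_balance(self, rng):
        out = smote_oversample(self._imbalanced(rng), seed=1)
        counts = out.class_counts()
        assert counts["CWA"] == counts["nonCWA"] == 90

    def test_synthetics_flagged_and_convex(self, rng):
        ds = self._imbalanced(rng)
        out = smote_oversample(ds, seed=2)
        Xmin = ds.matrix[ds.y == 1]
        lo, hi = Xmin.min(axis=0), Xmin.max(axis=0)
        synth = out.matrix[out.synthetic_mask]
        assert len(synth) == 80
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()
        assert all(a.encoding == "probability"
                   for a, s in zip(out.arrays, out.synthetic_mask) if s)

    def test_identical_minority_points_degenerate(self, rng):
        M = np.vstack([np.tile(np.full(200, 0.5), (7, 1)), rng.random((20, 200))])
        ds = make_dataset(M, ["CWA"] * 7 + ["nonCWA"] * 20)
        out = smote_oversample(ds, k_neighbors=5, seed=0)
        synth = out.matrix[out.synthetic_mask]
        assert np.allclose(synth, 0.5)

    def test_minority_too_small_raises(self, rng):
        ds = self._imbalanced(rng, n_min=4, n_maj=20)
        with pytest.raises(ValueError, match="at least 6"):
            smote_oversample(ds, k_neighbors=5)

    def test_reproducible_from_seed(self, rng):
        ds = self._imbalanced(rng)
        a = smote_oversample(ds, seed=42)
        b = smote_oversample(ds, seed=42)
        assert np.array_equal(a.matrix, b.matrix)

    def test_balanced_input_returned_unchanged(self, rng):
        M = rng.random((20, 200))
        ds = make_dataset(M, ["CWA"] * 10 + ["nonCWA"] * 10)
        assert smote_oversample(ds, seed=0) is ds


class TestSamplingRegimes:
    def test_model_counts_contract(self, rng):
        M = rng.integers(0, 2, size=(120, 200)).astype(float)
        M[10:30] = M[0]  # force duplicates in the majority class
        labels = ["CWA"] * 12 + ["nonCWA"] * 108
        ds = make_dataset(M, labels)
        m01 = apply_sampling(ds, "model01")
        m02 = apply_sampling(ds, "model02")
        m03 = apply_sampling(ds, "model03", seed=3)
        m04 = apply_sampling(ds, "model04", seed=3)
        maj01 = max(m01.class_counts().values())
        maj02 = max(m02.class_counts().values())
        assert len(m01) == 120
        assert len(m02) <= len(m01)
        assert len(m03) == 2 * maj01
        assert len(m04) == 2 * maj02
        assert m03.sampling_model == "Model03"
        assert m04.sampling_model == "Model04"

    def test_unknown_model_rejected(self, rng):
        ds = make_dataset(rng.random((4, 200)), ["CWA", "nonCWA"] * 2)
        with pytest.raises(ValueError):
            apply_sampling(ds, "model05")


class TestPersistence:
    def test_roundtrip(self, tmp_path, rng):
        M = rng.random((12, 200))
        ds = make_dataset(M, ["CWA"] * 3 + ["nonCWA"] * 9)
        path = tmp_path / "arrays.tsv"
        save_dataset(ds, path)
        loaded = load_dataset(path)
        assert np.array_equal(loaded.matrix, ds.matrix)
        assert loaded.class_labels == ds.class_labels
        assert not loaded.synthetic_mask.any()

    def test_slot_order_version_pinned(self, tmp_path, rng, small_grid):
        ds = make_dataset(rng.random((4, 200)), ["CWA"] * 2 + ["nonCWA"] * 2)
        path = tmp_path / "arrays.tsv"
        save_dataset(ds, path, grid_manifest=small_grid.manifest())
        manifest_file = path.with_suffix(".tsv.manifest.json")
        text = manifest_file.read_text()
        assert "slot_order_hash" in text
        manifest_file.write_text(
            text.replace("target-seed-algorithm/v1", "bogus/v0")
        )
        with pytest.raises(ValueError, match="slot order"):
            load_dataset(path)
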