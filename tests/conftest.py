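import warnings

import numpy as np
import pytest

from cholarray import FingerprintConfig
from cholarray import dti_grid as dg
from cholarray import meta_array as ma
from cholarray import synthetic_data as sd

warnings.filterwarnings("ignore", category=FutureWarning)


# ---------------------------------------------------------------- oracles
def oracle_confusion(y_true, y_pred) -> dict:
    """Brute-force recount of prediction outcomes."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def oracle_roc_auc(scores, labels) -> float:
    """Exhaustive pair counting; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_average_precision(scores, labels) -> float:
    """Step-wise AP: sum of (recall increment) x precision, computed by
    walking descending unique thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def fp_config() -> FingerprintConfig:
    return FingerprintConfig()


@pytest.fixture(scope="session")
def tiny_compounds():
    return sd.gen_tiny_smiles_set(seed=0)


@pytest.fixture(scope="session")
def dti_fixture():
    """Small planted-signal DTI fixture shared across tests."""
    return sd.gen_dti_dataset(sd.SyntheticSpec(n_per_target=150, seed=7))


@pytest.fixture(scope="session")
def small_grid(dti_fixture):
    """2-target x 4-algorithm x 2-seed trained grid (fast)."""
    targets = ("AChE", "BuChE")
    datasets = {t: dti_fixture.datasets[t] for t in targets}
    specs = dg.make_grid_specs(
        targets, seeds=(1, 2), fingerprint=FingerprintConfig(n_bits=1024)
    )
    return dg.BaseModelGrid(dg.train_grid(datasets, specs))


@pytest.fixture(scope="session")
def meta_dataset(small_grid, dti_fixture):
    """Array dataset predicted by the small grid on synthetic compounds."""
    spec = sd.SyntheticSpec(n_per_target=150, n_meta=200, seed=7)
    meta = sd.gen_meta_stage(spec, dti_fixture)
    arrays = ma.predict_meta(small_grid, meta.compound_ids, X=meta.X)
    return ma.ArrayDataset(arrays=arrays, class_labels=meta.class_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
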