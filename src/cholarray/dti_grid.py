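"""The 5-target x 4-algorithm x 10-seed grid of binary DTI classifiers.

Each spec trains one binary classifier on the fingerprints of one target.
The seed controls the 70:30 train/test division and any stochastic
learner internals. All four algorithms expose a continuous score in
[0, 1] (positive-class probability) so that ranking metrics and the meta
stage can consume any of them uniformly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from cholarray.fingerprints import FingerprintConfig, LabeledFingerprintSet
from cholarray.metrics import EvalReport, evaluate_scores

logger = logging.getLogger(__name__)

ALGORITHMS = ("RF", "DT", "SVM", "KNN")
DEFAULT_SEEDS = tuple(range(1, 11))  # S1 .. S10


def make_estimator(algorithm: str, seed: int, hyperparameters: dict | None = None):
    """A fresh sklearn estimator honoring the probability-score contract."""
    params = dict(hyperparameters or {})
    if algorithm == "RF":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm == "SVM":
        params.setdefault("kernel", "rbf")
        cv = params.pop("calibration_cv", 3)
        # sigmoid (Platt) calibration supplies the predict_proba contract
        return CalibratedClassifierCV(
            SVC(random_state=seed, **params),
            method="sigmoid",
            cv=cv,
            ensemble=False,
        )
    if algorithm == "KNN":
        params.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass(frozen=True)
class BaseModelSpec:
    target: str
    algorithm: str
    seed: int
    fingerprint: FingerprintConfig = FingerprintConfig()
    hyperparameters: tuple = ()  # sorted (key, value) pairs; dict-able

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.target, self.algorithm, self.seed)

    def hyperparams_dict(self) -> dict:
        return dict(self.hyperparameters)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 1
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class CVSummary:
    """Mean +/- sd of each metric over the k folds."""

    k: int
    mean: dict[str, float | None]
    sd: dict[str, float | None]
    degenerate_folds: int = 0


@dataclass
class TrainedBaseModel:
    spec: BaseModelSpec
    model: object
    train_report: EvalReport
    test_report: EvalReport
    cv_summary: CVSummary | None = None
    test_scores: np.ndarray | None = None
    test_labels: np.ndarray | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability in [0, 1] for each row of X."""
        proba = self.model.predict_proba(X)
        pos_col = list(self.model.classes_).index(1)
        return proba[:, pos_col]


class StratificationError(ValueError):
    """A class has too few members to stratify."""


def split(
    dataset: LabeledFingerprintSet, spec: SplitSpec
) -> tuple[LabeledFingerprintSet, LabeledFingerprintSet]:
    """Stratified, seeded train/test division (default 70:30).

    The partitions are disjoint, their union is the input, and the same
    seed reproduces the same partition.
    """
    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present")
    if counts.min() < 2:
        raise StratificationError(
            f"class with {counts.min()} member(s) cannot be stratified"
        )
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
    )
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def cross_validate(
    spec: BaseModelSpec, train_set: LabeledFingerprintSet, k: int = 10
) -> CVSummary:
    """Stratified k-fold CV on the training portion.

    Every sample is validated exactly once. Folds whose validation split
    is single-class are still scored; metrics undefined there are skipped
    in the mean/sd and the fold is counted as degenerate.
    """
    n = len(train_set)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    counts = np.bincount(train_set.labels)
    if k > counts[counts > 0].min():
        raise ValueError("k exceeds the minority class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    fold_reports: list[EvalReport] = []
    degenerate = 0
    for fit_idx, val_idx in skf.split(train_set.bit_matrix, train_set.labels):
        est = make_estimator(spec.algorithm, spec.seed, spec.hyperparams_dict())
        est.fit(train_set.bit_matrix[fit_idx], train_set.labels[fit_idx])
        pos_col = list(est.classes_).index(1)
        scores = est.predict_proba(train_set.bit_matrix[val_idx])[:, pos_col]
        val_labels = train_set.labels[val_idx]
        if len(np.unique(val_labels)) < 2:
            degenerate += 1
        fold_reports.append(evaluate_scores(scores, val_labels))

    names = list(fold_reports[0].as_dict().keys())
    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    for name in names:
        vals = [r.as_dict()[name] for r in fold_reports]
        defined = [v for v in vals if v is not None]
        if defined:
            mean[name] = float(np.mean(defined))
            sd[name] = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        else:
            mean[name] = None
            sd[name] = None
    return CVSummary(k=k, mean=mean, sd=sd, degenerate_folds=degenerate)


def make_grid_specs(
    targets,
    algorithms=ALGORITHMS,
    seeds=DEFAULT_SEEDS,
    fingerprint: FingerprintConfig = FingerprintConfig(),
    hyperparameters: dict[str, dict] | None = None,
) -> list[BaseModelSpec]:
    """Full cross-product of specs: |targets| x |algorithms| x |seeds|."""
    hp = hyperparameters or {}
    return [
        BaseModelSpec(
            target=t,
            algorithm=a,
            seed=s,
            fingerprint=fingerprint,
            hyperparameters=tuple(sorted(hp.get(a, {}).items())),
        )
        for t in targets
        for a in algorithms
        for s in seeds
    ]


def train_one(
    spec: BaseModelSpec,
    dataset: LabeledFingerprintSet,
    split_spec: SplitSpec | None = None,
    run_cv: bool = False,
) -> TrainedBaseModel:
    """Train and validate a single grid entry.

    The seed of ``spec`` drives the 70:30 division; test metrics are
    computed only on the held-out 30%.
    """
    sspec = split_spec or SplitSpec(seed=spec.seed)
    if sspec.seed != spec.seed:
        sspec = SplitSpec(
            train_fraction=sspec.train_fraction,
            stratified=sspec.stratified,
            seed=spec.seed,
            cv_folds=sspec.cv_folds,
        )
    train_set, test_set = split(dataset, sspec)
    est = make_estimator(spec.algorithm, spec.seed, spec.hyperparams_dict())
    est.fit(train_set.bit_matrix, train_set.labels)
    pos_col = list(est.classes_).index(1)
    train_scores = est.predict_proba(train_set.bit_matrix)[:, pos_col]
    test_scores = est.predict_proba(test_set.bit_matrix)[:, pos_col]
    cv = cross_validate(spec, train_set, sspec.cv_folds) if run_cv else None
    return TrainedBaseModel(
        spec=spec,
        model=est,
        train_report=evaluate_scores(train_scores, train_set.labels),
        test_report=evaluate_scores(test_scores, test_set.labels),
        cv_summary=cv,
        test_scores=test_scores,
        test_labels=test_set.labels.copy(),
    )


def train_grid(
    datasets: dict[str, LabeledFingerprintSet],
    specs: list[BaseModelSpec],
    split_spec: SplitSpec | None = None,
    run_cv: bool = False,
) -> list[TrainedBaseModel]:
    """Train every spec; a failure aborts only that spec (logged)."""
    missing = {s.target for s in specs} - set(datasets)
    if missing:
        raise ValueError(f"no dataset for target(s): {sorted(missing)}")
    models: list[TrainedBaseModel] = []
    for spec in specs:
        try:
            models.append(train_one(spec, datasets[spec.target], split_spec, run_cv))
        except Exception:
            logger.exception("training failed for %s", spec.key)
    return models


def ensemble_auc(
    models: list[TrainedBaseModel],
    method: str = "mean_seed",
    eval_X: np.ndarray | None = None,
    eval_labels: np.ndarray | None = None,
) -> float:
    """Seed-aggregated AUC for models sharing (target, algorithm).

    ``mean_seed`` (default): mean of each model's own held-out ROC-AUC.
    ``avg_prob``: ROC-AUC of seed-averaged probabilities on a common
    evaluation set (requires eval_X / eval_labels).
    """
    if not models:
        raise ValueError("no models")
    keys = {(m.spec.target, m.spec.algorithm) for m in models}
    if len(keys) != 1:
        raise ValueError("models must share (target, algorithm)")
    if len(models) < 2:
        warnings.warn("fewer than 2 seeds: ensemble-AUC reduces to plain AUC")
    if method == "mean_seed":
        aucs = [m.test_report.auc_roc for m in models]
        if any(a is None for a in aucs):
            raise ValueError("a member model has undefined ROC-AUC")
        return float(np.mean(aucs))
    if method == "avg_prob":
        if eval_X is None or eval_labels is None:
            raise ValueError("avg_prob needs a common evaluation set")
        avg = np.mean([m.score(eval_X) for m in models], axis=0)
        from cholarray.metrics import roc_auc

        auc = roc_auc(avg, eval_labels)
        if auc is None:
            raise ValueError("single-class evaluation set")
        return auc
    raise ValueError(f"unknown method {method!r}")


def ensemble_auc_table(
    models: list[TrainedBaseModel], method: str = "mean_seed"
) -> dict[tuple[str, str], float]:
    """ensemble-AUC per (target, algorithm) cell of the grid."""
    cells: dict[tuple[str, str], list[TrainedBaseModel]] = {}
    for m in models:
        cells.setdefault((m.spec.target, m.spec.algorithm), []).append(m)
    return {key: ensemble_auc(group, method=method) for key, group in cells.items()}


def select_best(
    models: list[TrainedBaseModel], method: str = "mean_seed"
) -> dict[str, TrainedBaseModel]:
    """Best model per target by ensemble-AUC.

    The winning (target, algorithm) cell is the one with the highest
    ensemble-AUC; within it, the winning seed has the highest test
    ROC-AUC, ties broken by higher test MCC then lower seed index.
    """
    table = ensemble_auc_table(models, method=method)
    best: dict[str, TrainedBaseModel] = {}
    for target in sorted({t for t, _ in table}):
        algo = max(
            (a for t, a in table if t == target),
            key=lambda a: table[(target, a)],
        )
        candidates = [
            m for m in models if m.spec.target == target and m.spec.algorithm == algo
        ]
        best[target] = max(
            candidates,
            key=lambda m: (
                m.test_report.auc_roc if m.test_report.auc_roc is not None else -1,
                m.test_report.mcc if m.test_report.mcc is not None else -2,
                -m.spec.seed,
            ),
        )
    return best


class BaseModelGrid:
    """Container indexing trained models by (target, algorithm, seed).

    Defines the canonical slot order of the 200-slot meta array:
    slow axis = target, middle = seed, fast = algorithm.
    """

    def __init__(self, models: list[TrainedBaseModel]):
        self._by_key = {m.spec.key: m for m in models}
        if len(self._by_key) != len(models):
            raise ValueError("duplicate (target, algorithm, seed) keys")
        self.targets = tuple(dict.fromkeys(m.spec.target for m in models))
        self.algorithms = tuple(dict.fromkeys(m.spec.algorithm for m in models))
        self.seeds = tuple(sorted({m.spec.seed for m in models}))
        expected = len(self.targets) * len(self.algorithms) * len(self.seeds)
        if expected != len(models):
            raise ValueError(
                f"incomplete grid: {len(models)} models for a "
                f"{len(self.targets)}x{len(self.algorithms)}x{len(self.seeds)} grid"
            )
        configs = {m.spec.fingerprint for m in models}
        if len(configs) != 1:
            raise ValueError("grid mixes fingerprint configs")
        self.fingerprint_config = configs.pop()

    def __len__(self) -> int:
        return len(self._by_key)

    def __getitem__(self, key: tuple[str, str, int]) -> TrainedBaseModel:
        return self._by_key[key]

    @property
    def models(self) -> list[TrainedBaseModel]:
        return [self._by_key[k] for k in self.slot_keys()]

    def slot_keys(self) -> list[tuple[str, str, int]]:
        """Flat slot order: target (slow), seed (middle), algorithm (fast)."""
        return [
            (t, a, s)
            for t in self.targets
            for s in self.seeds
            for a in self.algorithms
        ]

    def slot_index(self, target: str, algorithm: str, seed: int) -> int:
        t = self.targets.index(target)
        s = self.seeds.index(seed)
        a = self.algorithms.index(algorithm)
        return (t * len(self.seeds) + s) * len(self.algorithms) + a

    def manifest(self) -> dict:
        return {
            "targets": list(self.targets),
            "algorithms": list(self.algorithms),
            "seeds": list(self.seeds),
            "fingerprint": {
                "family": self.fingerprint_config.family,
                "diameter": self.fingerprint_config.diameter,
                "n_bits": self.fingerprint_config.n_bits,
            },
            "slot_order": ["target", "seed", "algorithm"],
            "n_models": len(self),
        }

    def save(self, out_dir) -> None:
        """One file per model plus a JSON manifest with metrics."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest()
        manifest["models"] = []
        for key in self.slot_keys():
            m = self._by_key[key]
            fname = "model_{}_{}_s{}.joblib".format(*key)
            joblib.dump(m.model, out / fname)
            manifest["models"].append(
                {
                    "target": key[0],
                    "algorithm": key[1],
                    "seed": key[2],
                    "file": fname,
                    "test_metrics": m.test_report.as_dict(),
                    "train_metrics": m.train_report.as_dict(),
                }
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir) -> "BaseModelGrid":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        fp = FingerprintConfig(**manifest["fingerprint"])
        models = []
        from cholarray.metrics import EvalReport

        for entry in manifest["models"]:
            spec = BaseModelSpec(
                target=entry["target"],
                algorithm=entry["algorithm"],
                seed=entry["seed"],
                fingerprint=fp,
            )
            est = joblib.load(src / entry["file"])
            rep = EvalReport()
            for k, v in entry["test_metrics"].items():
                setattr(rep, k, v)
            trep = EvalReport()
            for k, v in entry["train_metrics"].items():
                setattr(trep, k, v)
            models.append(
                TrainedBaseModel(
                    spec=spec, model=est, train_report=trep, test_report=rep
                )
            )
        return cls(models)
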