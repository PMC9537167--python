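"""Assemble, reshape and resample 200-slot meta-prediction arrays.

Every out-of-set compound is scored by all 200 grid models; the scores
(or their 0.5-thresholded binary calls) fill a fixed-order flat vector:
slow axis = target, middle = seed, fast = algorithm. Reshaping to any of
the declared 2D/3D shapes is row-major and lossless.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from cholarray.dti_grid import BaseModelGrid
from cholarray.fingerprints import fingerprint_matrix

#: Canonical slot count for the default 5x4x10 grid. Reduced grids
#: (fewer seeds/targets) produce proportionally shorter arrays.
N_SLOTS = 200
#: The declared 2D/3D shapes of the canonical 200-slot array.
VALID_SHAPES: tuple[tuple[int, ...], ...] = (
    (50, 4),
    (40, 5),
    (5, 10, 4),
    (10, 5, 4),
)
ENCODINGS = ("binary01", "binary12", "probability")

#: Version tag of the (target, seed, algorithm) -> flat index map.
#: Changing the slot order must change this string, which invalidates
#: persisted arrays via the manifest hash check.
SLOT_ORDER_VERSION = "target-seed-algorithm/v1"


def slot_order_hash(grid_manifest: dict) -> str:
    """Hash pinning slot semantics of a persisted array dataset."""
    key = SLOT_ORDER_VERSION + "|" + "|".join(
        grid_manifest["targets"]
    ) + "|" + "|".join(grid_manifest["algorithms"]) + "|" + ",".join(
        str(s) for s in grid_manifest["seeds"]
    )
    return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass
class MetaArray:
    """One compound's ordered vector of base-model outputs."""

    compound_id: str
    values: np.ndarray  # flat canonical order, length 200
    shape: tuple[int, ...] | str = "flat"
    encoding: str = "binary01"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("meta array must have at least one slot")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"encoding must be one of {ENCODINGS}")
        if self.shape != "flat":
            self.shape = tuple(self.shape)
            if int(np.prod(self.shape)) != self.values.size:
                raise ValueError(
                    f"shape {self.shape} does not hold {self.values.size} slots"
                )

    def as_array(self) -> np.ndarray:
        """Values in the declared shape (row-major fill of the flat order)."""
        if self.shape == "flat":
            return self.values.copy()
        return self.values.reshape(self.shape)


def reshape(array: MetaArray, shape) -> MetaArray:
    """Re-declare the array's shape; the flat canonical order is kept.

    flatten(reshape(a)) == flatten(a) always (row-major refilling).
    """
    if shape != "flat":
        shape = tuple(shape)
        if int(np.prod(shape)) != array.values.size:
            raise ValueError(
                f"dim product {int(np.prod(shape))} != {array.values.size}"
            )
    return MetaArray(
        compound_id=array.compound_id,
        values=array.values.copy(),
        shape=shape,
        encoding=array.encoding,
    )


def flatten(array: MetaArray) -> MetaArray:
    return reshape(array, "flat")


@dataclass
class ArrayDataset:
    """Meta arrays with class labels and sampling provenance."""

    arrays: list[MetaArray]
    class_labels: list[str]  # each "CWA" or "nonCWA"
    sampling_model: str = "Model01"
    synthetic_mask: np.ndarray | None = None  # True where SMOTE-generated
    collisions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.arrays) != len(self.class_labels):
            raise ValueError("labels must be parallel to arrays")
        bad = set(self.class_labels) - {"CWA", "nonCWA"}
        if bad:
            raise ValueError(f"bad class labels: {bad}")
        if self.synthetic_mask is None:
            self.synthetic_mask = np.zeros(len(self.arrays), dtype=bool)
        else:
            self.synthetic_mask = np.asarray(self.synthetic_mask, dtype=bool)
            if self.synthetic_mask.shape != (len(self.arrays),):
                raise ValueError("synthetic_mask must be parallel to arrays")

    def __len__(self) -> int:
        return len(self.arrays)

    @property
    def matrix(self) -> np.ndarray:
        """(n, 200) stacked flat values."""
        return np.vstack([a.values for a in self.arrays])

    @property
    def y(self) -> np.ndarray:
        """1 = CWA (positive class), 0 = nonCWA."""
        return np.asarray([1 if c == "CWA" else 0 for c in self.class_labels])

    def class_counts(self) -> dict[str, int]:
        return {
            "CWA": int(self.y.sum()),
            "nonCWA": int(len(self) - self.y.sum()),
        }

    def subset(self, idx, sampling_model: str | None = None) -> "ArrayDataset":
        idx = np.asarray(idx)
        return ArrayDataset(
            arrays=[self.arrays[i] for i in idx],
            class_labels=[self.class_labels[i] for i in idx],
            sampling_model=sampling_model or self.sampling_model,
            synthetic_mask=self.synthetic_mask[idx],
        )


def predict_meta(
    grid: BaseModelGrid,
    compounds,
    fingerprint_config=None,
    encoding: str = "binary01",
    X: np.ndarray | None = None,
) -> list[MetaArray]:
    """Score compounds with every grid model into ordered meta arrays.

    ``compounds`` is a MetaStageSet (fingerprinted with the grid's own
    config), or pass a precomputed feature matrix ``X`` plus compound ids
    via ``compounds`` being a list of ids. Binary encodings threshold
    each model's probability at 0.5; binary12 maps {0,1} -> {1,2}.
    """
    if fingerprint_config is not None and fingerprint_config != grid.fingerprint_config:
        raise ValueError(
            "fingerprint config mismatch: grid was trained with "
            f"{grid.fingerprint_config}, got {fingerprint_config}"
        )
    if X is None:
        ids = list(compounds.compound_ids)
        X = fingerprint_matrix(compounds.smiles, grid.fingerprint_config)
    else:
        ids = list(compounds)
        X = np.asarray(X)
        if X.shape[1] != grid.fingerprint_config.n_bits:
            raise ValueError(
                f"feature width {X.shape[1]} != grid n_bits "
                f"{grid.fingerprint_config.n_bits}"
            )
    scores = np.empty((X.shape[0], len(grid)))
    for j, key in enumerate(grid.slot_keys()):
        scores[:, j] = grid[key].score(X)
    if encoding == "binary01":
        values = (scores >= 0.5).astype(float)
    elif encoding == "binary12":
        values = (scores >= 0.5).astype(float) + 1.0
    elif encoding == "probability":
        values = scores
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return [
        MetaArray(compound_id=cid, values=row, shape="flat", encoding=encoding)
        for cid, row in zip(ids, values)
    ]


def dedup_arrays(data: ArrayDataset) -> ArrayDataset:
    """Model02 under-sampling: drop repeated (values, label) arrays.

    Among compounds with identical value vectors AND identical class
    label only the first (input order) survives. Identical vectors with
    conflicting labels are all kept and flagged as collisions. Idempotent.
    """
    seen: dict[tuple, int] = {}  # (values..., label) -> first index
    by_values: dict[tuple, list[int]] = {}
    keep: list[int] = []
    for i, (arr, lab) in enumerate(zip(data.arrays, data.class_labels)):
        vkey = tuple(arr.values.tolist())
        key = vkey + (lab,)
        by_values.setdefault(vkey, []).append(i)
        if key in seen:
            continue
        seen[key] = i
        keep.append(i)
    collisions = [
        (idxs[0], j)
        for vkey, idxs in by_values.items()
        if len({data.class_labels[i] for i in idxs}) > 1
        for j in idxs[1:]
        if data.class_labels[j] != data.class_labels[idxs[0]]
    ]
    out = data.subset(np.asarray(keep, dtype=int), sampling_model="Model02")
    out.collisions = collisions
    return out


def smote_oversample(
    data: ArrayDataset, k_neighbors: int = 5, seed: int = 0
) -> ArrayDataset:
    """Balance classes by synthesizing minority arrays (SMOTE).

    Each synthetic array is a convex combination x + u * (neighbor - x)
    with u ~ U[0, 1) between a minority array and one of its k nearest
    minority neighbors; values stay continuous (probability encoding) and
    carry synthetic_mask=True.
    """
    y = data.y
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == n_neg:
        return data
    minority_label = "CWA" if n_pos < n_neg else "nonCWA"
    min_idx = np.flatnonzero(y == (1 if minority_label == "CWA" else 0))
    n_min, n_maj = len(min_idx), max(n_pos, n_neg)
    if n_min < k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} members; SMOTE with k={k_neighbors} "
            f"needs at least {k_neighbors + 1}"
        )
    Xmin = data.matrix[min_idx]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
    neighbors = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    gap = rng.random(n_new)

    new_arrays: list[MetaArray] = []
    for t in range(n_new):
        x = Xmin[base[t]]
        other = Xmin[neighbors[base[t], pick[t]]]
        values = x + gap[t] * (other - x)
        new_arrays.append(
            MetaArray(
                compound_id=f"smote{t:05d}",
                values=values,
                shape="flat",
                encoding="probability",
            )
        )

    model = "Model04" if data.sampling_model == "Model02" else "Model03"
    return ArrayDataset(
        arrays=list(data.arrays) + new_arrays,
        class_labels=list(data.class_labels) + [minority_label] * n_new,
        sampling_model=model,
        synthetic_mask=np.concatenate(
            [data.synthetic_mask, np.ones(n_new, dtype=bool)]
        ),
    )


def apply_sampling(
    data: ArrayDataset, model: str, k_neighbors: int = 5, seed: int = 0
) -> ArrayDataset:
    """Dispatch the four sampling regimes (Model01..Model04)."""
    model = model.capitalize() if model.lower().startswith("model") else model
    if model in ("Model01", "model01"):
        return data
    if model in ("Model02", "model02"):
        return dedup_arrays(data)
    if model in ("Model03", "model03"):
        return smote_oversample(data, k_neighbors=k_neighbors, seed=seed)
    if model in ("Model04", "model04"):
        return smote_oversample(
            dedup_arrays(data), k_neighbors=k_neighbors, seed=seed
        )
    raise ValueError(f"unknown sampling model {model!r}")


def save_dataset(data: ArrayDataset, path, grid_manifest: dict | None = None) -> None:
    """Flat TSV: compound_id, class, synthetic flag, 200 value columns."""
    import json
    from pathlib import Path

    p = Path(path)
    n_slots = data.arrays[0].values.size if data.arrays else N_SLOTS
    with open(p, "w") as fh:
        cols = "\t".join(f"v{i:03d}" for i in range(n_slots))
        fh.write(f"compound_id\tclass\tsynthetic\t{cols}\n")
        for arr, lab, syn in zip(data.arrays, data.class_labels, data.synthetic_mask):
            vals = "\t".join(repr(float(v)) for v in arr.values)
            fh.write(f"{arr.compound_id}\t{lab}\t{int(syn)}\t{vals}\n")
    manifest = {
        "sampling_model": data.sampling_model,
        "encoding": data.arrays[0].encoding if data.arrays else "binary01",
        "slot_order_version": SLOT_ORDER_VERSION,
    }
    if grid_manifest is not None:
        manifest["slot_order_hash"] = slot_order_hash(grid_manifest)
    p.with_suffix(p.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )


def load_dataset(path) -> ArrayDataset:
    import json
    from pathlib import Path

    p = Path(path)
    manifest_path = p.with_suffix(p.suffix + ".manifest.json")
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    encoding = manifest.get("encoding", "binary01")
    if manifest.get("slot_order_version", SLOT_ORDER_VERSION) != SLOT_ORDER_VERSION:
        raise ValueError("persisted arrays use an incompatible slot order version")
    arrays: list[MetaArray] = []
    labels: list[str] = []
    synth: list[bool] = []
    with open(p) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            arrays.append(
                MetaArray(
                    compound_id=parts[0],
                    values=np.asarray(parts[3:], dtype=float),
                    encoding=encoding,
                )
            )
            labels.append(parts[1])
            synth.append(bool(int(parts[2])))
    return ArrayDataset(
        arrays=arrays,
        class_labels=labels,
        sampling_model=manifest.get("sampling_model", "Model01"),
        synthetic_mask=np.asarray(synth, dtype=bool),
    )
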