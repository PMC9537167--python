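"""Circular fingerprint generation (ECFP / FCFP, 1024-bit).

Two families x four diameters (0, 2, 4, 6) give the eight valid
configurations. Diameter d corresponds to Morgan radius d // 2. FCFP uses
feature (pharmacophoric) atom invariants; ECFP uses the default
connectivity invariants. Bits are folded to ``n_bits`` by the toolkit's
standard modulo folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

FAMILIES = ("ECFP", "FCFP")
DIAMETERS = (0, 2, 4, 6)


class StructureError(ValueError):
    """SMILES failed to parse."""


@dataclass(frozen=True)
class FingerprintConfig:
    family: str = "ECFP"
    diameter: int = 4
    n_bits: int = 1024

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.diameter not in DIAMETERS:
            raise ValueError(f"diameter must be one of {DIAMETERS}")
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")

    @property
    def radius(self) -> int:
        return self.diameter // 2

    @property
    def name(self) -> str:
        return f"{self.family}{self.diameter}"


def all_configs(n_bits: int = 1024) -> list[FingerprintConfig]:
    """The eight (family, diameter) combinations at a fixed bit length."""
    return [
        FingerprintConfig(family=f, diameter=d, n_bits=n_bits)
        for f in FAMILIES
        for d in DIAMETERS
    ]


@dataclass
class LabeledFingerprintSet:
    """Binary feature matrix with parallel binary activity labels."""

    compound_ids: list[str]
    bit_matrix: np.ndarray  # (n_compounds, n_bits) uint8 in {0,1}
    labels: np.ndarray  # (n_compounds,) uint8, 1 = active
    config: FingerprintConfig | None = None

    def __post_init__(self) -> None:
        self.bit_matrix = np.asarray(self.bit_matrix, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.bit_matrix.ndim != 2:
            raise ValueError("bit_matrix must be 2D")
        if len(self.compound_ids) != self.bit_matrix.shape[0]:
            raise ValueError("row count must match compound_ids")
        if self.labels.shape != (self.bit_matrix.shape[0],):
            raise ValueError("labels must be parallel to rows")
        if not np.isin(self.bit_matrix, (0, 1)).all():
            raise ValueError("bit_matrix entries must be 0/1")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.compound_ids)

    @property
    def n_bits(self) -> int:
        return self.bit_matrix.shape[1]

    def is_degenerate(self) -> bool:
        """True when all labels are identical (untrainable)."""
        return len(np.unique(self.labels)) < 2

    def subset(self, idx: np.ndarray) -> "LabeledFingerprintSet":
        idx = np.asarray(idx)
        return LabeledFingerprintSet(
            compound_ids=[self.compound_ids[i] for i in idx],
            bit_matrix=self.bit_matrix[idx],
            labels=self.labels[idx],
            config=self.config,
        )


@dataclass
class BuildReport:
    n_input: int = 0
    n_kept: int = 0
    failed: list[str] = field(default_factory=list)  # compound_ids


def _generator(config: FingerprintConfig):
    kwargs: dict = {"radius": config.radius, "fpSize": config.n_bits}
    if config.family == "FCFP":
        kwargs["atomInvariantsGenerator"] = (
            rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        )
    return rdFingerprintGenerator.GetMorganGenerator(**kwargs)


def fingerprint(smiles: str, config: FingerprintConfig) -> np.ndarray:
    """Hashed circular fingerprint as a 0/1 vector of length n_bits.

    Deterministic, and invariant to atom-order permutations of the same
    molecule (RDKit canonicalizes the graph before hashing).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    fp = _generator(config).GetFingerprint(mol)
    arr = np.zeros(config.n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def n_environments(smiles: str, config: FingerprintConfig) -> int:
    """Number of distinct hashed environments before folding.

    Used to verify that folding collisions are absent on small molecules
    (count of unfolded environments == set bits in the folded vector).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    kwargs: dict = {"radius": config.radius}
    if config.family == "FCFP":
        kwargs["atomInvariantsGenerator"] = (
            rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        )
    gen = rdFingerprintGenerator.GetMorganGenerator(**kwargs)
    return gen.GetSparseFingerprint(mol).GetNumOnBits()


def build_matrix(
    compound_set,
    config: FingerprintConfig,
    strict: bool = True,
) -> tuple[LabeledFingerprintSet, BuildReport]:
    """Fingerprint every compound of a LabeledCompoundSet into a matrix.

    In strict mode, a failing SMILES raises a StructureError naming the
    compound; in lenient mode the row is skipped and recorded in the
    report. Labels pass through unchanged (active -> 1).
    """
    if len(compound_set) == 0:
        raise ValueError("empty compound set")
    report = BuildReport(n_input=len(compound_set))
    ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for cid, smi, lab in zip(
        compound_set.compound_ids, compound_set.smiles, compound_set.labels
    ):
        try:
            row = fingerprint(smi, config)
        except StructureError as err:
            if strict:
                raise StructureError(f"compound {cid}: {err}") from err
            report.failed.append(cid)
            continue
        ids.append(cid)
        rows.append(row)
        labels.append(1 if lab == "active" else 0)
    if not rows:
        raise ValueError("no fingerprintable compounds")
    report.n_kept = len(rows)
    return (
        LabeledFingerprintSet(
            compound_ids=ids,
            bit_matrix=np.vstack(rows),
            labels=np.asarray(labels, dtype=np.uint8),
            config=config,
        ),
        report,
    )


def fingerprint_matrix(smiles_list: list[str], config: FingerprintConfig) -> np.ndarray:
    """Stack fingerprints for a list of SMILES (strict)."""
    return np.vstack([fingerprint(s, config) for s in smiles_list])
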