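"""Read, clean, deduplicate and binarize activity data.

Input is a ChEMBL-export-style CSV of activity measurements (one row per
assay record). Output is one labeled compound set per cholinergic target,
with activity calls binarized against a potency threshold, plus a
cleaning report accounting for every dropped row.
"""

from __future__ import annotations

import csv
import statistics
from collections import OrderedDict
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Canonical cholinergic target names, in fixed slot order.
TARGETS: tuple[str, ...] = ("nAChR", "mAChR", "AChE", "BuChE", "VAChT")

VALID_RELATIONS = ("=", "<", ">", "<=", ">=")

#: Default mapping from ChEMBL tid / pref_name tokens to canonical target
#: names. Editable: pass your own ``target_map`` to :func:`read_activity_csv`.
#: Only BuChE's tid (10532) is fixed by the source query; the others are
#: synthetic placeholders matching the simulate CLI output.
DEFAULT_TARGET_MAP: dict[str, str] = {
    "10532": "BuChE",
    "butyrylcholinesterase": "BuChE",
    "acetylcholinesterase": "AChE",
    "nicotinic acetylcholine receptor": "nAChR",
    "muscarinic acetylcholine receptor": "mAChR",
    "vesicular acetylcholine transporter": "VAChT",
    "nachr": "nAChR",
    "machr": "mAChR",
    "ache": "AChE",
    "buche": "BuChE",
    "vacht": "VAChT",
}

#: Column names of the source export, mapped to record fields.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "compound_id": "molregno",
    "smiles": "canonical_smiles",
    "standard_value": "standard_value",
    "standard_relation": "standard_relation",
    "standard_unit": "standard_units",
    "tid": "tid",
    "pref_name": "pref_name",
}


class ConfigurationError(ValueError):
    """A mandatory column or mapping entry is missing."""


class EmptyDatasetError(ValueError):
    """Reading or filtering produced zero usable records."""


class InputError(ValueError):
    """Malformed input content (e.g. unknown class token)."""


@dataclass(frozen=True)
class ActivityRecord:
    """One cleaned activity measurement."""

    compound_id: str
    smiles: str
    target_id: str
    standard_value: float
    standard_relation: str = "="
    standard_unit: str = "nM"

    def __post_init__(self) -> None:
        if self.target_id not in TARGETS:
            raise ValueError(f"unknown target_id {self.target_id!r}")
        if self.standard_value < 0:
            raise ValueError("standard_value must be non-negative")
        if self.standard_relation not in VALID_RELATIONS:
            raise ValueError(f"bad relation {self.standard_relation!r}")


@dataclass
class CleaningReport:
    """Counts per drop reason; reconciles with the input row count."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def reconciles(self) -> bool:
        return self.n_input == self.n_kept + self.n_dropped

    def to_text(self) -> str:
        lines = [f"input rows: {self.n_input}", f"kept: {self.n_kept}"]
        for reason in sorted(self.dropped):
            lines.append(f"dropped[{reason}]: {self.dropped[reason]}")
        return "\n".join(lines)


@dataclass
class LabeledCompoundSet:
    """Parallel lists of compounds with binary activity labels."""

    compound_ids: list[str]
    smiles: list[str]
    labels: list[str]  # each "active" or "inactive"

    def __post_init__(self) -> None:
        if not (len(self.compound_ids) == len(self.smiles) == len(self.labels)):
            raise ValueError("parallel lists must have equal length")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound_id")
        bad = set(self.labels) - {"active", "inactive"}
        if bad:
            raise ValueError(f"non-binary labels: {bad}")

    def __len__(self) -> int:
        return len(self.compound_ids)


@dataclass
class MetaStageSet:
    """Labeled SMILES for the meta stage (CWA vs nonCWA)."""

    compound_ids: list[str]
    smiles: list[str]
    class_labels: list[str]  # each "CWA" or "nonCWA"
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if not (
            len(self.compound_ids) == len(self.smiles) == len(self.class_labels)
        ):
            raise ValueError("parallel lists must have equal length")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound_id")
        bad = set(self.class_labels) - {"CWA", "nonCWA"}
        if bad:
            raise InputError(f"unknown class tokens: {bad}")

    def __len__(self) -> int:
        return len(self.compound_ids)

    @property
    def prevalence(self) -> float:
        """Fraction of CWA-labeled compounds."""
        n = len(self.class_labels)
        return sum(1 for c in self.class_labels if c == "CWA") / n


def _parse_smiles(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _map_target(
    row: dict[str, str], column_map: dict[str, str], target_map: dict[str, str]
) -> str | None:
    for key in ("tid", "pref_name"):
        col = column_map.get(key)
        if col and col in row:
            token = (row[col] or "").strip()
            for candidate in (token, token.lower()):
                if candidate in target_map:
                    return target_map[candidate]
    return None


def read_activity_csv(
    path,
    column_map: dict[str, str] | None = None,
    target_map: dict[str, str] | None = None,
) -> tuple[list[ActivityRecord], CleaningReport]:
    """Read an activity CSV into records, dropping unusable rows.

    Rows are dropped (and counted in the report) when the SMILES does not
    parse, the standard value is missing/non-numeric/negative, the unit
    is not nM, the relation is unknown, or the target cannot be mapped.

    Raises
    ------
    ConfigurationError
        If a mandatory mapped column is absent from the header.
    EmptyDatasetError
        If no usable record remains.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    tmap = {k.lower() if not k.isdigit() else k: v for k, v in (target_map or DEFAULT_TARGET_MAP).items()}

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        mandatory = ("compound_id", "smiles", "standard_value", "standard_unit")
        for key in mandatory:
            if cmap[key] not in header:
                raise ConfigurationError(
                    f"mandatory column {cmap[key]!r} (for {key}) missing from header"
                )
        if cmap["tid"] not in header and cmap["pref_name"] not in header:
            raise ConfigurationError(
                "neither tid nor pref_name column present; cannot map targets"
            )

        records: list[ActivityRecord] = []
        report = CleaningReport()
        for row in reader:
            report.n_input += 1
            unit = (row.get(cmap["standard_unit"]) or "").strip()
            if unit != "nM":
                report.drop("unit_dropped")
                continue
            raw_value = (row.get(cmap["standard_value"]) or "").strip()
            try:
                value = float(raw_value)
            except ValueError:
                report.drop("missing_value")
                continue
            if value < 0:
                report.drop("negative_value")
                continue
            relation = (row.get(cmap["standard_relation"]) or "=").strip() or "="
            if relation not in VALID_RELATIONS:
                report.drop("bad_relation")
                continue
            target = _map_target(row, cmap, tmap)
            if target is None:
                report.drop("unmapped_target")
                continue
            canonical = _parse_smiles((row.get(cmap["smiles"]) or "").strip())
            if canonical is None:
                report.drop("bad_smiles")
                continue
            records.append(
                ActivityRecord(
                    compound_id=str(row[cmap["compound_id"]]).strip(),
                    smiles=canonical,
                    target_id=target,
                    standard_value=value,
                    standard_relation=relation,
                    standard_unit="nM",
                )
            )
            report.n_kept += 1

    if not records:
        raise EmptyDatasetError(f"no usable activity records in {path}")
    return records, report


def deduplicate(records: list[ActivityRecord]) -> list[ActivityRecord]:
    """Collapse duplicate (compound, target) measurements.

    Multiple values reduce to their median; the relation survives only if
    all duplicates agree, otherwise it degrades to "=". Output preserves
    first-occurrence order. Idempotent.
    """
    groups: OrderedDict[tuple[str, str], list[ActivityRecord]] = OrderedDict()
    for rec in records:
        groups.setdefault((rec.compound_id, rec.target_id), []).append(rec)

    out: list[ActivityRecord] = []
    for (compound_id, target_id), recs in groups.items():
        if len(recs) == 1:
            out.append(recs[0])
            continue
        relations = {r.standard_relation for r in recs}
        out.append(
            ActivityRecord(
                compound_id=compound_id,
                smiles=recs[0].smiles,
                target_id=target_id,
                standard_value=statistics.median(r.standard_value for r in recs),
                standard_relation=relations.pop() if len(relations) == 1 else "=",
                standard_unit="nM",
            )
        )
    return out


def _resolve_call(value: float, relation: str, threshold: float) -> str | None:
    """Binary activity call, or None when the censored value is unresolvable."""
    if relation in ("=",):
        return "active" if value <= threshold else "inactive"
    if relation in ("<", "<="):
        # true value below `value`: resolvable only when the bound itself
        # is at or below the threshold
        return "active" if value <= threshold else None
    if relation in (">", ">="):
        return "inactive" if value >= threshold else None
    return None


def binarize(
    records: list[ActivityRecord], threshold_nM: float = 10_000.0
) -> tuple[dict[str, LabeledCompoundSet], CleaningReport]:
    """Binarize records into per-target labeled sets.

    A record is active iff its value is at or below ``threshold_nM``
    (default 10 uM). Censored records that cannot be resolved against the
    threshold are dropped and counted. Call :func:`deduplicate` first;
    duplicate (compound, target) pairs here raise.
    """
    if threshold_nM <= 0:
        raise ValueError("threshold_nM must be positive")
    report = CleaningReport(n_input=len(records))
    per_target: dict[str, dict[str, tuple[str, str]]] = {t: OrderedDict() for t in TARGETS}
    for rec in records:
        call = _resolve_call(rec.standard_value, rec.standard_relation, threshold_nM)
        if call is None:
            report.drop("censored_unresolvable")
            continue
        bucket = per_target[rec.target_id]
        if rec.compound_id in bucket:
            raise ValueError(
                f"duplicate (compound, target) pair {rec.compound_id}/{rec.target_id}; "
                "run deduplicate() first"
            )
        bucket[rec.compound_id] = (rec.smiles, call)
        report.n_kept += 1

    sets: dict[str, LabeledCompoundSet] = {}
    for target, bucket in per_target.items():
        if not bucket:
            continue
        sets[target] = LabeledCompoundSet(
            compound_ids=list(bucket),
            smiles=[v[0] for v in bucket.values()],
            labels=[v[1] for v in bucket.values()],
        )
    return sets, report


def read_meta_stage(path) -> MetaStageSet:
    """Read a two-column (SMILES, class) file for the meta stage.

    Columns may be comma- or whitespace-separated. Class tokens must be
    CWA or nonCWA (case-insensitive). Duplicate SMILES keep the first
    occurrence; the number dropped is recorded on the result.
    """
    canon_class = {"cwa": "CWA", "noncwa": "nonCWA", "non-cwa": "nonCWA"}
    ids: list[str] = []
    smiles_list: list[str] = []
    labels: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected two columns")
            smi, token = parts[0].strip(), parts[1].strip()
            if token.lower() not in canon_class:
                raise InputError(f"{path}:{lineno}: unknown class token {token!r}")
            canonical = _parse_smiles(smi)
            if canonical is None:
                raise InputError(f"{path}:{lineno}: unparseable SMILES {smi!r}")
            if canonical in seen:
                n_dup += 1
                continue
            seen.add(canonical)
            ids.append(f"meta{len(ids) + 1:04d}")
            smiles_list.append(canonical)
            labels.append(canon_class[token.lower()])
    if not ids:
        raise EmptyDatasetError(f"no usable rows in {path}")
    return MetaStageSet(ids, smiles_list, labels, n_duplicates_dropped=n_dup)
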