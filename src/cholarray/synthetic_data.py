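"""Synthetic fixtures with the statistical structure the pipeline assumes.

Every stage of the pipeline is testable offline: per-target fingerprint
sets carry a planted, disjoint informative bit set per target; meta-stage
compounds carry a latent 5-target activity profile and a threat label
drawn from a configurable rule on that profile. Generators are
bit-reproducible from (spec, seed). No real or plausible hazardous
structure is generated or embedded anywhere — the SMILES fixture is a
fixed list of innocuous approved drugs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from cholarray.chem_data import TARGETS, LabeledCompoundSet
from cholarray.fingerprints import FingerprintConfig, LabeledFingerprintSet
from cholarray.meta_array import ArrayDataset, MetaArray


def default_cwa_rule(profile: np.ndarray) -> float:
    """P(threat label) given a 5-slot activity profile.

    High probability iff the compound is active on both esterase targets
    (AChE and BuChE), echoing the cholinergic mechanism the detector is
    meant to pick up.
    """
    ache = profile[TARGETS.index("AChE")]
    buche = profile[TARGETS.index("BuChE")]
    return 0.9 if (ache and buche) else 0.02


@dataclass
class SyntheticSpec:
    n_per_target: int = 200
    n_bits: int = 1024
    informative_bits_per_target: int = 9  # odd, so majority is unambiguous
    activity_noise: float = 0.1  # label flip probability
    bit_flip: float = 0.15  # planted-bit disagreement with the latent activity
    background_density: float = 0.05
    n_cwa: int = 0  # 0 = draw labels from cwa_rule
    n_noncwa: int = 0
    n_meta: int = 600
    cwa_rule: object = default_cwa_rule
    seed: int = 0
    targets: tuple[str, ...] = TARGETS

    def __post_init__(self) -> None:
        if not 0 <= self.activity_noise < 0.5:
            raise ValueError("activity_noise must be in [0, 0.5)")
        if self.informative_bits_per_target % 2 == 0:
            raise ValueError("informative_bits_per_target must be odd")
        if self.informative_bits_per_target * len(self.targets) > self.n_bits:
            raise ValueError("not enough bits for disjoint planted sets")


@dataclass
class DTIFixture:
    """Per-target labeled fingerprint sets plus the planted ground truth."""

    datasets: dict[str, LabeledFingerprintSet]
    planted_bits: dict[str, np.ndarray]
    clean_labels: dict[str, np.ndarray]  # pre-noise majority labels


def _plant_background(rng: np.random.Generator, n: int, spec: SyntheticSpec
                      ) -> np.ndarray:
    return (rng.random((n, spec.n_bits)) < spec.background_density).astype(np.uint8)


def _assign_planted_bits(rng: np.random.Generator, spec: SyntheticSpec
                         ) -> dict[str, np.ndarray]:
    """Disjoint informative bit indices per target."""
    k = spec.informative_bits_per_target
    chosen = rng.choice(spec.n_bits, size=k * len(spec.targets), replace=False)
    return {
        t: np.sort(chosen[i * k : (i + 1) * k])
        for i, t in enumerate(spec.targets)
    }


def _planted_signal(
    rng: np.random.Generator, latent: np.ndarray, k: int, bit_flip: float
) -> np.ndarray:
    """Planted bit block: each bit copies the latent activity, flipped
    independently with probability ``bit_flip``."""
    flips = (rng.random((latent.size, k)) < bit_flip).astype(np.uint8)
    return latent[:, None] ^ flips


def gen_dti_dataset(spec: SyntheticSpec) -> DTIFixture:
    """One labeled fingerprint set per target with planted signal.

    Each compound draws a fair latent activity; every planted bit copies
    it with probability 1 - bit_flip (bits are therefore mutually
    correlated and individually informative). The clean label is the
    majority of the planted bits, and the observed label is the clean
    label XOR a Bernoulli(activity_noise) flip. Marginal class balance
    is ~50%.
    """
    rng = np.random.default_rng(spec.seed)
    planted = _assign_planted_bits(rng, spec)
    k = spec.informative_bits_per_target
    datasets: dict[str, LabeledFingerprintSet] = {}
    clean: dict[str, np.ndarray] = {}
    for target in spec.targets:
        n = spec.n_per_target
        X = _plant_background(rng, n, spec)
        latent = (rng.random(n) < 0.5).astype(np.uint8)
        signal = _planted_signal(rng, latent, k, spec.bit_flip)
        X[:, planted[target]] = signal
        majority = (signal.sum(axis=1) > k // 2).astype(np.uint8)
        flips = (rng.random(n) < spec.activity_noise).astype(np.uint8)
        labels = majority ^ flips
        datasets[target] = LabeledFingerprintSet(
            compound_ids=[f"{target}_c{i:05d}" for i in range(n)],
            bit_matrix=X,
            labels=labels,
            config=FingerprintConfig(n_bits=spec.n_bits),
        )
        clean[target] = majority
    return DTIFixture(datasets=datasets, planted_bits=planted, clean_labels=clean)


def clean_labels_for(
    fixture: DTIFixture, target: str, compound_ids: list[str]
) -> np.ndarray:
    """Pre-noise (ground-truth) activity labels for generated compounds.

    Compound ids embed their row index, so any subset (e.g. a held-out
    split) can be mapped back to the latent truth for recovery checks.
    """
    idx = [int(cid.rsplit("_c", 1)[1]) for cid in compound_ids]
    return fixture.clean_labels[target][idx]


@dataclass
class MetaStageFeatures:
    """Feature-level synthetic meta-stage compounds."""

    compound_ids: list[str]
    X: np.ndarray  # (n, n_bits) uint8
    profiles: np.ndarray  # (n, n_targets) uint8 latent activity profile
    class_labels: list[str]  # "CWA" / "nonCWA" drawn from cwa_rule
    rule_truth: np.ndarray  # (n,) uint8: deterministic part of the rule

    def __len__(self) -> int:
        return len(self.compound_ids)

    @property
    def prevalence(self) -> float:
        return sum(1 for c in self.class_labels if c == "CWA") / len(self)


def gen_meta_stage(
    spec: SyntheticSpec, fixture: DTIFixture
) -> MetaStageFeatures:
    """Feature-level meta-stage set with latent activity profiles.

    Each compound draws a latent 5-target profile (fair coin per target),
    expresses it in the planted bits of the corresponding targets (same
    bit_flip model as the training data), and receives a threat label
    with probability cwa_rule(profile). The deterministic rule truth
    (rule probability > 0.5) is recorded for parameter-recovery checks.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_meta
    k = spec.informative_bits_per_target
    X = _plant_background(rng, n, spec)
    profiles = (rng.random((n, len(spec.targets))) < 0.5).astype(np.uint8)
    for j, target in enumerate(spec.targets):
        X[:, fixture.planted_bits[target]] = _planted_signal(
            rng, profiles[:, j], k, spec.bit_flip
        )
    probs = np.array([spec.cwa_rule(p) for p in profiles])
    labels = rng.random(n) < probs
    return MetaStageFeatures(
        compound_ids=[f"meta_c{i:05d}" for i in range(n)],
        X=X,
        profiles=profiles,
        class_labels=["CWA" if b else "nonCWA" for b in labels],
        rule_truth=(probs > 0.5).astype(np.uint8),
    )


def gen_meta_arrays(
    spec: SyntheticSpec,
    per_slot_accuracy: float = 1.0,
    n_targets: int = 5,
    n_seeds: int = 10,
    n_algorithms: int = 4,
) -> ArrayDataset:
    """Directly synthesized 200-slot arrays with a per-slot accuracy knob.

    Slot (t, s, a) equals the compound's latent activity on target t with
    probability ``per_slot_accuracy``, else the flipped value. Accuracy
    1.0 separates classes perfectly under the rule; 0.5 is pure noise.
    """
    if n_targets * n_seeds * n_algorithms != 200:
        raise ValueError("grid dims must multiply to 200")
    rng = np.random.default_rng(spec.seed + 2)
    if spec.n_cwa or spec.n_noncwa:
        # fixed class counts: profiles drawn conditional on the rule truth
        labels = ["CWA"] * spec.n_cwa + ["nonCWA"] * spec.n_noncwa
        profiles = np.empty((len(labels), n_targets), dtype=np.uint8)
        for i, lab in enumerate(labels):
            while True:
                p = (rng.random(n_targets) < 0.5).astype(np.uint8)
                if (spec.cwa_rule(p) > 0.5) == (lab == "CWA"):
                    profiles[i] = p
                    break
    else:
        profiles = (rng.random((spec.n_meta, n_targets)) < 0.5).astype(np.uint8)
        probs = np.array([spec.cwa_rule(p) for p in profiles])
        labels = ["CWA" if b else "nonCWA" for b in rng.random(spec.n_meta) < probs]

    n = len(labels)
    slots_per_target = n_seeds * n_algorithms
    truth = np.repeat(profiles, slots_per_target, axis=1).astype(float)
    keep = rng.random(truth.shape) < per_slot_accuracy
    values = np.where(keep, truth, 1.0 - truth)
    arrays = [
        MetaArray(compound_id=f"arr_c{i:05d}", values=values[i])
        for i in range(n)
    ]
    return ArrayDataset(arrays=arrays, class_labels=list(labels))


#: Fixed embedded fixture: innocuous, well-known approved drugs and
#: vitamins. Used only for I/O and fingerprint smoke tests.
TINY_SMILES: tuple[str, ...] = (
    "CC(=O)OC1=CC=CC=C1C(=O)O",            # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",        # caffeine
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)NC1=CC=C(O)C=C1",               # paracetamol
    "CC(CS)C(=O)N1CCCC1C(=O)O",            # captopril
    "CN1CCC[C@H]1c1cccnc1",                # nicotine
    "OC(=O)CC(O)(CC(O)=O)C(O)=O",          # citric acid
    "NC(=O)c1ccncc1",                      # isonicotinamide
    "OCC1OC(O)C(O)C(O)C1O",                # glucose
    "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O", # testosterone
    "ClC1=CC2=C(C=C1)N(C)C(=O)CN=C2C1=CC=CC=C1",  # diazepam-like
    "CN(C)CCOC(C1=CC=CC=C1)C1=CC=CC=C1",   # diphenhydramine
    "CC(N)Cc1ccccc1",                      # amphetamine-scaffold (generic amine)
    "NCCc1ccc(O)c(O)c1",                   # dopamine
    "OC(=O)c1ccccc1O",                     # salicylic acid
    "Nc1ccc(cc1)S(N)(=O)=O",               # sulfanilamide
    "OC(=O)C1=CN=CC=C1",                   # niacin
    "CC(=O)Nc1ccc(OCC(O)CNC(C)C)cc1",      # practolol-like
    "COc1cc2c(cc1OC)CN(C)CC2",             # tetrahydroisoquinoline ether
    "CN1CCN(CC1)C1=NC2=CC=CC=C2N=C1",      # quinoxaline piperazine
    "OCC(O)C(O)C(O)C(O)CO",                # sorbitol
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",      # atenolol
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",          # procainamide
    "CN(C)C(=N)N=C(N)N",                   # metformin
    "OC(=O)CCc1ccccc1",                    # hydrocinnamic acid
    "COC(=O)c1ccccc1O",                    # methyl salicylate
    "NC(Cc1ccc(O)cc1)C(O)=O",              # tyrosine
    "NC(CC(O)=O)C(O)=O",                   # aspartate
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",       # salbutamol
    "Clc1ccccc1C1=NCC(=O)Nc2ccc(cc12)N(=O)=O",  # nitro-benzodiazepinone
    "CCOC(=O)c1ccccc1",                    # ethyl benzoate
    "Cn1cnc2c1c(=O)[nH]c(=O)n2C",          # theobromine
    "OCC(O)CO",                            # glycerol
    "CC(=O)OCC(COC(C)=O)OC(C)=O",          # triacetin
    "NC(=O)N",                             # urea
    "OC(=O)C=Cc1ccccc1",                   # cinnamic acid
    "CN1CCC(CC1)=C1c2ccccc2CCc2ccccc12",   # cyproheptadine-like
    "CCC(C)C1(CC)C(=O)NC(=O)NC1=O",        # barbital-like
    "COc1ccc2cc(ccc2c1)C(C)C(O)=O",        # naproxen
    "OC1=CC(=O)c2ccccc2O1",                # chromone-ol
)


def gen_tiny_smiles_set(seed: int = 0) -> LabeledCompoundSet:
    """~40 embedded valid drug-like SMILES with deterministic pseudo-labels.

    Labels are arbitrary coin flips from the seed (they carry no chemical
    meaning); both classes are always present.
    """
    rng = np.random.default_rng(seed)
    labels = ["active" if b else "inactive" for b in rng.random(len(TINY_SMILES)) < 0.5]
    if len(set(labels)) < 2:  # coin-flip degeneracy guard (n=40: ~never)
        labels[0] = "active" if labels[0] == "inactive" else "inactive"
    return LabeledCompoundSet(
        compound_ids=[f"tiny{i:03d}" for i in range(len(TINY_SMILES))],
        smiles=list(TINY_SMILES),
        labels=labels,
    )


ACTIVITY_CSV_COLUMNS = (
    "molregno", "canonical_smiles", "activity_id", "assay_id",
    "standard_value", "standard_relation", "standard_units",
    "tid", "target_type", "pref_name", "organism",
)

_TARGET_PREF_NAMES = {
    "nAChR": ("Nicotinic acetylcholine receptor", "9001"),
    "mAChR": ("Muscarinic acetylcholine receptor", "9002"),
    "AChE": ("Acetylcholinesterase", "9003"),
    "BuChE": ("Butyrylcholinesterase", "10532"),
    "VAChT": ("Vesicular acetylcholine transporter", "9005"),
}


def write_activity_csv(path, seed: int = 0, n_dirty: int = 3) -> int:
    """Write a small export-style activity CSV built from the embedded
    SMILES fixture; includes ``n_dirty`` deliberately droppable rows.

    Returns the number of clean rows written.
    """
    rng = np.random.default_rng(seed)
    compounds = gen_tiny_smiles_set(seed)
    rows = []
    activity_id = 1000
    for cid, smi in zip(compounds.compound_ids, compounds.smiles):
        for target in TARGETS:
            if rng.random() < 0.4:
                continue
            pref, tid = _TARGET_PREF_NAMES[target]
            value = float(np.round(10 ** rng.uniform(1, 6), 2))
            relation = rng.choice(["=", "=", "=", "<", ">"])
            rows.append(
                [cid, smi, activity_id, activity_id + 1, value, relation,
                 "nM", tid, "SINGLE PROTEIN", pref, "Homo sapiens"]
            )
            activity_id += 2
    n_clean = len(rows)
    dirty = [
        ["dirty1", "CC(=O)O", 1, 1, 5.0, "=", "ug.mL-1", "10532",
         "SINGLE PROTEIN", "Butyrylcholinesterase", "Homo sapiens"],
        ["dirty2", "C1CC", 2, 2, 5.0, "=", "nM", "10532",
         "SINGLE PROTEIN", "Butyrylcholinesterase", "Homo sapiens"],
        ["dirty3", "CC(=O)O", 3, 3, "", "=", "nM", "10532",
         "SINGLE PROTEIN", "Butyrylcholinesterase", "Homo sapiens"],
    ]
    rows.extend(dirty[:n_dirty])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ACTIVITY_CSV_COLUMNS)
        writer.writerows(rows)
    return n_clean


def write_meta_smiles(path, seed: int = 0) -> int:
    """Two-column SMILES/class file from the embedded fixture.

    Class tokens are pseudo-labels for pipeline smoke tests only; no
    hazardous structure is implied or present.
    """
    rng = np.random.default_rng(seed)
    compounds = gen_tiny_smiles_set(seed)
    n = 0
    with open(path, "w") as fh:
        for smi in compounds.smiles:
            token = "CWA" if rng.random() < 0.15 else "nonCWA"
            fh.write(f"{smi},{token}\n")
            n += 1
    return n
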