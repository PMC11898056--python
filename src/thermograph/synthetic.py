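"""Synthetic thermostability datasets with a controllable signal.

The generator emulates the three inputs the model consumes — per-residue
embeddings, contact maps and thermostability targets — with an additive
embedding model

    row_i = tau[type_i] + mu(target) + eps_i,   eps_i ~ N(0, sigma^2 I)

where ``tau`` are fixed random unit vectors per amino-acid type (scaled by
``residue_scale``) and ``mu`` is a class prototype of norm ``effect_size``
(classification) or a fixed unit direction scaled by
``(t_m - 45) / 50 * effect_size`` (regression).  Contact maps have a chain
band of width ``contact_band`` plus sparse symmetric long-range contacts.

Targets use the standard organism-level thermostability bands: Cryophilic
(-20 to 5 C), Psychrophilic (5 to 25), Mesophilic (25 to 45), Thermophilic
(45 to 75) and Hyperthermophilic (above 75, sampled up to 95).  The binary
hot/cold split is at 45 C.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import (
    AMINO_ACIDS,
    ContactMap,
    EmbeddingMatrix,
    ProteinRecord,
    save_dataset_container,
    load_dataset_container,
)

__all__ = [
    "CLASS_BANDS_5",
    "SyntheticSpec",
    "DatasetPrototypes",
    "generate_protein",
    "generate_dataset",
    "check_separability",
]

#: (low, high) temperature band per 5-class label, coldest first.  The
#: hyperthermophilic band is open above; sampling caps it at 95 C.
CLASS_BANDS_5 = ((-20.0, 5.0), (5.0, 25.0), (25.0, 45.0), (45.0, 75.0), (75.0, 95.0))

#: hot/cold boundary in degrees Celsius.
HOT_THRESHOLD = 45.0


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (30, 60)
    F: int = 32
    task: str = "classification"
    n_classes: int = 2
    effect_size: float = 3.0
    residue_scale: float = 1.0
    noise_sd: float = 0.5
    contact_band: int = 2
    long_range_density: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < 3:
            raise ValueError("minimum protein length is 3")
        if self.task == "classification" and self.n_classes not in (2, 5):
            raise ValueError("n_classes must be 2 or 5")
        if not 0.0 <= self.long_range_density <= 1.0:
            raise ValueError("long_range_density must lie in [0, 1]")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclasses.dataclass
class DatasetPrototypes:
    """Fixed per-dataset directions: residue-type vectors and target signal."""

    residue_vectors: np.ndarray  # (20, F), rows of norm residue_scale
    class_prototypes: np.ndarray | None  # (C, F), rows of norm effect_size
    regression_direction: np.ndarray | None  # (F,), unit norm

    @classmethod
    def create(cls, spec: SyntheticSpec, rng: np.random.Generator):
        def unit_rows(n):
            v = rng.standard_normal((n, spec.F))
            return v / np.linalg.norm(v, axis=1, keepdims=True)

        residue = unit_rows(len(AMINO_ACIDS)) * spec.residue_scale
        if spec.task == "classification":
            return cls(residue, unit_rows(spec.n_classes) * spec.effect_size, None)
        return cls(residue, None, unit_rows(1)[0])


def _class_mean(prototypes: DatasetPrototypes, spec: SyntheticSpec, target):
    if spec.task == "classification":
        return prototypes.class_prototypes[int(target)]
    return (
        prototypes.regression_direction
        * (float(target) - HOT_THRESHOLD)
        / 50.0
        * spec.effect_size
    )


def _contact_map(L: int, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    i, j = np.indices((L, L))
    sep = np.abs(i - j)
    m = ((sep >= 1) & (sep <= spec.contact_band)).astype(np.float64)
    if spec.long_range_density > 0:
        upper = (j > i + spec.contact_band)
        hits = upper & (rng.random((L, L)) < spec.long_range_density)
        weights = rng.uniform(0.5, 1.0, size=(L, L))
        m = m + np.where(hits, weights, 0.0)
        m = np.maximum(m, m.T)
    return m


def generate_protein(
    spec: SyntheticSpec,
    class_or_tm,
    rng: np.random.Generator,
    prototypes: DatasetPrototypes,
    protein_id: str = "p0",
    split: str = "train",
):
    """Generate one (record, embedding, contact map) triple.

    The target is a class index (classification) or a melting temperature in
    degrees C (regression); it determines the class-mean component of every
    residue embedding.
    """
    L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    codes = rng.integers(0, len(AMINO_ACIDS), size=L)
    sequence = "".join(AMINO_ACIDS[c] for c in codes)
    mu = _class_mean(prototypes, spec, class_or_tm)
    emb = (
        prototypes.residue_vectors[codes]
        + mu
        + spec.noise_sd * rng.standard_normal((L, spec.F))
    )
    contact = _contact_map(L, spec, rng)
    rec = ProteinRecord(
        id=protein_id,
        sequence=sequence,
        residue_labels=codes.astype(np.int64),
        class_label=int(class_or_tm) if spec.task == "classification" else None,
        tm=float(class_or_tm) if spec.task == "regression" else None,
        split=split,
        n_classes=spec.n_classes if spec.task == "classification" else None,
    )
    return rec, EmbeddingMatrix(emb), ContactMap(contact)


def _assign_splits(n: int, rng: np.random.Generator) -> list[str]:
    """70/15/15 split by protein, reproducible from the generator state."""
    n_train = int(round(0.70 * n))
    n_valid = int(round(0.15 * n))
    tags = ["train"] * n_train + ["valid"] * n_valid + ["test"] * (n - n_train - n_valid)
    perm = rng.permutation(n)
    return [tags[k] for k in np.argsort(perm)]


def generate_dataset(spec: SyntheticSpec, path):
    """Generate a dataset container at ``path``; fully reproducible from seed.

    Classification targets are balanced to within one protein per class;
    regression melting temperatures are drawn uniformly inside each of the
    five bands (balanced across bands), hyperthermophilic capped at 95 C.
    """
    rng = np.random.default_rng(spec.seed)
    prototypes = DatasetPrototypes.create(spec, rng)
    n = spec.n_proteins
    if spec.task == "classification":
        targets = [c % spec.n_classes for c in range(n)]
    else:
        bands = [CLASS_BANDS_5[c % len(CLASS_BANDS_5)] for c in range(n)]
        targets = [rng.uniform(lo, hi) for lo, hi in bands]
    order = rng.permutation(n)
    targets = [targets[k] for k in order]
    splits = _assign_splits(n, rng)
    width = len(str(n - 1))
    triples = [
        generate_protein(
            spec, targets[i], rng, prototypes, protein_id=f"syn{i:0{width}d}",
            split=splits[i],
        )
        for i in range(n)
    ]
    save_dataset_container(
        path,
        triples,
        task=spec.task,
        n_classes=spec.n_classes if spec.task == "classification" else None,
    )
    return path


def check_separability(container_path) -> float:
    """Sanity floor: nearest-class-mean accuracy on mean-pooled raw embeddings.

    Fits class means on the train split and scores the test split; any
    trained model should beat this.  Raises on regression containers.
    """
    triples, task, n_classes = load_dataset_container(container_path)
    if task != "classification":
        raise ValueError("check_separability requires a classification container")
    pooled = {s: [] for s in ("train", "test")}
    labels = {s: [] for s in ("train", "test")}
    for rec, emb, _ in triples:
        if rec.split in pooled:
            pooled[rec.split].append(emb.values.mean(axis=0))
            labels[rec.split].append(rec.class_label)
    classes = sorted(set(labels["train"]))
    means = {
        c: np.mean(
            [v for v, y in zip(pooled["train"], labels["train"]) if y == c], axis=0
        )
        for c in classes
    }
    correct = 0
    for v, y in zip(pooled["test"], labels["test"]):
        dists = {c: np.linalg.norm(v - m) for c, m in means.items()}
        pred = min(sorted(dists), key=lambda c: dists[c])
        correct += int(pred == y)
    return correct / len(labels["test"])
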