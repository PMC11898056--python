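"""Domain types and I/O for thermostability datasets.

A dataset is a collection of proteins, each carrying

* the amino-acid sequence (and per-residue integer type codes),
* a per-residue embedding matrix ``P`` (L x F) as produced by a protein
  language model,
* a residue-residue contact map ``A`` (L x L, weights in [0, 1]) used as the
  weighted adjacency of the protein graph, and
* a target: either a thermostability class or a melting temperature in
  degrees Celsius, plus a train/valid/test split tag.

On disk a dataset is a single HDF5 container with one group per protein id
(datasets ``embedding`` float32 L x F and ``contact`` float32 L x L, and the
metadata as group attributes), mirrored by an in-file metadata table with
columns id, target, split, task.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "UNKNOWN_RESIDUE",
    "CLASS_NAMES_5",
    "CLASS_NAMES_2",
    "SPLITS",
    "ProteinRecord",
    "EmbeddingMatrix",
    "ContactMap",
    "Batch",
    "encode_residues",
    "decode_residues",
    "read_fasta",
    "validate_contact_map",
    "save_dataset_container",
    "load_dataset_container",
    "make_batch",
]

#: The 20 canonical amino-acid one-letter codes, alphabetical.  A residue's
#: integer code is its index here; anything else maps to UNKNOWN_RESIDUE.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_RESIDUE = -1

#: Thermostability classes ordered from coldest to hottest source organism.
CLASS_NAMES_5 = (
    "Cryophilic",
    "Psychrophilic",
    "Mesophilic",
    "Thermophilic",
    "Hyperthermophilic",
)
#: Binary split at 45 degrees C.
CLASS_NAMES_2 = ("cold", "hot")

SPLITS = ("train", "valid", "test")

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_residues(sequence: str) -> np.ndarray:
    """Map a sequence to integer residue-type codes.

    Canonical letters map to 0..19 (alphabetical); any other letter (e.g. the
    wildcard ``X``) maps to :data:`UNKNOWN_RESIDUE`.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    return np.array(
        [_CODE.get(aa, UNKNOWN_RESIDUE) for aa in sequence.upper()], dtype=np.int64
    )


def decode_residues(codes) -> str:
    """Inverse of :func:`encode_residues` for canonical codes (unknown -> X)."""
    return "".join(
        AMINO_ACIDS[c] if 0 <= c < len(AMINO_ACIDS) else "X" for c in codes
    )


@dataclasses.dataclass
class ProteinRecord:
    """One protein: sequence, residue codes, target and split tag.

    Exactly one of ``class_label`` / ``tm`` is set, matching the task
    (classification vs melting-temperature regression).
    """

    id: str
    sequence: str
    residue_labels: np.ndarray
    class_label: int | None = None
    tm: float | None = None
    split: str = "train"
    n_classes: int | None = None

    def __post_init__(self):
        self.residue_labels = np.asarray(self.residue_labels, dtype=np.int64)
        if len(self.residue_labels) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: residue_labels length "
                f"{len(self.residue_labels)} != sequence length {len(self.sequence)}"
            )
        if (self.class_label is None) == (self.tm is None):
            raise ValueError(
                f"record {self.id!r}: exactly one of class_label/tm must be set"
            )
        if self.class_label is not None and self.n_classes is not None:
            if not 0 <= self.class_label < self.n_classes:
                raise ValueError(
                    f"record {self.id!r}: class index {self.class_label} "
                    f"out of range for C={self.n_classes}"
                )
        if self.split not in SPLITS:
            raise ValueError(f"record {self.id!r}: unknown split {self.split!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def target(self) -> float:
        return float(self.class_label if self.class_label is not None else self.tm)

    @property
    def task(self) -> str:
        return "classification" if self.class_label is not None else "regression"


@dataclasses.dataclass
class EmbeddingMatrix:
    """Per-residue embedding matrix P of shape (L, F)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("embedding must be a 2-D (L, F) array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("embedding must have L >= 1 and F >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def F(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class ContactMap:
    """Symmetric L x L contact-strength matrix with entries in [0, 1]."""

    values: np.ndarray

    @property
    def L(self) -> int:
        return self.values.shape[0]


def validate_contact_map(values, tol: float = 1e-6) -> ContactMap:
    """Check and canonicalise a raw contact matrix.

    The matrix must be square, symmetric within ``tol`` (it is then replaced
    by ``(M + M.T) / 2``), with entries in [0, 1] up to a 1e-9 numerical
    slack (then clipped).
    """
    m = np.asarray(values, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"contact map must be square, got shape {m.shape}")
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > tol:
        raise ValueError(f"contact map asymmetry {asym:.3g} exceeds tolerance {tol:g}")
    m = (m + m.T) / 2.0
    if m.size and (m.min() < -1e-9 or m.max() > 1.0 + 1e-9):
        raise ValueError(
            f"contact values outside [0, 1]: min={m.min():.3g}, max={m.max():.3g}"
        )
    return ContactMap(np.clip(m, 0.0, 1.0))


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein sequences from a FASTA file.

    Sequences are upper-cased and residue codes populated; non-canonical
    letters are tolerated (coded as unknown) but non-alphabetic characters
    raise an error naming the offending record.  Records get no target; the
    caller attaches targets before the records enter a container.
    """
    path = Path(path)
    records = []
    for seq_record in SeqIO.parse(str(path), "fasta"):
        seq = str(seq_record.seq).upper()
        if not seq:
            raise ValueError(f"record {seq_record.id!r} has an empty sequence")
        bad = [ch for ch in seq if not ch.isalpha()]
        if bad:
            raise ValueError(
                f"record {seq_record.id!r} contains invalid characters: {bad!r}"
            )
        records.append(
            _UntargetedRecord(
                id=seq_record.id, sequence=seq, residue_labels=encode_residues(seq)
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


class _UntargetedRecord(ProteinRecord):
    """A ProteinRecord before a target is attached (FASTA input stage)."""

    def __post_init__(self):
        self.residue_labels = np.asarray(self.residue_labels, dtype=np.int64)
        if len(self.residue_labels) != len(self.sequence):
            raise ValueError(f"record {self.id!r}: label/sequence length mismatch")

    @property
    def task(self) -> str:
        return "untargeted"


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_dataset_container(path, triples, task: str, n_classes: int | None = None):
    """Write (record, embedding, contact) triples into one HDF5 container.

    Writing is deterministic: proteins are stored in the given order with
    HDF5 object timestamps disabled, so identical inputs produce
    byte-identical files.
    """
    path = Path(path)
    ids = [rec.id for rec, _, _ in triples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in container")
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["task"] = task
        if n_classes is not None:
            f.attrs["n_classes"] = int(n_classes)
        for rec, emb, cmap in triples:
            g = f.create_group(rec.id, track_order=True)
            g.create_dataset(
                "embedding", data=emb.values.astype(np.float32), track_times=False
            )
            g.create_dataset(
                "contact", data=cmap.values.astype(np.float32), track_times=False
            )
            g.attrs["sequence"] = rec.sequence
            g.attrs["split"] = rec.split
            g.attrs["target"] = rec.target
    return path


def load_dataset_container(path):
    """Load a container; returns (triples, task, n_classes).

    Every triple is validated against the type invariants; a shape mismatch
    between sequence, embedding and contact map raises an error naming the
    protein id.
    """
    path = Path(path)
    triples = []
    with h5py.File(path, "r") as f:
        task = f.attrs.get("task")
        if task is None:
            raise ValueError(f"container {path} lacks a task attribute")
        task = str(task)
        n_classes = int(f.attrs["n_classes"]) if "n_classes" in f.attrs else None
        for pid in f:
            g = f[pid]
            if "sequence" not in g.attrs or "target" not in g.attrs:
                raise ValueError(f"protein {pid!r}: missing metadata (target/sequence)")
            seq = str(g.attrs["sequence"])
            emb = EmbeddingMatrix(np.asarray(g["embedding"], dtype=np.float64))
            cmap = validate_contact_map(np.asarray(g["contact"], dtype=np.float64))
            if emb.L != len(seq) or cmap.L != len(seq):
                raise ValueError(
                    f"protein {pid!r}: length mismatch (sequence L={len(seq)}, "
                    f"embedding L={emb.L}, contact L={cmap.L})"
                )
            target = float(g.attrs["target"])
            rec = ProteinRecord(
                id=pid,
                sequence=seq,
                residue_labels=encode_residues(seq),
                class_label=int(target) if task == "classification" else None,
                tm=target if task == "regression" else None,
                split=str(g.attrs["split"]),
                n_classes=n_classes,
            )
            triples.append((rec, emb, cmap))
    return triples, task, n_classes


def metadata_table(triples, task: str):
    """Metadata as a pandas DataFrame with columns id, target, split, task."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.id for r, _, _ in triples],
            "target": [r.target for r, _, _ in triples],
            "split": [r.split for r, _, _ in triples],
            "task": task,
        }
    )


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Batch:
    """Padded protein batch with a validity mask.

    ``embeddings`` is (B, L_max, F), ``contacts`` is (B, L_max, L_max),
    ``mask`` is (B, L_max) booleans true exactly at valid residue positions;
    padded entries are zero.
    """

    records: list
    embeddings: np.ndarray
    contacts: np.ndarray
    mask: np.ndarray
    targets: np.ndarray

    def __len__(self) -> int:
        return len(self.records)


def make_batch(triples, batch_size: int, shuffle_seed: int | None = None):
    """Group triples into padded batches of at most ``batch_size`` proteins.

    Order is preserved unless ``shuffle_seed`` is given, in which case the
    triples are permuted reproducibly before batching.
    """
    if not triples:
        raise ValueError("cannot batch an empty dataset")
    triples = list(triples)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        triples = [triples[i] for i in rng.permutation(len(triples))]
    batches = []
    for start in range(0, len(triples), batch_size):
        chunk = triples[start : start + batch_size]
        lmax = max(rec.length for rec, _, _ in chunk)
        f_dim = chunk[0][1].F
        emb = np.zeros((len(chunk), lmax, f_dim))
        con = np.zeros((len(chunk), lmax, lmax))
        mask = np.zeros((len(chunk), lmax), dtype=bool)
        targets = np.empty(len(chunk))
        for i, (rec, e, c) in enumerate(chunk):
            L = rec.length
            emb[i, :L] = e.values
            con[i, :L, :L] = c.values
            mask[i, :L] = True
            targets[i] = rec.target
        batches.append(
            Batch(
                records=[rec for rec, _, _ in chunk],
                embeddings=emb,
                contacts=con,
                mask=mask,
                targets=targets,
            )
        )
    return batches
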