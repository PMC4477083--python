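"""Core bag/instance/multi-label containers and dataset I/O.

The multiple-instance view of symptom data: a patient is a *bag*, each of
their symptoms is an *instance* (a fixed-dimension numeric vector; by default
a one-hot indicator over the symptom vocabulary, optionally scaled by a
severity weight), and the bag carries a *set* of class labels (syndromes).
A bag is positive for a class exactly when the class is in its label set;
one-vs-rest views realise the small-positive / large-negative regime.

Datasets round-trip through JSON (nested, schema below) and a long-format
CSV (one row per bag x symptom, labels repeated per row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Instance",
    "Bag",
    "MILDataset",
    "BinaryView",
    "read_dataset",
    "write_dataset",
    "binary_view",
    "filter_min_instances",
    "presence_matrix",
]


class DatasetValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class Instance:
    """A single instance: a finite d-dimensional feature vector.

    ``symptom_id`` names the symptom the vector encodes (one-hot case);
    it is None for generic MIL data.
    """

    vector: np.ndarray
    symptom_id: str | None = None

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.ndim != 1 or vec.size < 1:
            raise DatasetValidationError("instance vector must be 1-D with d >= 1")
        if not np.all(np.isfinite(vec)):
            raise DatasetValidationError("instance vector has non-finite coordinates")
        object.__setattr__(self, "vector", vec)

    @property
    def dimension(self) -> int:
        return int(self.vector.shape[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Instance):
            return NotImplemented
        return self.symptom_id == other.symptom_id and np.array_equal(
            self.vector, other.vector
        )

    def __hash__(self) -> int:
        return hash((self.symptom_id, self.vector.tobytes()))


@dataclass(frozen=True)
class Bag:
    """One patient: an identifier, >= 1 instances, and a label set."""

    bag_id: str
    instances: tuple[Instance, ...]
    labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", tuple(self.instances))
        object.__setattr__(self, "labels", frozenset(self.labels))
        if len(self.instances) < 1:
            raise DatasetValidationError(f"bag {self.bag_id!r} has no instances")
        dims = {inst.dimension for inst in self.instances}
        if len(dims) > 1:
            raise DatasetValidationError(
                f"bag {self.bag_id!r} mixes instance dimensions {sorted(dims)}"
            )

    @property
    def dimension(self) -> int:
        return self.instances[0].dimension

    def instance_matrix(self) -> np.ndarray:
        """Stack the bag's instances into an (n_instances, d) array."""
        return np.stack([inst.vector for inst in self.instances])


@dataclass(frozen=True)
class MILDataset:
    """A multi-label MIL dataset with its class and symptom vocabularies."""

    bags: tuple[Bag, ...]
    class_vocabulary: tuple[str, ...]
    symptom_vocabulary: tuple[str, ...] = ()
    dimension: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bags", tuple(self.bags))
        object.__setattr__(self, "class_vocabulary", tuple(self.class_vocabulary))
        object.__setattr__(self, "symptom_vocabulary", tuple(self.symptom_vocabulary))
        if len(set(self.class_vocabulary)) != len(self.class_vocabulary):
            raise DatasetValidationError("duplicate class codes in vocabulary")
        if len(set(self.symptom_vocabulary)) != len(self.symptom_vocabulary):
            raise DatasetValidationError("duplicate symptom ids in vocabulary")
        dim = self.dimension
        if dim is None:
            if self.symptom_vocabulary:
                dim = len(self.symptom_vocabulary)
            elif self.bags:
                dim = self.bags[0].dimension
        object.__setattr__(self, "dimension", dim)
        ids = [b.bag_id for b in self.bags]
        if len(set(ids)) != len(ids):
            raise DatasetValidationError("duplicate bag ids")
        classes = set(self.class_vocabulary)
        for bag in self.bags:
            if dim is not None and bag.dimension != dim:
                raise DatasetValidationError(
                    f"bag {bag.bag_id!r} has dimension {bag.dimension}, expected {dim}"
                )
            unknown = bag.labels - classes
            if unknown:
                raise DatasetValidationError(
                    f"bag {bag.bag_id!r} carries unknown labels {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.bags)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MILDataset):
            return NotImplemented
        return (
            self.class_vocabulary == other.class_vocabulary
            and self.symptom_vocabulary == other.symptom_vocabulary
            and self.dimension == other.dimension
            and self.bags == other.bags
        )

    def bag_by_id(self, bag_id: str) -> Bag:
        for bag in self.bags:
            if bag.bag_id == bag_id:
                return bag
        raise KeyError(bag_id)


@dataclass(frozen=True)
class BinaryView:
    """One-vs-rest view of a multi-label dataset for one target class."""

    target_class: str
    positive_bags: tuple[Bag, ...]
    negative_bags: tuple[Bag, ...]

    @property
    def n_positive(self) -> int:
        return len(self.positive_bags)

    @property
    def n_negative(self) -> int:
        return len(self.negative_bags)

    def all_bags(self) -> tuple[Bag, ...]:
        return self.positive_bags + self.negative_bags


def one_hot_instance(
    symptom: str, vocabulary: Sequence[str], severity: float = 1.0
) -> Instance:
    """Encode a symptom as a one-hot vector scaled by ``severity`` in [0, 1]."""
    vec = np.zeros(len(vocabulary), dtype=float)
    try:
        vec[list(vocabulary).index(symptom)] = float(severity)
    except ValueError:
        raise DatasetValidationError(f"symptom {symptom!r} not in vocabulary") from None
    return Instance(vector=vec, symptom_id=symptom)


def binary_view(
    dataset: MILDataset, target_class: str, *, multilabel_negatives: str = "include"
) -> BinaryView:
    """Partition labeled bags into positives (carry ``target_class``) and the rest.

    ``multilabel_negatives="exclude"`` drops bags with >= 2 labels from the
    negative side (they remain positive when they carry the target), trading
    the partition property for cleaner negatives.
    """
    if target_class not in dataset.class_vocabulary:
        raise KeyError(f"unknown class code {target_class!r}")
    pos, neg = [], []
    for bag in dataset.bags:
        if target_class in bag.labels:
            pos.append(bag)
        elif multilabel_negatives == "include" or len(bag.labels) < 2:
            neg.append(bag)
    return BinaryView(target_class, tuple(pos), tuple(neg))


def filter_min_instances(dataset: MILDataset, min_instances: int = 2) -> MILDataset:
    """Inclusion filter: keep only bags with at least ``min_instances`` instances."""
    kept = tuple(b for b in dataset.bags if len(b.instances) >= min_instances)
    return MILDataset(
        kept, dataset.class_vocabulary, dataset.symptom_vocabulary, dataset.dimension
    )


def presence_matrix(dataset: MILDataset, bags: Sequence[Bag] | None = None) -> np.ndarray:
    """Bag-level feature summary: coordinate-wise max over each bag's instances.

    For one-hot symptom data this is the (n_bags, d) symptom presence/severity
    indicator matrix used by the bag-level baseline classifiers.
    """
    use = dataset.bags if bags is None else bags
    if not use:
        return np.zeros((0, dataset.dimension or 0))
    return np.stack([bag.instance_matrix().max(axis=0) for bag in use])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _bag_to_json(bag: Bag, vocab: Sequence[str]) -> dict:
    instances: list = []
    for inst in bag.instances:
        if inst.symptom_id is not None and list(vocab):
            sev = float(inst.vector.max()) if inst.vector.size else 1.0
            instances.append({"symptom": inst.symptom_id, "severity": sev})
        else:
            instances.append([float(x) for x in inst.vector])
    return {"id": bag.bag_id, "labels": sorted(bag.labels), "instances": instances}


def _bag_from_json(rec: dict, vocab: Sequence[str], dim: int | None) -> Bag:
    try:
        instances = []
        for item in rec["instances"]:
            if isinstance(item, dict):
                instances.append(
                    one_hot_instance(item["symptom"], vocab, item.get("severity", 1.0))
                )
            else:
                instances.append(Instance(np.asarray(item, dtype=float)))
        return Bag(str(rec["id"]), tuple(instances), frozenset(rec.get("labels", [])))
    except (KeyError, TypeError, ValueError) as exc:
        raise DatasetValidationError(
            f"malformed bag record {rec.get('id', '<missing id>')!r}: {exc}"
        ) from exc


def write_dataset(dataset: MILDataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset to ``path`` as JSON or long-format CSV."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        payload = {
            "classes": list(dataset.class_vocabulary),
            "symptoms": list(dataset.symptom_vocabulary),
            "dimension": dataset.dimension,
            "bags": [_bag_to_json(b, dataset.symptom_vocabulary) for b in dataset.bags],
        }
        path.write_text(json.dumps(payload, ensure_ascii=False, indent=1))
    elif fmt == "csv":
        if not dataset.symptom_vocabulary:
            raise DatasetValidationError(
                "CSV format requires symptom-encoded data (non-empty symptom vocabulary)"
            )
        rows = []
        for bag in dataset.bags:
            labels = ";".join(sorted(bag.labels))
            for inst in bag.instances:
                rows.append(
                    {
                        "bag_id": bag.bag_id,
                        "symptom": inst.symptom_id,
                        "severity": float(inst.vector.max()),
                        "labels": labels,
                    }
                )
        frame = pd.DataFrame(rows, columns=["bag_id", "symptom", "severity", "labels"])
        with path.open("w", encoding="utf-8") as fh:
            fh.write("# classes: " + ";".join(dataset.class_vocabulary) + "\n")
            fh.write("# symptoms: " + ";".join(dataset.symptom_vocabulary) + "\n")
            frame.to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_dataset(path: str | Path, format: str | None = None) -> MILDataset:
    """Read and validate a dataset written by :func:`write_dataset`."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        payload = json.loads(path.read_text())
        vocab = payload.get("symptoms", [])
        dim = payload.get("dimension")
        bags = tuple(_bag_from_json(rec, vocab, dim) for rec in payload.get("bags", []))
        return MILDataset(bags, tuple(payload.get("classes", [])), tuple(vocab), dim)
    if fmt == "csv":
        with path.open("r", encoding="utf-8") as fh:
            header = [fh.readline(), fh.readline()]
            classes = header[0].split(":", 1)[1].strip().split(";") if ":" in header[0] else []
            symptoms = header[1].split(":", 1)[1].strip().split(";") if ":" in header[1] else []
            classes = [c for c in classes if c]
            symptoms = [s for s in symptoms if s]
            frame = pd.read_csv(fh, dtype={"bag_id": str, "symptom": str, "labels": str})
        bags = []
        for bag_id, grp in frame.groupby("bag_id", sort=False):
            labels = grp["labels"].iloc[0]
            label_set = frozenset(x for x in str(labels).split(";") if x and x != "nan")
            instances = tuple(
                one_hot_instance(row.symptom, symptoms, row.severity)
                for row in grp.itertuples()
            )
            bags.append(Bag(str(bag_id), instances, label_set))
        return MILDataset(tuple(bags), tuple(classes), tuple(symptoms))
    raise ValueError(f"unknown format {fmt!r}")


def from_long_frame(
    frame: pd.DataFrame,
    class_vocabulary: Iterable[str] | None = None,
    symptom_vocabulary: Iterable[str] | None = None,
) -> MILDataset:
    """Build a dataset from a long-format DataFrame (bag_id, symptom, severity, labels)."""
    if symptom_vocabulary is None:
        symptom_vocabulary = sorted(frame["symptom"].unique())
    symptom_vocabulary = tuple(symptom_vocabulary)
    bags = []
    seen_labels: set[str] = set()
    for bag_id, grp in frame.groupby("bag_id", sort=False):
        label_set = frozenset(
            x for x in str(grp["labels"].iloc[0]).split(";") if x and x != "nan"
        )
        seen_labels |= label_set
        sev = grp["severity"] if "severity" in grp else pd.Series(1.0, index=grp.index)
        instances = tuple(
            one_hot_instance(s, symptom_vocabulary, w)
            for s, w in zip(grp["symptom"], sev)
        )
        bags.append(Bag(str(bag_id), instances, label_set))
    if class_vocabulary is None:
        class_vocabulary = sorted(seen_labels)
    return MILDataset(tuple(bags), tuple(class_vocabulary), symptom_vocabulary)
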