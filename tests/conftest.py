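"""Shared fixtures: tiny hand-built bag collections and symptom datasets."""

from __future__ import annotations

import numpy as np
import pytest

from mrsmil.data_model import Bag, Instance, MILDataset, one_hot_instance


def vector_bag(bag_id: str, points, labels=()) -> Bag:
    """Bag of raw-vector instances from a list of coordinate tuples."""
    return Bag(
        bag_id,
        tuple(Instance(np.asarray(p, dtype=float)) for p in points),
        frozenset(labels),
    )


def symptom_bag(bag_id: str, symptoms, vocab, labels=()) -> Bag:
    return Bag(
        bag_id,
        tuple(one_hot_instance(s, vocab) for s in symptoms),
        frozenset(labels),
    )


@pytest.fixture
def vocab3():
    return ("fever", "cough", "rash")


@pytest.fixture
def tiny_dataset(vocab3):
    """Two-class, three-symptom dataset with one co-labeled bag."""
    bags = (
        symptom_bag("p1", ["fever", "cough"], vocab3, {"C1"}),
        symptom_bag("p2", ["fever"], vocab3, {"C1", "C2"}),
        symptom_bag("p3", ["rash"], vocab3, {"C2"}),
        symptom_bag("p4", ["rash", "cough"], vocab3, {"C2"}),
        symptom_bag("p5", ["cough"], vocab3, {"C1"}),
    )
    return MILDataset(bags, ("C1", "C2"), vocab3)


@pytest.fixture
def two_cluster_bags():
    """Five positive bags near (0,0) and five negative bags near (10,10)."""
    rng = np.random.default_rng(42)
    pos = [
        vector_bag(f"p{i}", [rng.normal(0.0, 0.3, size=2) for _ in range(2)])
        for i in range(5)
    ]
    neg = [
        vector_bag(f"n{i}", [rng.normal(10.0, 0.3, size=2) for _ in range(2)])
        for i in range(5)
    ]
    return pos, neg
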