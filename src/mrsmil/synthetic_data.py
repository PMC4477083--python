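"""Synthetic multi-label symptom-syndrome bag generator with known ground truth.

The generator emulates a clinical symptom-survey regime: a vocabulary of 88
binary symptoms, 7 syndrome classes, each with a planted symptom signature
of ~10 symptoms, adjacent class signatures partially overlapping, and every
patient (bag) carrying one to three syndrome labels. A patient expresses
each signature symptom of each of their assigned syndromes with probability
``expression_prob`` (class-OR semantics: a symptom appears if any assigned
class expresses it) and every other symptom with probability ``noise_rate``;
patients with fewer than two symptoms are resampled, mirroring the usual
"at least two explicit symptoms" inclusion criterion.

Because signatures are planted, every pipeline stage has a ground truth to
recover: selected representative symptoms can be scored against the planted
signatures, and classification against the sampled label sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .data_model import Bag, Instance, MILDataset

__all__ = ["GeneratorConfig", "SweepPreset", "GroundTruth", "generate", "presets"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    label_rate is the Poisson rate of *extra* labels per bag: the label-set
    size is 1 + min(Poisson(label_rate), max_labels - 1), i.e. 1 + a Poisson
    draw truncated so the total stays within [1, max_labels].
    """

    n_classes: int = 7
    n_symptoms: int = 88
    signature_size: int = 10
    overlap_fraction: float = 0.2
    n_bags: int = 500
    label_rate: float = 0.8
    max_labels: int = 3
    expression_prob: float = 0.8
    noise_rate: float = 0.05
    min_symptoms: int = 2
    severity: str = "binary"  # "binary" (1.0) or "beta" (Beta(4,2) draws)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signature_size > self.n_symptoms:
            raise ValueError("signature_size exceeds n_symptoms")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        for p in (self.expression_prob, self.noise_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def class_codes(self) -> tuple[str, ...]:
        return tuple(f"C{i + 1}" for i in range(self.n_classes))

    @property
    def symptom_codes(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_symptoms))


@dataclass(frozen=True)
class SweepPreset:
    """A base configuration swept over a list of cohort sizes."""

    base: GeneratorConfig
    sizes: tuple[int, ...]

    def __iter__(self) -> Iterator[GeneratorConfig]:
        for n in self.sizes:
            yield replace(self.base, n_bags=n)


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-class signatures and the sampled per-bag label sets."""

    signatures: dict[str, frozenset[str]]
    labels: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for c, sig in self.signatures.items():
            if not sig:
                raise ValueError(f"empty signature for class {c}")
        for b, labs in self.labels.items():
            if not labs:
                raise ValueError(f"empty label set for bag {b}")


def _plant_signatures(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[str, frozenset[str]]:
    """Chain construction: class i shares round(overlap * size) symptoms with
    class i-1's signature; the remainder is drawn from symptoms unused so far."""
    overlap = int(round(cfg.overlap_fraction * cfg.signature_size))
    fresh_needed = cfg.signature_size + (cfg.n_classes - 1) * (cfg.signature_size - overlap)
    if fresh_needed > cfg.n_symptoms:
        raise ValueError(
            f"infeasible signatures: need {fresh_needed} distinct symptoms, "
            f"vocabulary has {cfg.n_symptoms}"
        )
    symptoms = list(cfg.symptom_codes)
    unused = list(symptoms)
    rng.shuffle(unused)
    signatures: dict[str, frozenset[str]] = {}
    prev: list[str] = []
    for i, c in enumerate(cfg.class_codes):
        if i == 0 or overlap == 0:
            take = cfg.signature_size
            shared: list[str] = []
        else:
            shared = [str(s) for s in rng.choice(prev, size=overlap, replace=False)]
            take = cfg.signature_size - overlap
        fresh = [unused.pop() for _ in range(take)]
        sig = shared + fresh
        signatures[c] = frozenset(sig)
        prev = sorted(sig)
    return signatures


def _sample_bag_symptoms(
    label_set: tuple[str, ...],
    signatures: dict[str, frozenset[str]],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[str]:
    expressed = set()
    for c in label_set:
        for s in sorted(signatures[c]):
            if rng.random() < cfg.expression_prob:
                expressed.add(s)
    signature_union = set().union(*(signatures[c] for c in label_set))
    for s in cfg.symptom_codes:
        if s not in signature_union and rng.random() < cfg.noise_rate:
            expressed.add(s)
    return sorted(expressed)


def generate(config: GeneratorConfig) -> tuple[MILDataset, GroundTruth]:
    """Generate a dataset and its ground truth; fully reproducible from the seed."""
    for attempt in range(10):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, attempt]))
        signatures = _plant_signatures(config, rng)
        bags: list[Bag] = []
        labels: dict[str, frozenset[str]] = {}
        classes = list(config.class_codes)
        vocab = config.symptom_codes
        index = {s: i for i, s in enumerate(vocab)}
        for b in range(config.n_bags):
            n_labels = 1 + min(int(rng.poisson(config.label_rate)), config.max_labels - 1)
            n_labels = min(n_labels, config.n_classes)
            label_set = tuple(
                sorted(str(c) for c in rng.choice(classes, size=n_labels, replace=False))
            )
            symptoms = _sample_bag_symptoms(label_set, signatures, config, rng)
            while len(symptoms) < config.min_symptoms:
                symptoms = _sample_bag_symptoms(label_set, signatures, config, rng)
            instances = []
            for s in symptoms:
                sev = 1.0 if config.severity == "binary" else float(rng.beta(4.0, 2.0))
                vec = np.zeros(len(vocab))
                vec[index[s]] = sev
                instances.append(Instance(vec, symptom_id=s))
            bag_id = f"B{b:04d}"
            bags.append(Bag(bag_id, tuple(instances), frozenset(label_set)))
            labels[bag_id] = frozenset(label_set)
        positives = {c: sum(1 for bag in bags if c in bag.labels) for c in classes}
        if all(v > 0 for v in positives.values()):
            dataset = MILDataset(tuple(bags), config.class_codes, vocab)
            return dataset, GroundTruth(signatures, labels)
    raise RuntimeError(
        "could not generate a dataset with every class represented; "
        "increase n_bags or reduce n_classes"
    )


def presets() -> dict[str, GeneratorConfig | SweepPreset]:
    """Named study conditions.

    easy : fully separable sanity regime — single-label bags, every
        signature symptom expressed, no noise, no overlap.
    paper-like : the default overlapping, noisy, multi-label regime.
    hard : heavier overlap (0.4) and noise (0.1).
    small-sample : the easy regime swept over cohort sizes 100..2000.
    """
    easy = GeneratorConfig(
        overlap_fraction=0.0, label_rate=0.0, expression_prob=1.0, noise_rate=0.0
    )
    return {
        "easy": easy,
        "paper-like": GeneratorConfig(),
        "hard": GeneratorConfig(overlap_fraction=0.4, noise_rate=0.1),
        "small-sample": SweepPreset(
            base=easy, sizes=(100, 200, 400, 600, 800, 1000, 1500, 2000)
        ),
    }
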