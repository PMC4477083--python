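"""Top-K maximum-posterior differentiation and the multi-label evaluation.

Each fitted class model supplies a likelihood for a test bag (the mixture
density of the bag's embedding on that class's prototypes); Bayes' rule
combines it with the class prior and the K highest-posterior classes are
assigned to the bag (K = 3 by default, matching a 7-class syndrome panel).

Evaluation follows the per-class A/B/C counting convention:
A = bags assigned the class within their top-K, B = of those, bags truly
carrying the class, C = bags carrying the class in ground truth;
precision = B/A, recall = B/C, macro averages over classes with C > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.naive_bayes import BernoulliNB

from .data_model import Bag, MILDataset, presence_matrix
from .manifold_ranking import MRParams
from .representative_selection import SelectionConfig
from .syndrome_gmm import ClassModel, GMMConfig
from .representative_selection import embed_bags

logger = logging.getLogger(__name__)

__all__ = [
    "RankingResult",
    "ClassCounts",
    "EvaluationReport",
    "ExperimentConfig",
    "bag_score",
    "posterior",
    "predict_dataset",
    "evaluate",
    "run_experiment",
    "naive_bayes_baseline",
]


@dataclass(frozen=True)
class RankingResult:
    """Per-bag normalised class posterior and the ordered top-K classes."""

    bag_id: str
    posterior: dict[str, float]
    top_k: tuple[str, ...]

    def __post_init__(self) -> None:
        total = sum(self.posterior.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior sums to {total}, expected 1")


@dataclass(frozen=True)
class ClassCounts:
    """The per-class A/B/C counts behind precision and recall."""

    A: int  # bags assigned the class in their top-K
    B: int  # of those, correct (class in ground truth)
    C: int  # bags carrying the class in ground truth

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C) < 0 or self.B > min(self.A, self.C):
            raise ValueError("counts must satisfy 0 <= B <= min(A, C)")

    @property
    def precision(self) -> float:
        return self.B / self.A if self.A > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.B / self.C if self.C > 0 else 0.0


@dataclass(frozen=True)
class EvaluationReport:
    counts: dict[str, ClassCounts]
    precision: dict[str, float]
    recall: dict[str, float]
    macro_precision: float
    macro_recall: float
    flagged: tuple[str, ...]  # classes with A == 0 or C == 0

    def to_dict(self) -> dict:
        return {
            "counts": {c: asdict(v) for c, v in sorted(self.counts.items())},
            "precision": {c: self.precision[c] for c in sorted(self.precision)},
            "recall": {c: self.recall[c] for c in sorted(self.recall)},
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "flagged": sorted(self.flagged),
        }


def bag_score(model: ClassModel, bag: Bag) -> float:
    """Class likelihood of a bag: mixture density at the bag's embedding."""
    return float(np.exp(_log_bag_score(model, bag)))


def _log_bag_score(model: ClassModel, bag: Bag) -> float:
    E = embed_bags([bag], model.representatives.prototypes,
                   model.representatives.embedding_sigma)
    return float(model.gmm.logpdf(E)[0])


def posterior(
    models: Sequence[ClassModel],
    bag: Bag,
    K: int = 3,
    class_order: Sequence[str] | None = None,
) -> RankingResult:
    """Bayes posterior over classes for one bag, plus its top-K classes.

    posterior(c) is proportional to prior(c) * likelihood_c(bag), computed in
    log space. If every likelihood underflows to zero the posterior falls
    back to the normalised priors. Ties in the ranking break by class
    vocabulary order.
    """
    if not models:
        raise ValueError("no class models given")
    classes = [m.target_class for m in models]
    order = {c: i for i, c in enumerate(class_order or classes)}
    logp = np.array(
        [np.log(m.prior) + _log_bag_score(m, bag) for m in models]
    )
    if not np.any(np.isfinite(logp)):
        logp = np.log(np.array([m.prior for m in models]))
    from scipy.special import logsumexp

    post = np.exp(logp - logsumexp(logp))
    post = post / post.sum()
    ranked = sorted(range(len(models)), key=lambda i: (-post[i], order[classes[i]]))
    top = tuple(classes[i] for i in ranked[: min(K, len(models))])
    return RankingResult(bag.bag_id, dict(zip(classes, map(float, post))), top)


def predict_dataset(
    models: Sequence[ClassModel],
    bags: Sequence[Bag],
    K: int = 3,
    class_order: Sequence[str] | None = None,
) -> list[RankingResult]:
    return [posterior(models, bag, K=K, class_order=class_order) for bag in bags]


def evaluate(
    results: Sequence[RankingResult],
    truth: Sequence[Bag],
    K: int = 3,
    classes: Sequence[str] | None = None,
) -> EvaluationReport:
    """Score top-K predictions against labeled bags via the A/B/C counts."""
    truth_by_id = {b.bag_id: b for b in truth}
    if classes is None:
        classes = sorted({c for b in truth for c in b.labels})
    for res in results:
        if res.bag_id not in truth_by_id:
            raise KeyError(f"prediction for unknown bag {res.bag_id!r}")
    counts: dict[str, ClassCounts] = {}
    flagged: list[str] = []
    for c in classes:
        A = B = 0
        for res in results:
            if c in res.top_k[:K]:
                A += 1
                if c in truth_by_id[res.bag_id].labels:
                    B += 1
        C = sum(1 for res in results if c in truth_by_id[res.bag_id].labels)
        counts[c] = ClassCounts(A, B, C)
        if A == 0 or C == 0:
            flagged.append(c)
    precision = {c: counts[c].precision for c in classes}
    recall = {c: counts[c].recall for c in classes}
    scored = [c for c in classes if counts[c].C > 0]
    macro_p = float(np.mean([precision[c] for c in scored])) if scored else 0.0
    macro_r = float(np.mean([recall[c] for c in scored])) if scored else 0.0
    return EvaluationReport(counts, precision, recall, macro_p, macro_r, tuple(flagged))


@dataclass(frozen=True)
class ExperimentConfig:
    """Repeated random-split evaluation protocol (default: 80/20, 10 repeats)."""

    repeats: int = 10
    test_fraction: float = 0.2
    top_k: int = 3
    mr_params: MRParams = field(default_factory=MRParams)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    gmm: GMMConfig = field(default_factory=GMMConfig)


def _split(
    dataset: MILDataset, test_fraction: float, rng: np.random.Generator
) -> tuple[list[Bag], list[Bag]]:
    n = len(dataset.bags)
    n_test = max(1, int(round(test_fraction * n)))
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [b for i, b in enumerate(dataset.bags) if i not in test_idx]
    test = [b for i, b in enumerate(dataset.bags) if i in test_idx]
    return train, test


def run_experiment(
    dataset: MILDataset,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> dict:
    """Repeat (split -> select -> fit -> classify -> evaluate) and aggregate.

    Returns a JSON-serialisable report with per-class and macro
    precision/recall means and standard deviations over the repeats. Classes
    with fewer than two positive training bags in a repeat are skipped in
    that repeat (and recorded).
    """
    from .model import MRSMIL  # local import: model builds on this module

    cfg = config or ExperimentConfig()
    per_repeat: list[dict] = []
    skipped: list[list[str]] = []
    for rep in range(cfg.repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1, rep]))
        train, test = _split(dataset, cfg.test_fraction, rng)
        train_ds = MILDataset(
            tuple(train), dataset.class_vocabulary,
            dataset.symptom_vocabulary, dataset.dimension,
        )
        model = MRSMIL(
            train_ds, top_k=cfg.top_k, mr_params=cfg.mr_params,
            selection=cfg.selection, gmm=cfg.gmm,
        )
        fit = model.fit(seed=int(np.random.SeedSequence([seed, 2, rep]).generate_state(1)[0] % (2**31)))
        skipped.append(sorted(fit.skipped_classes))
        if fit.skipped_classes:
            logger.info("repeat %d: skipped classes %s", rep, sorted(fit.skipped_classes))
        results = fit.predict(test)
        report = evaluate(results, test, K=cfg.top_k, classes=fit.fitted_classes)
        per_repeat.append(report.to_dict())
    return _aggregate_report(dataset, per_repeat, skipped, seed, cfg, method="mrs-mil")


def naive_bayes_baseline(
    dataset: MILDataset,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> dict:
    """Comparison arm: per-class Bernoulli naive Bayes on bag-level symptom
    indicators, ranked top-K by one-vs-rest posterior. Same protocol and
    report schema as :func:`run_experiment`."""
    cfg = config or ExperimentConfig()
    per_repeat: list[dict] = []
    skipped: list[list[str]] = []
    for rep in range(cfg.repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1, rep]))
        train, test = _split(dataset, cfg.test_fraction, rng)
        X_train = presence_matrix(dataset, train) > 0
        X_test = presence_matrix(dataset, test) > 0
        fitted: dict[str, BernoulliNB] = {}
        skip: list[str] = []
        for c in dataset.class_vocabulary:
            y = np.array([1 if c in b.labels else 0 for b in train])
            if y.sum() < 2 or y.sum() == len(y):
                skip.append(c)
                continue
            clf = BernoulliNB(alpha=1.0)
            clf.fit(X_train, y)
            fitted[c] = clf
        skipped.append(sorted(skip))
        classes = list(fitted)
        scores = np.column_stack(
            [fitted[c].predict_log_proba(X_test)[:, 1] for c in classes]
        )
        vocab_rank = {c: i for i, c in enumerate(dataset.class_vocabulary)}
        results = []
        for i, bag in enumerate(test):
            row = scores[i]
            ranked = sorted(
                range(len(classes)), key=lambda j: (-row[j], vocab_rank[classes[j]])
            )
            top = tuple(classes[j] for j in ranked[: cfg.top_k])
            p = np.exp(row - row.max())
            p = p / p.sum()
            results.append(RankingResult(bag.bag_id, dict(zip(classes, map(float, p))), top))
        report = evaluate(results, test, K=cfg.top_k, classes=classes)
        per_repeat.append(report.to_dict())
    return _aggregate_report(dataset, per_repeat, skipped, seed, cfg, method="naive-bayes")


def _aggregate_report(
    dataset: MILDataset,
    per_repeat: list[dict],
    skipped: list[list[str]],
    seed: int,
    cfg: ExperimentConfig,
    method: str,
) -> dict:
    classes = sorted({c for rep in per_repeat for c in rep["precision"]})
    per_class = {}
    for c in classes:
        ps = [rep["precision"][c] for rep in per_repeat if c in rep["precision"]]
        rs = [rep["recall"][c] for rep in per_repeat if c in rep["recall"]]
        per_class[c] = {
            "precision_mean": float(np.mean(ps)),
            "precision_std": float(np.std(ps)),
            "recall_mean": float(np.mean(rs)),
            "recall_std": float(np.std(rs)),
        }
    macro_p = [rep["macro_precision"] for rep in per_repeat]
    macro_r = [rep["macro_recall"] for rep in per_repeat]
    return {
        "method": method,
        "seed": seed,
        "config": {
            "repeats": cfg.repeats,
            "test_fraction": cfg.test_fraction,
            "top_k": cfg.top_k,
        },
        "n_bags": len(dataset.bags),
        "classes": classes,
        "per_class": per_class,
        "macro_precision_mean": float(np.mean(macro_p)),
        "macro_precision_std": float(np.std(macro_p)),
        "macro_recall_mean": float(np.mean(macro_r)),
        "macro_recall_std": float(np.std(macro_r)),
        "skipped_classes": skipped,
        "per_repeat": per_repeat,
    }


def run_sweep(
    sizes: Sequence[int],
    generator_config,
    experiment: ExperimentConfig | None = None,
    repeats: int = 3,
    seed: int = 0,
) -> dict:
    """Precision-vs-sample-size curve: rerun the experiment at each dataset
    size (fresh data from the generator each time, same base seed)."""
    from dataclasses import replace as _replace

    from .synthetic_data import generate

    cfg = experiment or ExperimentConfig()
    cfg = _replace(cfg, repeats=repeats)
    curve = []
    for idx, n in enumerate(sizes):
        gen_cfg = _replace(generator_config, n_bags=int(n), seed=seed)
        dataset, _ = generate(gen_cfg)
        report = run_experiment(dataset, cfg, seed=seed + idx)
        curve.append(
            {
                "n_bags": int(n),
                "macro_precision": report["macro_precision_mean"],
                "macro_recall": report["macro_recall_mean"],
            }
        )
    return {"seed": seed, "repeats": repeats, "curve": curve}
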