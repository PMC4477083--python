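"""Per-class representative-instance (symptom) selection.

A candidate prototype set maps every bag into a similarity feature space —
coordinate j of a bag is the best match of any of its instances to
prototype j under a Gaussian kernel (the most-similar-instance embedding
used throughout the embedded-instance-selection MIL family). Each candidate
set is scored by the size of the minimum reference set obtained in that
embedded space: a prototype set under which few labeled bags suffice to
separate the class from the rest is a good symptom signature for the class.

The search is greedy forward selection over candidate symptoms (ranked by
positive-bag frequency), with early stopping once the MRS size stops
shrinking. For large collections, scoring uses a deterministic stratified
subsample of the labeled bags; the reference-set construction is designed
to be insensitive to the number of labeled bags, which is what makes the
capped scoring sound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import Bag, BinaryView, Instance
from .manifold_ranking import MRParams
from .mrs import generate_mrs_from_points, mrs_size

__all__ = [
    "SelectionConfig",
    "RepresentativeInstanceSet",
    "candidate_prototypes",
    "embed_bags",
    "median_embedding_sigma",
    "score_candidate_set",
    "select_representatives",
    "selected_precision",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the greedy representative-symptom search.

    max_prototypes : hard cap on the selected set size.
    patience : stop after this many consecutive steps without a strictly
        smaller MRS.
    max_candidates : candidate pool size (top symptoms by positive-bag
        frequency) examined at the first step.
    refine_pool : pool retained after the first step, ranked by the
        first-step MRS scores.
    max_scoring_bags : cap on the number of labeled bags used to score
        candidate sets; a stratified subsample is drawn deterministically
        from the selection seed when the collection is larger.
    pool_ranking : how candidates are admitted to the pool. "lift" ranks by
        the smoothed ratio of positive-bag to negative-bag frequency — the
        instances the method is after are exactly those dense among
        positives and sparse among negatives, and under multi-label
        co-occurrence raw positive frequency also admits other classes'
        signature symptoms. "frequency" uses raw positive-bag frequency.
    strategy : "ranked" (default) scores the nested prefixes of the pool
        order and returns the prefix with the smallest MRS; "greedy" re-scores
        every remaining candidate at every step and adds the one minimising
        the MRS size. Ranked search is preferred because the MRS size is
        nearly flat (saturated) for very small prototype sets, where
        step-wise greedy choices degenerate into noise-chasing; the density
        ranking supplies the order and the MRS criterion picks the set.
    """

    max_prototypes: int = 15
    patience: int = 2
    max_candidates: int = 30
    refine_pool: int = 20
    max_scoring_bags: int = 300
    pool_ranking: str = "lift"  # "lift" (pos/neg frequency ratio) or "frequency"
    strategy: str = "ranked"  # "ranked" (prefixes of the pool order) or "greedy"


@dataclass(frozen=True)
class RepresentativeInstanceSet:
    """Selected prototypes for one class plus the MRS size they achieved."""

    target_class: str
    prototypes: tuple[Instance, ...]
    mrs_size: int
    embedding_sigma: float
    trace: tuple[tuple[int, str | None, int], ...] = ()  # (step, symptom, score)

    @property
    def symptom_ids(self) -> frozenset[str]:
        return frozenset(p.symptom_id for p in self.prototypes if p.symptom_id)


def candidate_prototypes(view: BinaryView) -> list[Instance]:
    """Distinct instances of the positive bags, by descending bag frequency.

    Ties break on symptom id (then on the raw vector for id-less instances),
    so the ordering is deterministic.
    """
    if not view.positive_bags:
        raise ValueError("positive bags are empty")
    freq: dict[Instance, int] = {}
    for bag in view.positive_bags:
        for inst in set(bag.instances):
            freq[inst] = freq.get(inst, 0) + 1
    return sorted(
        freq,
        key=lambda inst: (
            -freq[inst],
            inst.symptom_id if inst.symptom_id is not None else "",
            tuple(inst.vector),
        ),
    )


def median_embedding_sigma(
    bags: Sequence[Bag], prototypes: Sequence[Instance]
) -> float:
    """Median nonzero instance-to-prototype distance (fallback 1.0)."""
    X = np.concatenate([b.instance_matrix() for b in bags])
    P = np.stack([p.vector for p in prototypes])
    d = cdist(X, P).ravel()
    nonzero = d[d > 0]
    return float(np.median(nonzero)) if nonzero.size else 1.0


def embed_bags(
    bags: Sequence[Bag], prototypes: Sequence[Instance], sigma: float
) -> np.ndarray:
    """Most-similar-instance embedding: (n_bags, n_prototypes) array with
    entry [i, j] = max_{x in bag i} exp(-||x - prototype_j||^2 / sigma^2)."""
    if not prototypes:
        raise ValueError("prototype list is empty")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    P = np.stack([p.vector for p in prototypes])
    X = np.concatenate([b.instance_matrix() for b in bags])
    counts = np.array([len(b.instances) for b in bags])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    K = np.exp(-(cdist(X, P) ** 2) / sigma**2)
    out = np.empty((len(bags), len(prototypes)))
    for i in range(len(bags)):
        out[i] = K[offsets[i] : offsets[i + 1]].max(axis=0)
    return out


def score_candidate_set(
    prototypes: Sequence[Instance],
    view: BinaryView,
    params: MRParams,
    sigma: float | None = None,
    size_limit: int | None = None,
) -> int:
    """MRS size in the embedding induced by ``prototypes`` (lower = better)."""
    bags = view.all_bags()
    if sigma is None:
        sigma = median_embedding_sigma(bags, prototypes)
    E = embed_bags(bags, prototypes, sigma)
    refset = generate_mrs_from_points(
        E[: view.n_positive], E[view.n_positive :], params, size_limit=size_limit
    )
    return mrs_size(refset)


def _candidate_pool(view: BinaryView, cfg: SelectionConfig) -> list[Instance]:
    """Admit the top ``max_candidates`` candidates into the search pool.

    Under "lift" ranking, a candidate's score is the ratio of its positive-
    bag frequency to its negative-bag frequency (both Laplace-smoothed):
    high-lift instances are dense among positive bags and sparse among
    negative ones, which is the stated selection target.
    """
    candidates = candidate_prototypes(view)
    if cfg.pool_ranking == "frequency":
        return candidates[: cfg.max_candidates]
    neg_freq: dict[Instance, int] = {}
    for bag in view.negative_bags:
        for inst in set(bag.instances):
            neg_freq[inst] = neg_freq.get(inst, 0) + 1
    pos_freq: dict[Instance, int] = {}
    for bag in view.positive_bags:
        for inst in set(bag.instances):
            pos_freq[inst] = pos_freq.get(inst, 0) + 1
    n_pos, n_neg = max(view.n_positive, 1), max(view.n_negative, 1)

    def lift(inst: Instance) -> float:
        p = (pos_freq.get(inst, 0) + 1) / (n_pos + 2)
        q = (neg_freq.get(inst, 0) + 1) / (n_neg + 2)
        return p / q

    ranked = sorted(
        candidates,
        key=lambda inst: (
            -lift(inst),
            inst.symptom_id if inst.symptom_id is not None else "",
            tuple(inst.vector),
        ),
    )
    return ranked[: cfg.max_candidates]


def _subsample_view(view: BinaryView, cap: int, seed: int) -> BinaryView:
    """Deterministic stratified subsample keeping class balance workable."""
    n_pos, n_neg = view.n_positive, view.n_negative
    if n_pos + n_neg <= cap:
        return view
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E1EC7]))
    keep_pos = min(n_pos, max(cap // 2, cap - n_neg))
    keep_neg = cap - keep_pos
    pos_idx = np.sort(rng.choice(n_pos, size=keep_pos, replace=False))
    neg_idx = np.sort(rng.choice(n_neg, size=keep_neg, replace=False))
    return BinaryView(
        view.target_class,
        tuple(view.positive_bags[i] for i in pos_idx),
        tuple(view.negative_bags[i] for i in neg_idx),
    )


def select_representatives(
    view: BinaryView,
    params: MRParams,
    max_prototypes: int | None = None,
    patience: int | None = None,
    config: SelectionConfig | None = None,
    seed: int = 0,
) -> RepresentativeInstanceSet:
    """Greedy forward search for the prototype set with the smallest MRS.

    At each step the candidate whose inclusion yields the smallest embedded
    MRS is added (ties: candidate order); the search stops when the MRS size
    has not strictly decreased for ``patience`` consecutive steps, when
    ``max_prototypes`` is reached, or when the minimum possible size (2) is
    achieved. The best set seen is returned (ties: fewer prototypes, then
    earlier discovery).
    """
    if not view.positive_bags or not view.negative_bags:
        raise ValueError("both classes must be non-empty")
    cfg = config or SelectionConfig()
    if max_prototypes is None:
        max_prototypes = cfg.max_prototypes
    if patience is None:
        patience = cfg.patience

    scoring_view = _subsample_view(view, cfg.max_scoring_bags, seed)
    candidates = _candidate_pool(scoring_view, cfg)
    if not candidates:
        raise ValueError("no candidate prototypes in positive bags")

    if cfg.strategy == "ranked":
        best_set, best_score, trace = _ranked_search(
            candidates, scoring_view, params, max_prototypes
        )
    elif cfg.strategy == "greedy":
        best_set, best_score, trace = _greedy_search(
            candidates, scoring_view, params, max_prototypes, patience, cfg
        )
    else:
        raise ValueError(f"unknown search strategy {cfg.strategy!r}")

    sigma = median_embedding_sigma(scoring_view.all_bags(), best_set)
    return RepresentativeInstanceSet(
        target_class=view.target_class,
        prototypes=tuple(best_set),
        mrs_size=int(best_score),
        embedding_sigma=sigma,
        trace=tuple(trace),
    )


def _ranked_search(
    candidates: list[Instance],
    view: BinaryView,
    params: MRParams,
    max_prototypes: int,
) -> tuple[list[Instance], int, list[tuple[int, str | None, int]]]:
    """Score the nested prefixes of the (density-ranked) candidate order and
    keep the prefix with the smallest MRS (ties: the shorter prefix)."""
    best_k, best_score = 1, math.inf
    trace: list[tuple[int, str | None, int]] = []
    for k in range(1, min(max_prototypes, len(candidates)) + 1):
        score = score_candidate_set(
            candidates[:k], view, params,
            size_limit=None if not math.isfinite(best_score) else int(best_score),
        )
        trace.append((k, candidates[k - 1].symptom_id, int(score)))
        if score < best_score:
            best_score, best_k = score, k
        if best_score <= 2:
            break  # MRS size is always >= 2: cannot improve further
    return list(candidates[:best_k]), int(best_score), trace


def _greedy_search(
    candidates: list[Instance],
    view: BinaryView,
    params: MRParams,
    max_prototypes: int,
    patience: int,
    cfg: SelectionConfig,
) -> tuple[list[Instance], int, list[tuple[int, str | None, int]]]:
    """Step-wise greedy: at every step add the candidate minimising the MRS
    size (ties: candidate order); stop on ``patience`` non-improving steps."""
    selected: list[Instance] = []
    best_set: list[Instance] = []
    best_score = math.inf
    no_improve = 0
    trace: list[tuple[int, str | None, int]] = []
    pool = list(candidates)

    for step in range(1, max_prototypes + 1):
        step_best_idx = -1
        step_best_score = None
        step_scores: dict[int, int] = {}
        for idx, cand in enumerate(pool):
            if cand in selected:
                continue
            trial = selected + [cand]
            limit = step_best_score  # exact prune: runs past the incumbent lose
            score = score_candidate_set(trial, view, params, size_limit=limit)
            step_scores[idx] = score
            if step_best_score is None or score < step_best_score:
                step_best_score = score
                step_best_idx = idx
        if step_best_idx < 0:
            break
        chosen = pool[step_best_idx]
        selected.append(chosen)
        trace.append((step, chosen.symptom_id, int(step_best_score)))
        if step == 1 and cfg.refine_pool < len(pool):
            order = sorted(step_scores, key=lambda i: (step_scores[i], i))
            keep = set(order[: cfg.refine_pool]) | {step_best_idx}
            pool = [c for i, c in enumerate(pool) if i in keep]
        if step_best_score < best_score:
            best_score = step_best_score
            best_set = list(selected)
            no_improve = 0
        else:
            no_improve += 1
            if no_improve >= patience:
                break
        if best_score <= 2:
            break
    return best_set, int(best_score), trace


def selected_precision(selected: set[str], standard: set[str]) -> float:
    """Fraction of the selected symptoms that comply with the standard list."""
    selected = set(selected)
    if not selected:
        raise ValueError("selected symptom set is empty")
    return len(selected & set(standard)) / len(selected)
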