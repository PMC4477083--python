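"""User-facing model object tying the pipeline together.

``MRSMIL`` is constructed from a labeled :class:`MILDataset`; ``fit`` runs
the full per-class pipeline — representative-symptom selection by minimum
reference set, mixture fitting with MDL order selection, class priors — and
returns an :class:`MRSMILResults` carrying the fitted class models, a
``summary()`` table, prediction and evaluation methods.

Typical use::

    from mrsmil import MRSMIL, synthetic_data
    ds, truth = synthetic_data.generate(synthetic_data.presets()["paper-like"])
    res = MRSMIL(ds).fit(seed=0)
    print(res.summary())
    rankings = res.predict(ds.bags[:5])
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Bag, MILDataset, binary_view, from_long_frame
from .differentiation import EvaluationReport, RankingResult, evaluate, predict_dataset
from .manifold_ranking import MRParams
from .representative_selection import (
    RepresentativeInstanceSet,
    SelectionConfig,
    select_representatives,
)
from .syndrome_gmm import ClassModel, GMMConfig, build_class_model

logger = logging.getLogger(__name__)

__all__ = ["MRSMIL", "MRSMILResults", "class_models_from_dict"]


class MRSMIL:
    """Minimum-reference-set multiple-instance learner for multi-label bags.

    Parameters
    ----------
    dataset : labeled training data (every bag needs a non-empty label set).
    top_k : number of classes assigned to a bag at prediction time.
    mr_params, selection, gmm : stage configurations; defaults reproduce the
        standard pipeline (alpha=0.99 manifold ranking with median bandwidth,
        greedy selection with patience 2, full-covariance mixtures with MDL).
    """

    def __init__(
        self,
        dataset: MILDataset,
        *,
        top_k: int = 3,
        mr_params: MRParams | None = None,
        selection: SelectionConfig | None = None,
        gmm: GMMConfig | None = None,
    ):
        if not dataset.bags:
            raise ValueError("dataset has no bags")
        self.dataset = dataset
        self.top_k = top_k
        self.mr_params = mr_params or MRParams()
        self.selection = selection or SelectionConfig()
        self.gmm = gmm or GMMConfig()

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, **kwargs) -> "MRSMIL":
        """Build from a long-format DataFrame (bag_id, symptom, severity, labels)."""
        return cls(from_long_frame(frame), **kwargs)

    def fit(self, seed: int = 0) -> "MRSMILResults":
        """Run selection + mixture fitting for every class; deterministic in seed."""
        class_models: dict[str, ClassModel] = {}
        skipped: list[str] = []
        for ci, c in enumerate(self.dataset.class_vocabulary):
            view = binary_view(self.dataset, c)
            if view.n_positive < 2 or view.n_negative < 1:
                logger.warning("class %s skipped: %d positives / %d negatives",
                               c, view.n_positive, view.n_negative)
                skipped.append(c)
                continue
            sel_seed = int(np.random.SeedSequence([seed, 10, ci]).generate_state(1)[0] % (2**31))
            gmm_seed = int(np.random.SeedSequence([seed, 11, ci]).generate_state(1)[0] % (2**31))
            reps = select_representatives(
                view, self.mr_params, config=self.selection, seed=sel_seed
            )
            class_models[c] = build_class_model(
                self.dataset, c, reps, gmm_config=self.gmm, seed=gmm_seed
            )
        if not class_models:
            raise ValueError("no class could be fitted (too few positive bags)")
        return MRSMILResults(self, class_models, tuple(skipped), seed)


@dataclass
class MRSMILResults:
    """Fitted per-class models plus prediction, evaluation and summary."""

    model: MRSMIL
    class_models: dict[str, ClassModel]
    skipped_classes: tuple[str, ...]
    seed: int

    @property
    def fitted_classes(self) -> list[str]:
        return [c for c in self.model.dataset.class_vocabulary if c in self.class_models]

    @property
    def representatives(self) -> dict[str, RepresentativeInstanceSet]:
        return {c: m.representatives for c, m in self.class_models.items()}

    def predict(self, bags: Sequence[Bag], K: int | None = None) -> list[RankingResult]:
        """Top-K maximum-posterior ranking for each bag."""
        models = [self.class_models[c] for c in self.fitted_classes]
        return predict_dataset(
            models, bags, K=K or self.model.top_k,
            class_order=self.model.dataset.class_vocabulary,
        )

    def evaluate(
        self, dataset: MILDataset | Sequence[Bag] | None = None, K: int | None = None
    ) -> EvaluationReport:
        """A/B/C-count evaluation on ``dataset`` (default: the training data)."""
        if dataset is None:
            bags: Sequence[Bag] = self.model.dataset.bags
        elif isinstance(dataset, MILDataset):
            bags = dataset.bags
        else:
            bags = dataset
        results = self.predict(bags, K=K)
        return evaluate(results, bags, K=K or self.model.top_k, classes=self.fitted_classes)

    def summary(self) -> str:
        """Human-readable per-class table of the fitted pipeline."""
        rows = []
        for c in self.fitted_classes:
            cm = self.class_models[c]
            reps = cm.representatives
            rows.append(
                {
                    "class": c,
                    "n_prototypes": len(reps.prototypes),
                    "mrs_size": reps.mrs_size,
                    "gmm_k": cm.gmm.k,
                    "prior": round(cm.prior, 4),
                    "prototypes": ";".join(
                        p.symptom_id or "?" for p in reps.prototypes
                    ),
                }
            )
        frame = pd.DataFrame(rows)
        header = (
            f"MRS-MIL results ({len(self.fitted_classes)} classes, "
            f"{len(self.model.dataset.bags)} bags, seed={self.seed})"
        )
        skipped = f"\nskipped classes: {', '.join(self.skipped_classes)}" if self.skipped_classes else ""
        return header + "\n" + frame.to_string(index=False) + skipped

    def to_dict(self) -> dict:
        """JSON-serialisable dump of the fitted models (prototypes, GMMs, priors)."""
        out: dict = {"seed": self.seed, "top_k": self.model.top_k, "classes": {}}
        for c, cm in self.class_models.items():
            out["classes"][c] = {
                "prior": cm.prior,
                "embedding_sigma": cm.representatives.embedding_sigma,
                "mrs_size": cm.representatives.mrs_size,
                "prototypes": [
                    {"symptom": p.symptom_id, "vector": p.vector.tolist()}
                    for p in cm.representatives.prototypes
                ],
                "gmm": {
                    "weights": cm.gmm.weights.tolist(),
                    "means": cm.gmm.means.tolist(),
                    "covariances": cm.gmm.covariances.tolist(),
                },
            }
        return out


def class_models_from_dict(payload: dict) -> dict[str, ClassModel]:
    """Rebuild fitted class models from a :meth:`MRSMILResults.to_dict` dump."""
    from .data_model import Instance
    from .syndrome_gmm import GaussianMixture

    models: dict[str, ClassModel] = {}
    for c, rec in payload["classes"].items():
        prototypes = tuple(
            Instance(np.asarray(p["vector"], dtype=float), p.get("symptom"))
            for p in rec["prototypes"]
        )
        reps = RepresentativeInstanceSet(
            target_class=c,
            prototypes=prototypes,
            mrs_size=int(rec["mrs_size"]),
            embedding_sigma=float(rec["embedding_sigma"]),
        )
        gmm = GaussianMixture(
            weights=np.asarray(rec["gmm"]["weights"]),
            means=np.asarray(rec["gmm"]["means"]),
            covariances=np.asarray(rec["gmm"]["covariances"]),
            fitted_loglik=float(rec["gmm"].get("fitted_loglik", 0.0)),
        )
        models[c] = ClassModel(c, reps, gmm, float(rec["prior"]))
    return models
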