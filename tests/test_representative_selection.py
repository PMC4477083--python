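"""Candidate enumeration, similarity embedding, MRS scoring, and the search."""

import numpy as np
import pytest

from mrsmil.data_model import BinaryView, MILDataset, binary_view
from mrsmil.manifold_ranking import MRParams
from mrsmil.representative_selection import (
    SelectionConfig,
    candidate_prototypes,
    embed_bags,
    median_embedding_sigma,
    score_candidate_set,
    select_representatives,
    selected_precision,
)

from conftest import symptom_bag, vector_bag

VOCAB = ("fever", "cough", "rash", "chills")


def make_view(pos_symptoms, neg_symptoms):
    pos = tuple(
        symptom_bag(f"p{i}", s, VOCAB, {"C1"}) for i, s in enumerate(pos_symptoms)
    )
    neg = tuple(
        symptom_bag(f"n{i}", s, VOCAB, {"C2"}) for i, s in enumerate(neg_symptoms)
    )
    return BinaryView("C1", pos, neg)


class TestCandidatePrototypes:
    def test_frequency_then_id_ordering(self):
        view = make_view([["fever", "cough"], ["fever"], ["rash"]], [["chills"]])
        ids = [c.symptom_id for c in candidate_prototypes(view)]
        # fever in 2 bags; cough and rash in 1 each, tie broken by symptom id
        assert ids == ["fever", "cough", "rash"]

    def test_single_bag_candidates(self):
        view = make_view([["fever", "rash"]], [["cough"]])
        assert {c.symptom_id for c in candidate_prototypes(view)} == {"fever", "rash"}

    def test_duplicates_across_bags_appear_once(self):
        view = make_view([["fever"], ["fever"], ["fever"]], [["cough"]])
        assert len(candidate_prototypes(view)) == 1

    def test_no_positive_bags_raises(self):
        view = BinaryView("C1", (), (symptom_bag("n0", ["cough"], VOCAB),))
        with pytest.raises(ValueError):
            candidate_prototypes(view)


class TestEmbedBags:
    def test_bag_containing_prototype_has_coordinate_one(self):
        view = make_view([["fever", "cough"]], [["rash"]])
        protos = candidate_prototypes(view)
        E = embed_bags(view.positive_bags, protos, sigma=1.0)
        np.testing.assert_allclose(E[0], 1.0)

    def test_one_hot_mismatch_kernel_value(self):
        # disjoint one-hot symptoms are sqrt(2) apart: exp(-2/sigma^2)
        bag = symptom_bag("b", ["cough"], VOCAB)
        proto = candidate_prototypes(make_view([["fever"]], [["rash"]]))
        E = embed_bags([bag], proto, sigma=1.0)
        assert E[0, 0] == pytest.approx(np.exp(-2.0))

    def test_embedding_dimension_is_prototype_count(self):
        view = make_view([["fever", "cough", "rash"]], [["chills"]])
        protos = candidate_prototypes(view)
        E = embed_bags(view.all_bags(), protos, sigma=1.0)
        assert E.shape == (2, len(protos))

    def test_max_over_instances(self):
        bag = symptom_bag("b", ["fever", "cough"], VOCAB)
        proto = candidate_prototypes(make_view([["fever"]], [["rash"]]))
        E = embed_bags([bag], proto, sigma=1.0)
        assert E[0, 0] == pytest.approx(1.0)  # best-matching instance wins

    def test_empty_prototypes_rejected(self):
        with pytest.raises(ValueError):
            embed_bags([symptom_bag("b", ["fever"], VOCAB)], [], sigma=1.0)


def test_median_embedding_sigma_one_hot():
    view = make_view([["fever"], ["cough"]], [["rash"]])
    protos = candidate_prototypes(view)
    # all nonzero instance-prototype distances equal sqrt(2)
    assert median_embedding_sigma(view.all_bags(), protos) == pytest.approx(np.sqrt(2))


class TestScoreCandidateSet:
    def test_perfectly_separating_prototype_scores_two(self):
        view = make_view(
            [["fever"], ["fever"], ["fever", "cough"]],
            [["rash"], ["rash", "chills"], ["chills"]],
        )
        protos = candidate_prototypes(view)[:1]  # fever
        assert score_candidate_set(protos, view, MRParams()) == 2

    def test_uninformative_prototype_scores_high(self):
        # every bag carries the prototype: embedding constant -> inseparable
        view = make_view(
            [["fever", "cough"], ["fever"]], [["fever"], ["fever", "rash"]]
        )
        protos = [c for c in candidate_prototypes(view) if c.symptom_id == "fever"]
        score = score_candidate_set(protos, view, MRParams(sigma=1.0))
        assert score == len(view.all_bags())

    def test_two_bags_minimum_score(self):
        view = make_view([["fever"]], [["rash"]])
        assert score_candidate_set(candidate_prototypes(view), view, MRParams()) == 2


class TestSelectRepresentatives:
    def test_perfect_symptom_selected_first(self):
        view = make_view(
            [["fever", "cough"], ["fever"], ["fever", "rash"]],
            [["cough"], ["rash"], ["cough", "chills"]],
        )
        reps = select_representatives(view, MRParams(), max_prototypes=3)
        assert reps.prototypes[0].symptom_id == "fever"
        assert reps.mrs_size == 2

    def test_max_prototypes_one(self):
        view = make_view([["fever", "cough"]], [["rash"]])
        reps = select_representatives(view, MRParams(), max_prototypes=1)
        assert len(reps.prototypes) == 1

    def test_deterministic(self):
        view = make_view(
            [["fever", "cough"], ["fever"], ["rash", "fever"]],
            [["cough", "chills"], ["rash"], ["chills"]],
        )
        a = select_representatives(view, MRParams(), seed=5)
        b = select_representatives(view, MRParams(), seed=5)
        assert [p.symptom_id for p in a.prototypes] == [p.symptom_id for p in b.prototypes]
        assert a.mrs_size == b.mrs_size

    def test_greedy_strategy_also_finds_separator(self):
        view = make_view(
            [["fever", "cough"], ["fever"], ["fever", "rash"]],
            [["cough"], ["rash"], ["cough", "chills"]],
        )
        cfg = SelectionConfig(strategy="greedy")
        reps = select_representatives(view, MRParams(), config=cfg)
        assert reps.prototypes[0].symptom_id == "fever"
        assert reps.mrs_size == 2

    def test_best_score_bounds_trace(self):
        view = make_view(
            [["fever", "cough"], ["fever", "chills"], ["fever"]],
            [["cough", "rash"], ["rash"], ["chills", "rash"]],
        )
        reps = select_representatives(view, MRParams())
        assert reps.mrs_size == min(score for _, _, score in reps.trace)

    def test_empty_class_raises(self):
        view = BinaryView("C1", (), ())
        with pytest.raises(ValueError):
            select_representatives(view, MRParams())

    def test_signature_recovery_on_planted_data(self):
        import dataclasses

        from mrsmil.synthetic_data import generate, presets

        cfg = dataclasses.replace(
            presets()["paper-like"], n_bags=200, seed=11
        )
        ds, truth = generate(cfg)
        view = binary_view(ds, "C3")
        reps = select_representatives(view, MRParams(), seed=0)
        prec = selected_precision(reps.symptom_ids, truth.signatures["C3"])
        assert prec >= 0.6  # majority of selected symptoms are planted


class TestSelectedPrecision:
    def test_identical_sets(self):
        assert selected_precision({"a", "b"}, {"a", "b"}) == 1.0

    def test_partial_compliance(self):
        assert selected_precision({"a", "b", "c", "d"}, {"a", "b", "x"}) == 0.5

    def test_disjoint_sets(self):
        assert selected_precision({"a"}, {"b"}) == 0.0

    def test_empty_selected_raises(self):
        with pytest.raises(ValueError):
            selected_precision(set(), {"a"})
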