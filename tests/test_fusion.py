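"""Weight enumeration, weighted voting, and the exhaustive grid search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdparts.fusion import (accuracy, enumerate_weight_vectors,
                              evaluate_weights, grid_search,
                              single_best_part_accuracy, weighted_vote)
from birdparts.part_table import PartRecord, PartTable
from birdparts.synthetic_data import TableSpec, generate_detection_table
from birdparts.voc_io import PartType

import oracles


def _rec(img, part, species, conf):
    return PartRecord(image_id=img, part=part, species_id=species,
                      confidence=conf)


class TestEnumeration:
    @pytest.mark.parametrize("step,expected", [
        (100, 4),    # only the one-hot corners
        (50, 10),    # stars and bars: C(5, 3)
        (25, 35),    # C(7, 3)
    ])
    def test_counts_against_stars_and_bars(self, step, expected):
        vectors = enumerate_weight_vectors(step)
        assert len(vectors) == expected == math.comb(100 // step + 3, 3)

    @pytest.mark.parametrize("step", [50, 25])
    def test_matches_nested_loop_oracle(self, step):
        got = {tuple(v) for v in enumerate_weight_vectors(step)}
        assert got == set(oracles.weight_vectors_oracle(step))

    def test_rows_sum_to_one_and_unique(self):
        vectors = enumerate_weight_vectors(10)
        assert np.all(vectors.sum(axis=1) == 100)
        assert len({tuple(v) for v in vectors}) == len(vectors)

    @pytest.mark.parametrize("bad", [0, 3, 7, -5])
    def test_invalid_step_rejected(self, bad):
        with pytest.raises(ValueError):
            enumerate_weight_vectors(bad)


class TestWeightedVote:
    def test_single_record_one_hot(self):
        vote = weighted_vote([_rec("a", PartType.head, 7, 0.8)], (100, 0, 0, 0))
        assert vote == (7, pytest.approx(0.8))

    def test_two_part_arithmetic(self):
        recs = [_rec("a", PartType.head, 1, 0.9),
                _rec("a", PartType.tail, 2, 0.8)]
        vote = weighted_vote(recs, (50, 0, 0, 50))
        assert vote == (1, pytest.approx(0.45))  # 0.45 > 0.40

    def test_exact_tie_goes_to_lower_species(self):
        recs = [_rec("a", PartType.head, 9, 0.5),
                _rec("a", PartType.tail, 2, 0.5)]
        vote = weighted_vote(recs, (50, 0, 0, 50))
        assert vote[0] == 2

    def test_abstains_without_positive_score(self):
        assert weighted_vote([], (25, 25, 25, 25)) is None
        recs = [_rec("a", PartType.head, 1, 0.9)]
        assert weighted_vote(recs, (0, 0, 0, 100)) is None

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        recs = [_rec("a", PartType(i), int(rng.integers(1, 5)),
                     float(rng.random())) for i in range(4)]
        w = rng.multinomial(100, [0.25] * 4)
        vote = weighted_vote(recs, w)
        rng.shuffle(recs)
        again = weighted_vote(recs, w)
        if vote is None:
            assert again is None
        else:
            assert again[0] == vote[0]
            assert again[1] == pytest.approx(vote[1])


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy({"a": 1, "b": 2}, {"a": 1, "b": 2}) == 1.0

    def test_abstentions_count_as_errors(self):
        assert accuracy({"a": None, "b": None}, {"a": 1, "b": 2}) == 0.0

    def test_three_of_four(self):
        pred = {"a": 1, "b": 2, "c": 3, "d": 9}
        truth = {"a": 1, "b": 2, "c": 3, "d": 4}
        assert accuracy(pred, truth) == 0.75

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            accuracy({"a": 1}, {"b": 1})


def _table_from(records, truth):
    by_img: dict = {}
    for r in records:
        by_img.setdefault(r.image_id, []).append(r)
    return PartTable(records=by_img, true_species=truth)


class TestGridSearch:
    def test_single_correct_record_reaches_one(self):
        table = _table_from([_rec("a", PartType.head, 3, 0.9)], {"a": 3})
        result = grid_search(table, step_hundredths=25)
        assert result.best_accuracy == 1.0

    def test_best_dominates_uniform_and_corners(self, rng):
        table = generate_detection_table(TableSpec(n_images=120, n_species=10,
                                                   seed=5))
        result = grid_search(table, step_hundredths=10)
        probes = np.array([[25, 25, 25, 25], [100, 0, 0, 0], [0, 100, 0, 0],
                           [0, 0, 100, 0], [0, 0, 0, 100]])
        counts = evaluate_weights(table, probes)
        assert result.best_accuracy >= counts.max() / len(table.true_species)

    def test_planted_head_only_structure_recovered(self):
        """Only head records are reliable: the optimum matches head-only."""
        spec = TableSpec(n_images=400, n_species=12, p_part=(1.0, 0.0, 0.0, 0.0),
                         dropout=0.0, seed=9)
        table = generate_detection_table(spec)
        result = grid_search(table, step_hundredths=10)
        head_only = evaluate_weights(table, np.array([[100, 0, 0, 0]]))[0]
        assert result.best_accuracy == pytest.approx(
            head_only / len(table.true_species))

    def test_vectorised_counts_agree_with_scalar_votes(self, rng):
        table = generate_detection_table(TableSpec(n_images=60, n_species=6,
                                                   seed=3))
        vectors = enumerate_weight_vectors(20)
        counts = evaluate_weights(table, vectors)
        for vec, count in zip(vectors, counts):
            correct = 0
            for img, true_sp in table.true_species.items():
                vote = weighted_vote(table.records.get(img, []), vec)
                correct += vote is not None and vote[0] == true_sp
            assert correct == count

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            grid_search(PartTable(records={}, true_species={}), 50)
        with pytest.raises(ValueError):
            grid_search(PartTable(records={}, true_species=None), 50)


def test_single_best_part_baseline():
    recs = [_rec("a", PartType.head, 3, 0.9), _rec("a", PartType.tail, 1, 0.5),
            _rec("b", PartType.head, 2, 0.4), _rec("b", PartType.tail, 5, 0.6)]
    table = _table_from(recs, {"a": 3, "b": 2})
    assert single_best_part_accuracy(table) == 0.5
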