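"""Weighted-vote species fusion with exhaustive part-weight search.

Each image is classified from its part table: every part record votes for its
species with weight ``w_part × confidence``; the species with the largest
summed score wins (exact ties go to the lower species id, and an image with
no positively-weighted record abstains, which counts as an error).

The four part weights live on a 0.01 grid and sum to 1 — represented here as
integers in hundredths summing to 100 so the enumeration is exact.  At step
0.01 there are C(103, 3) = 176,851 weight vectors; the grid search evaluates
the classification accuracy of every one and returns the maximiser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .part_table import PartTable

N_PARTS = 4


def enumerate_weight_vectors(step_hundredths: int = 1) -> np.ndarray:
    """All weight 4-tuples (hundredths) on the grid, lexicographically ordered.

    Returns an integer array of shape (M, 4) whose rows are the multiples of
    `step_hundredths` in [0, 100] summing to exactly 100;
    M = C(100/step + 3, 3).
    """
    step = int(step_hundredths)
    if step <= 0 or 100 % step:
        raise ValueError(f"step must divide 100, got {step}")
    v = np.arange(0, 101, step, dtype=np.int64)
    a, b, c = np.meshgrid(v, v, v, indexing="ij")
    d = 100 - a - b - c
    mask = d >= 0
    return np.stack([a[mask], b[mask], c[mask], d[mask]], axis=1)


def weighted_vote(records: list, weights) -> tuple[int, float] | None:
    """Classify one image's records under a weight vector.

    Returns (species_id, score) or None when no record carries positive
    weighted score (abstention).  Ties break to the lower species id.
    """
    w = np.asarray(weights, dtype=np.float64) / 100.0
    scores: dict[int, float] = {}
    for r in records:
        scores[r.species_id] = scores.get(r.species_id, 0.0) \
            + w[r.part.ordinal] * r.confidence
    best = None
    for species_id in sorted(scores):
        s = scores[species_id]
        if s > 0 and (best is None or s > best[1]):
            best = (species_id, s)
    return best


def accuracy(predictions: dict, truth: dict) -> float:
    """Fraction of images classified correctly; abstentions are errors."""
    if set(predictions) != set(truth):
        raise ValueError("prediction and truth image sets differ")
    if not truth:
        raise ValueError("empty truth mapping")
    correct = sum(1 for img, sp in truth.items() if predictions[img] == sp)
    return correct / len(truth)


@dataclass
class FusionResult:
    best_weights: tuple          # integers in hundredths, sum 100
    best_accuracy: float
    predictions: dict            # image_id -> species_id or None
    n_evaluated: int
    n_ties: int                  # weight vectors sharing the best accuracy
    n_abstained: int             # images with no vote under best weights


def _image_matrices(table: PartTable):
    """Per image: (4 × k) confidence matrix, column species ids, true column."""
    out = []
    for image_id, true_sp in sorted(table.true_species.items()):
        recs = table.records.get(image_id, [])
        species = sorted({r.species_id for r in recs} | {true_sp})
        col = {sp: j for j, sp in enumerate(species)}
        mat = np.zeros((N_PARTS, len(species)))
        for r in recs:
            mat[r.part.ordinal, col[r.species_id]] += r.confidence
        out.append((image_id, mat, np.asarray(species), col[true_sp]))
    return out


def evaluate_weights(table: PartTable, weight_matrix: np.ndarray) -> np.ndarray:
    """Vectorised correct-classification counts for many weight vectors.

    weight_matrix: (M, 4) integer hundredths.  Returns (M,) counts of images
    whose argmax-species (with the tie rule) equals the truth.
    """
    if table.true_species is None:
        raise ValueError("part table carries no ground truth")
    if not table.true_species:
        raise ValueError("empty part table")
    wf = weight_matrix.astype(np.float64) / 100.0
    counts = np.zeros(weight_matrix.shape[0], dtype=np.int64)
    for _, mat, species, true_col in _image_matrices(table):
        scores = wf @ mat                      # (M, k)
        s_true = scores[:, true_col]
        ok = s_true > 0
        true_sp = species[true_col]
        lower = species < true_sp
        higher = species > true_sp
        if lower.any():
            ok &= s_true > scores[:, lower].max(axis=1)
        if higher.any():
            ok &= s_true >= scores[:, higher].max(axis=1)
        counts += ok
    return counts


def grid_search(table: PartTable, step_hundredths: int = 1) -> FusionResult:
    """Exhaustive accuracy maximisation over the weight grid.

    Ties across weight vectors resolve to the lexicographically smallest
    vector; the number of tied maximisers is reported.
    """
    vectors = enumerate_weight_vectors(step_hundredths)
    counts = evaluate_weights(table, vectors)
    best_count = counts.max()
    best_idx = int(np.argmax(counts))   # first occurrence == lexicographic min
    n_images = len(table.true_species)
    best_weights = tuple(int(w) for w in vectors[best_idx])
    predictions = {}
    n_abstained = 0
    for image_id in sorted(table.true_species):
        vote = weighted_vote(table.records.get(image_id, []), best_weights)
        predictions[image_id] = vote[0] if vote else None
        n_abstained += vote is None
    return FusionResult(
        best_weights=best_weights,
        best_accuracy=best_count / n_images,
        predictions=predictions,
        n_evaluated=len(vectors),
        n_ties=int((counts == best_count).sum()),
        n_abstained=n_abstained,
    )


def single_best_part_accuracy(table: PartTable) -> float:
    """Baseline: classify each image by its single most confident record."""
    if table.true_species is None:
        raise ValueError("part table carries no ground truth")
    correct = 0
    for image_id, true_sp in table.true_species.items():
        recs = table.records.get(image_id, [])
        if recs:
            best = max(recs, key=lambda r: (r.confidence, -r.species_id))
            correct += best.species_id == true_sp
    return correct / len(table.true_species)
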