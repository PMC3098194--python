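"""Midcell-division segregation simulator.

Links the localization phenotype to the stability phenotype: if a cell
divides exactly at midcell and foci are inherited by the daughter whose
half they occupy, a cell with all foci on one side produces a plasmid-free
daughter. Simulating this over lineages predicts the per-generation loss
rate implied by a localization model alone.

The simulator is memoryless between generations: each plasmid-bearing
lineage re-draws its focus positions from the same localization model every
generation (no intergenerational focus tracking), divides at midcell, and
plasmid-bearing daughters replicate back to the model's copy number while
plasmid-free daughters stay empty. The predicted loss rate is the fraction
of plasmid-free daughters among all daughters born to plasmid-bearing
mothers — the quantity a replica-picking stability assay measures.

Under a model where each focus lands on either side independently with
probability 1/2 and n foci per cell, a given daughter is empty with
probability (1/2)**n, so the predicted loss rate is (1/2)**n per
generation; a single-copy plasmid (n = 1) loses at 0.5 per generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import CellRecord
from .synthetic import LocalizationModel, ParameterError, sample_positions

__all__ = ["DivisionOutcome", "LossPrediction", "divide", "predict_loss_rate"]


@dataclass(frozen=True)
class DivisionOutcome:
    """Focus partition of one midcell division."""

    daughters: tuple[int, int]
    plasmid_free_daughter: bool


@dataclass(frozen=True)
class LossPrediction:
    """Monte-Carlo predicted loss rate per generation with its standard error."""

    loss_rate: float
    se: float
    n_divisions: int
    foci_per_cell: int


def divide(cell: CellRecord, seed: int = 0) -> DivisionOutcome:
    """Partition a cell's foci between two daughters at a midcell septum.

    Foci at relative position < 0.5 go to daughter 1, > 0.5 to daughter 2;
    a focus exactly at midcell is assigned by a fair seeded coin. An empty
    mother yields (0, 0) and is not counted as a loss event (it was already
    plasmid-free).
    """
    rel = cell.relative_foci()
    n_left = int((rel < 0.5).sum())
    n_right = int((rel > 0.5).sum())
    n_mid = len(rel) - n_left - n_right
    if n_mid:
        rng = np.random.default_rng(seed)
        to_left = int(rng.integers(0, 2, size=n_mid).sum())
        n_left += to_left
        n_right += n_mid - to_left
    free = cell.n_foci > 0 and (n_left == 0 or n_right == 0)
    return DivisionOutcome(daughters=(n_left, n_right), plasmid_free_daughter=free)


def predict_loss_rate(
    model: LocalizationModel,
    copy_number: int,
    n_generations: int = 10,
    n_lineages: int = 10_000,
    seed: int = 0,
) -> LossPrediction:
    """Predict the per-generation loss rate implied by a localization model.

    Each of ``n_lineages`` plasmid-bearing lineages carries
    ``copy_number / copies_per_focus`` foci (at least one). Per generation,
    focus positions are re-drawn from the model, the cell divides at
    midcell, and the two daughters are scored; the lineage continues
    through a random daughter, staying empty once the plasmid is lost.

    Returns the plasmid-free-daughter fraction among daughters of
    plasmid-bearing mothers, with its binomial Monte-Carlo standard error.
    """
    if n_lineages < 1 or n_generations < 1:
        raise ParameterError("n_lineages and n_generations must be >= 1")
    if copy_number < 1:
        raise ParameterError("copy_number must be >= 1")
    n_foci = max(1, round(copy_number / model.copies_per_focus))
    rng = np.random.default_rng(seed)
    bearing = np.ones(n_lineages, dtype=bool)
    free_daughters = 0
    total_daughters = 0
    for _ in range(n_generations):
        m = int(bearing.sum())
        if m == 0:
            break
        pos = sample_positions(model, m * n_foci, rng).reshape(m, n_foci)
        side = pos > 0.5
        at_mid = pos == 0.5  # measure zero for continuous models, handled anyway
        if at_mid.any():
            side = np.where(at_mid, rng.integers(0, 2, size=pos.shape).astype(bool), side)
        n_right = side.sum(axis=1)
        d1_empty = n_right == n_foci
        d2_empty = n_right == 0
        free_daughters += int(d1_empty.sum()) + int(d2_empty.sum())
        total_daughters += 2 * m
        # follow one random daughter per lineage
        follow_d2 = rng.integers(0, 2, size=m).astype(bool)
        lost = np.where(follow_d2, d2_empty, d1_empty)
        idx = np.flatnonzero(bearing)
        bearing[idx[lost]] = False
    if total_daughters == 0:
        return LossPrediction(0.0, 0.0, 0, n_foci)
    rate = free_daughters / total_daughters
    se = float(np.sqrt(rate * (1.0 - rate) / total_daughters))
    return LossPrediction(
        loss_rate=rate, se=se, n_divisions=total_daughters // 2, foci_per_cell=n_foci
    )
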