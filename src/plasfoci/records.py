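"""Core data records shared across the pipeline.

A :class:`CellRecord` holds one segmented rod-shaped cell: its long-axis
length in micrometres and the axial coordinates (also in micrometres,
measured from one pole) of every fluorescent focus detected in it. A
:class:`PassageSeries` holds serial-passage retention data — at each
checkpoint generation, how many colonies were replica-picked and how many
still carried the plasmid. :class:`MatingCounts` holds the CFU bookkeeping
of one mating assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CellRecord",
    "PassageCheckpoint",
    "PassageSeries",
    "MatingCounts",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a record violates its documented invariants."""


@dataclass(frozen=True)
class CellRecord:
    """One cell: identifier, axial length (µm) and focus positions (µm).

    Focus positions are measured from one (arbitrary) pole along the long
    axis; the foci list may be empty for a plasmid-free cell.
    """

    cell_id: str
    length: float
    foci: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isfinite(self.length) or self.length <= 0:
            raise ValidationError(
                f"cell {self.cell_id!r}: length must be positive and finite, "
                f"got {self.length}"
            )
        object.__setattr__(self, "foci", tuple(float(x) for x in self.foci))
        for x in self.foci:
            if not np.isfinite(x) or x < 0 or x > self.length:
                raise ValidationError(
                    f"cell {self.cell_id!r}: focus at {x} µm outside "
                    f"[0, {self.length}] µm"
                )

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    def relative_foci(self) -> np.ndarray:
        """Focus positions as fractions of cell length, in [0, 1]."""
        return np.asarray(self.foci, dtype=float) / self.length


@dataclass(frozen=True)
class PassageCheckpoint:
    generation: float
    colonies_tested: int
    colonies_positive: int

    def __post_init__(self) -> None:
        if self.colonies_tested <= 0:
            raise ValidationError("colonies_tested must be positive")
        if not 0 <= self.colonies_positive <= self.colonies_tested:
            raise ValidationError(
                f"colonies_positive {self.colonies_positive} outside "
                f"[0, {self.colonies_tested}]"
            )
        if self.generation < 0:
            raise ValidationError("generation must be non-negative")

    @property
    def retention(self) -> float:
        """Fraction of colonies still plasmid-positive at this checkpoint."""
        return self.colonies_positive / self.colonies_tested


@dataclass(frozen=True)
class PassageSeries:
    """Serial-passage retention data: checkpoints at increasing generations."""

    checkpoints: tuple[PassageCheckpoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "checkpoints", tuple(self.checkpoints))
        gens = [c.generation for c in self.checkpoints]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValidationError("checkpoint generations must be strictly increasing")

    @property
    def generations(self) -> np.ndarray:
        return np.array([c.generation for c in self.checkpoints], dtype=float)

    @property
    def retentions(self) -> np.ndarray:
        return np.array([c.retention for c in self.checkpoints], dtype=float)

    @property
    def colonies_tested(self) -> np.ndarray:
        return np.array([c.colonies_tested for c in self.checkpoints], dtype=int)


@dataclass(frozen=True)
class MatingCounts:
    """Donor and transconjugant CFU counts with dilution bookkeeping.

    ``donor_cfu`` and ``transconjugant_cfu`` are the plate counts; the
    dilution factors convert plate counts back to the mating-mix scale
    (count × factor = CFU in the mating).
    """

    donor_cfu: float
    transconjugant_cfu: float
    dilution_factor_donor: float = 1.0
    dilution_factor_transconjugant: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "donor_cfu",
            "transconjugant_cfu",
            "dilution_factor_donor",
            "dilution_factor_transconjugant",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if self.donor_cfu <= 0:
            raise ValidationError("donor_cfu must be positive")
        if self.dilution_factor_donor <= 0 or self.dilution_factor_transconjugant <= 0:
            raise ValidationError("dilution factors must be positive")

    @property
    def donors_corrected(self) -> float:
        return self.donor_cfu * self.dilution_factor_donor

    @property
    def transconjugants_corrected(self) -> float:
        return self.transconjugant_cfu * self.dilution_factor_transconjugant


def population_counts(cells: Sequence[CellRecord]) -> np.ndarray:
    """Foci counts per cell as an integer array."""
    return np.array([c.n_foci for c in cells], dtype=int)
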