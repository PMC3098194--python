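"""Synthetic populations, passage series and mating counts.

This module generates the three kinds of data the pipeline analyses, with
the statistical structure the measurements assume:

* populations of rod-shaped cells (lengths ~2–6 µm) carrying 0–10
  fluorescent plasmid foci whose axial positions follow a genotype-specific
  localization model — even distribution along the cell, clustering at the
  poles and midcell, or exclusion from the poles;
* serial-passage retention series under per-generation Bernoulli plasmid
  loss, scored by replica-picking a fixed number of colonies per checkpoint;
* mating-assay CFU counts at a given conjugative transfer frequency.

Four named presets encode the phenotypes of the wild-type plasmid and its
stability-operon deletion mutants (``wt``, ``stbA``, ``stbB``, ``stbABC``).
All generators take explicit integer seeds and never touch global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import CellRecord, MatingCounts, PassageCheckpoint, PassageSeries

__all__ = [
    "LocalizationModel",
    "ParameterError",
    "PRESETS",
    "get_preset",
    "generate_population",
    "sample_positions",
    "simulate_passage",
    "simulate_mating",
    "lognormal_lengths",
]

FAMILIES = ("uniform", "polar_cluster", "pole_excluded", "mixture")


class ParameterError(ValueError):
    """Raised when a model or simulation parameter is out of its domain."""


@dataclass(frozen=True)
class LocalizationModel:
    """Generative model of axial focus positions in fractional coordinates.

    Parameters
    ----------
    family:
        One of ``uniform`` (flat on [0, 1]), ``polar_cluster`` / ``mixture``
        (weighted Gaussian components reflected into [0, 1]), or
        ``pole_excluded`` (flat on [exclusion_width, 1 - exclusion_width]).
    components:
        ``(weight, center, spread)`` triples for Gaussian families; weights
        must sum to 1. Ignored by the uniform families.
    exclusion_width:
        Fractional length excluded at each pole (``pole_excluded`` only).
    copies_per_focus:
        How many plasmid copies one diffraction-limited focus represents
        (1 for dispersed plasmids, >1 for clustered ones).
    foci_count_dist:
        Discrete distribution over the number of foci per cell, as a
        mapping ``count -> probability``.
    """

    family: str
    components: tuple[tuple[float, float, float], ...] = ()
    exclusion_width: float = 0.0
    copies_per_focus: int = 1
    foci_count_dist: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )
        comps = tuple((float(w), float(c), float(s)) for w, c, s in self.components)
        object.__setattr__(self, "components", comps)
        if self.family in ("polar_cluster", "mixture"):
            if not comps:
                raise ParameterError(f"family {self.family!r} requires components")
            total = sum(w for w, _, _ in comps)
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"components: weights must sum to 1 (got {total!r})"
                )
            for w, c, s in comps:
                if w < 0:
                    raise ParameterError("components: weights must be >= 0")
                if not 0.0 <= c <= 1.0:
                    raise ParameterError("components: centers must lie in [0, 1]")
                if s < 0:
                    raise ParameterError("components: spreads must be >= 0")
        if not 0.0 <= self.exclusion_width < 0.5:
            raise ParameterError(
                f"exclusion_width must lie in [0, 0.5), got {self.exclusion_width}"
            )
        if int(self.copies_per_focus) != self.copies_per_focus or self.copies_per_focus < 1:
            raise ParameterError(
                f"copies_per_focus must be a positive integer, got {self.copies_per_focus}"
            )
        dist = {int(k): float(v) for k, v in dict(self.foci_count_dist).items()}
        object.__setattr__(self, "foci_count_dist", dist)
        if not dist:
            raise ParameterError("foci_count_dist must be non-empty")
        if any(k < 0 for k in dist):
            raise ParameterError("foci_count_dist: counts must be non-negative")
        if any(p < 0 for p in dist.values()):
            raise ParameterError("foci_count_dist: probabilities must be >= 0")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ParameterError("foci_count_dist: probabilities must sum to 1")

    @property
    def mean_foci(self) -> float:
        return sum(k * p for k, p in self.foci_count_dist.items())


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Reflect real values into [0, 1] (triangle-wave fold).

    Reflection rather than truncation avoids piling probability mass up at
    the poles when a Gaussian component sits near a boundary.
    """
    x = np.abs(np.mod(x, 2.0))
    return np.where(x > 1.0, 2.0 - x, x)


def sample_positions(
    model: LocalizationModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` fractional axial positions in [0, 1] from the model."""
    if n == 0:
        return np.empty(0, dtype=float)
    if model.family == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if model.family == "pole_excluded":
        w = model.exclusion_width
        return rng.uniform(w, 1.0 - w, size=n)
    weights = np.array([w for w, _, _ in model.components])
    centers = np.array([c for _, c, _ in model.components])
    spreads = np.array([s for _, _, s in model.components])
    which = rng.choice(len(weights), size=n, p=weights / weights.sum())
    raw = rng.normal(centers[which], spreads[which])
    return _reflect_unit(raw)


def _sample_counts(
    model: LocalizationModel, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    counts = np.array(sorted(model.foci_count_dist), dtype=int)
    probs = np.array([model.foci_count_dist[int(k)] for k in counts])
    return rng.choice(counts, size=n_cells, p=probs / probs.sum())


def lognormal_lengths(
    n: int,
    rng: np.random.Generator,
    mean_um: float = 3.0,
    sigma_log: float = 0.25,
) -> np.ndarray:
    """Cell lengths (µm) from a log-normal with the given arithmetic mean.

    The default gives a typical exponential-phase length distribution with
    most cells between 2 and 6 µm.
    """
    mu = math.log(mean_um) - 0.5 * sigma_log**2
    return rng.lognormal(mean=mu, sigma=sigma_log, size=n)


def generate_population(
    model: LocalizationModel,
    n_cells: int,
    seed: int,
    length_mean_um: float = 3.0,
    length_sigma_log: float = 0.25,
) -> list[CellRecord]:
    """Generate ``n_cells`` cells with foci placed according to ``model``.

    Per cell, a focus count is drawn from ``model.foci_count_dist``, a cell
    length from a log-normal, and fractional positions from the model's
    family; positions are scaled by the cell length to micrometres.
    Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ParameterError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(seed)
    counts = _sample_counts(model, n_cells, rng)
    lengths = lognormal_lengths(n_cells, rng, length_mean_um, length_sigma_log)
    all_pos = sample_positions(model, int(counts.sum()), rng)
    cells: list[CellRecord] = []
    offset = 0
    width = len(str(n_cells - 1))
    for i in range(n_cells):
        k = int(counts[i])
        rel = all_pos[offset : offset + k]
        offset += k
        cells.append(
            CellRecord(
                cell_id=f"cell{i:0{width}d}",
                length=float(lengths[i]),
                foci=tuple(rel * lengths[i]),
            )
        )
    return cells


def simulate_passage(
    loss_rate_per_generation: float,
    total_generations: float = 80.0,
    checkpoint_interval: float = 20.0,
    colonies_per_checkpoint: int = 100,
    seed: int = 0,
) -> PassageSeries:
    """Simulate a serial-passage stability assay.

    A plasmid-bearing lineage loses the plasmid with probability ``L`` per
    generation, so expected retention at generation ``g`` is ``(1 - L)**g``.
    At each checkpoint (including generation 0), ``colonies_per_checkpoint``
    colonies are replica-picked and the number still plasmid-positive is a
    binomial draw from the expected retention.
    """
    L = loss_rate_per_generation
    if not 0.0 <= L <= 1.0:
        raise ParameterError(
            f"loss_rate_per_generation must lie in [0, 1], got {L}"
        )
    if total_generations <= 0 or checkpoint_interval <= 0:
        raise ParameterError("generations and checkpoint interval must be positive")
    if colonies_per_checkpoint < 1:
        raise ParameterError("colonies_per_checkpoint must be >= 1")
    rng = np.random.default_rng(seed)
    gens = [0.0]
    g = checkpoint_interval
    while g <= total_generations + 1e-9:
        gens.append(float(g))
        g += checkpoint_interval
    checkpoints = []
    for g in gens:
        expected = (1.0 - L) ** g
        positive = int(rng.binomial(colonies_per_checkpoint, expected))
        checkpoints.append(
            PassageCheckpoint(
                generation=g,
                colonies_tested=colonies_per_checkpoint,
                colonies_positive=positive,
            )
        )
    return PassageSeries(tuple(checkpoints))


def simulate_mating(
    transfer_frequency: float,
    donor_cfu: float,
    seed: int = 0,
    dilution_factor_donor: float = 1.0,
    dilution_factor_transconjugant: float = 1.0,
) -> MatingCounts:
    """Simulate one mating assay.

    Transconjugant CFU is Poisson-sampled with mean
    ``transfer_frequency × donor_cfu`` (both on the mating-mix scale); the
    counts are then expressed on the plate scale via the dilution factors.
    """
    if transfer_frequency < 0:
        raise ParameterError("transfer_frequency must be >= 0")
    if donor_cfu <= 0:
        raise ParameterError("donor_cfu must be positive")
    rng = np.random.default_rng(seed)
    mean_t = transfer_frequency * donor_cfu
    t = float(rng.poisson(mean_t))
    return MatingCounts(
        donor_cfu=donor_cfu / dilution_factor_donor,
        transconjugant_cfu=t / dilution_factor_transconjugant,
        dilution_factor_donor=dilution_factor_donor,
        dilution_factor_transconjugant=dilution_factor_transconjugant,
    )


# --- Genotype presets -------------------------------------------------------
#
# wt:     dispersed single-copy foci, flat along the axis, ~6 foci/cell
#         (64% of cells with 4-6 foci, ~34% with 7-10, ~2% focus-free).
# stbA:   clustered multi-copy foci (2 copies/focus) at the poles and
#         midcell; ~2 foci/cell, 85% of cells with 1-3 foci, 11% focus-free.
#         Mixture weights reproduce the ~33% one-sided-cell fraction.
# stbB:   dispersed single-copy foci excluded from the outermost 10% of
#         the cell at each pole; ~5.6 foci/cell.
# stbABC: like stbA but with more midcell and less polar mass.

PRESETS: dict[str, LocalizationModel] = {
    "wt": LocalizationModel(
        family="uniform",
        copies_per_focus=1,
        foci_count_dist={
            0: 0.02,
            4: 0.22,
            5: 0.22,
            6: 0.20,
            7: 0.14,
            8: 0.10,
            9: 0.06,
            10: 0.04,
        },
    ),
    "stbA": LocalizationModel(
        family="polar_cluster",
        components=((0.35, 0.05, 0.05), (0.35, 0.95, 0.05), (0.30, 0.5, 0.05)),
        copies_per_focus=2,
        foci_count_dist={0: 0.11, 1: 0.22, 2: 0.30, 3: 0.33, 4: 0.04},
    ),
    "stbB": LocalizationModel(
        family="pole_excluded",
        exclusion_width=0.1,
        copies_per_focus=1,
        foci_count_dist={
            0: 0.03,
            4: 0.25,
            5: 0.24,
            6: 0.21,
            7: 0.13,
            8: 0.09,
            9: 0.03,
            10: 0.02,
        },
    ),
    "stbABC": LocalizationModel(
        family="polar_cluster",
        components=((0.28, 0.05, 0.05), (0.28, 0.95, 0.05), (0.44, 0.5, 0.05)),
        copies_per_focus=2,
        foci_count_dist={0: 0.11, 1: 0.24, 2: 0.28, 3: 0.26, 4: 0.08, 5: 0.03},
    ),
}


def get_preset(name: str) -> LocalizationModel:
    """Look up a genotype preset by name (``wt``/``stbA``/``stbB``/``stbABC``)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
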