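"""Positional statistics for axial focus coordinates.

Coordinates are analysed in two complementary views. The *unfolded* view
keeps the fractional position along the full axis in [0, 1] and is used for
cell-quarter occupancy (quarters are physical regions of the cell). The
*folded* (half-cell) view maps each position to its distance from the
nearest pole, ``min(x, 1 - x)`` in [0, 0.5], and is used for the five-slice
distributions; it is invariant under the arbitrary choice of which pole is
"first" in a micrograph.

The random-occupancy null is exact: the probability that ``n`` independent
uniform points on [0, 1] leave none of ``k`` equal-width bins empty is the
surjection probability, computed by inclusion–exclusion

    P(n, k) = sum_{j=0}^{k} (-1)^j C(k, j) ((k - j) / k)^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import CellRecord, ValidationError

__all__ = [
    "RelativeFocusSet",
    "BinnedDistribution",
    "OccupancyResult",
    "normalize_and_fold",
    "fold",
    "bin_half_cell",
    "polar_fraction",
    "occupancy_null_probability",
    "occupancy_test",
    "compare_binned",
    "count_histogram",
    "one_sided_fraction",
]


@dataclass(frozen=True)
class RelativeFocusSet:
    """Per-cell fractional focus coordinates, unfolded and folded."""

    cell_id: str
    relative_positions: tuple[float, ...]
    folded_positions: tuple[float, ...]


@dataclass(frozen=True)
class BinnedDistribution:
    """Counts of folded positions in equal slices of the half-cell."""

    edges: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.edges) - 1:
            raise ValidationError("need exactly one count per bin")
        if any(c < 0 for c in self.counts):
            raise ValidationError("bin counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def fractions(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.full(len(self.counts), np.nan)
        return np.asarray(self.counts, dtype=float) / total


@dataclass(frozen=True)
class OccupancyResult:
    """All-quarters-occupied test for one focus-count stratum.

    ``observed_fraction`` is the proportion of stratum cells with at least
    one focus in every one of ``n_bins`` equal slices of the full axis;
    ``expected_probability`` is the exact uniform null; the χ² statistic is
    the goodness-of-fit of the (occupied, not-occupied) dichotomy (df = 1).
    When either expected category count is below 5 the asymptotic χ² is
    unreliable, so the result is flagged and an exact binomial p-value is
    reported alongside.
    """

    n_foci: int
    n_bins: int
    n_cells: int
    observed_fraction: float
    expected_probability: float
    chi2: float
    df: int
    p_value: float
    low_expected_count: bool = False
    binomial_p_value: float | None = None


def fold(relative: np.ndarray) -> np.ndarray:
    """Distance to the nearest pole in fractional coordinates: min(x, 1-x)."""
    relative = np.asarray(relative, dtype=float)
    return np.minimum(relative, 1.0 - relative)


def normalize_and_fold(cell: CellRecord) -> RelativeFocusSet:
    """Normalize focus positions by cell length and fold onto the half-cell."""
    rel = cell.relative_foci()
    return RelativeFocusSet(
        cell_id=cell.cell_id,
        relative_positions=tuple(rel.tolist()),
        folded_positions=tuple(fold(rel).tolist()),
    )


def _assign_bins(values: np.ndarray, n_bins: int, span: float) -> np.ndarray:
    """Equal-width bin indices on [0, span]: half-open [a, b), last bin closed."""
    idx = np.floor(values * n_bins / span).astype(int)
    return np.minimum(idx, n_bins - 1)


def bin_half_cell(folded: Sequence[float], n_bins: int = 5) -> BinnedDistribution:
    """Count folded positions in ``n_bins`` equal slices of [0, 0.5].

    Bins are half-open ``[a, b)`` with the last bin closed at 0.5, so a
    value exactly on an interior edge belongs to the bin above it.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = np.asarray(list(folded), dtype=float)
    if values.size and (values.min() < 0 or values.max() > 0.5):
        raise ValidationError("folded positions must lie in [0, 0.5]")
    edges = tuple(np.linspace(0.0, 0.5, n_bins + 1).tolist())
    counts = np.zeros(n_bins, dtype=int)
    if values.size:
        np.add.at(counts, _assign_bins(values, n_bins, 0.5), 1)
    return BinnedDistribution(edges=edges, counts=tuple(int(c) for c in counts))


def polar_fraction(folded: Sequence[float], threshold: float = 0.1) -> float:
    """Fraction of folded positions strictly below ``threshold``.

    The boundary is excluded, consistent with the half-open bin convention.
    Returns NaN for an empty input.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError(f"threshold must lie in (0, 0.5], got {threshold}")
    values = np.asarray(list(folded), dtype=float)
    if values.size == 0:
        return float("nan")
    if values.min() < 0 or values.max() > 0.5:
        raise ValidationError("folded positions must lie in [0, 0.5]")
    return float(np.mean(values < threshold))


def occupancy_null_probability(n_foci: int, n_bins: int = 4) -> float:
    """Exact P(no empty bin) for n_foci iid uniform points in n_bins bins.

    Inclusion–exclusion over the set of empty bins; returns 0 when
    ``n_foci < n_bins`` (pigeonhole).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    n, k = n_foci, n_bins
    if n < k:
        return 0.0
    total = 0.0
    for j in range(k + 1):
        total += (-1) ** j * math.comb(k, j) * ((k - j) / k) ** n
    return min(max(total, 0.0), 1.0)


def _all_bins_occupied(cells: Sequence[CellRecord], n_bins: int) -> np.ndarray:
    """Boolean per cell: at least one focus in every equal full-axis bin.

    Cells in one stratum share a focus count, so positions stack into a
    rectangular matrix and the check vectorizes across cells.
    """
    if not cells:
        return np.empty(0, dtype=bool)
    n_foci = cells[0].n_foci
    if n_foci < n_bins:
        return np.zeros(len(cells), dtype=bool)
    rel = np.array([c.foci for c in cells], dtype=float)
    rel /= np.array([c.length for c in cells], dtype=float)[:, None]
    idx = _assign_bins(rel, n_bins, 1.0)
    flags = np.ones(len(cells), dtype=bool)
    for b in range(n_bins):
        flags &= (idx == b).any(axis=1)
    return flags


def occupancy_test(
    cells: Sequence[CellRecord], n_foci: int, n_bins: int = 4
) -> OccupancyResult:
    """Test all-quarters occupancy against the exact uniform null.

    Restricts to the stratum of cells with exactly ``n_foci`` foci, computes
    the fraction with at least one focus in every equal-width slice of the
    full axis, and performs a χ² goodness-of-fit of the binary outcome
    against the inclusion–exclusion null probability (df = 1).
    """
    stratum = [c for c in cells if c.n_foci == n_foci]
    if not stratum:
        raise ValidationError(f"no cells with exactly {n_foci} foci")
    m = len(stratum)
    occupied = _all_bins_occupied(stratum, n_bins)
    obs_frac = float(occupied.mean())
    p0 = occupancy_null_probability(n_foci, n_bins)
    observed = np.array([occupied.sum(), m - occupied.sum()], dtype=float)
    expected = np.array([m * p0, m * (1.0 - p0)], dtype=float)
    low = bool((expected < 5).any())
    if expected.min() > 0:
        chi2, p_value = stats.chisquare(observed, expected)
        chi2, p_value = float(chi2), float(p_value)
    else:
        # Degenerate null (p0 in {0, 1}): chi-square undefined; any
        # deviation is an exact impossibility under the null.
        chi2 = math.inf if observed[expected == 0].sum() > 0 else 0.0
        p_value = 0.0 if math.isinf(chi2) else 1.0
        low = True
    binom_p = None
    if low and 0.0 < p0 < 1.0:
        binom_p = float(stats.binomtest(int(occupied.sum()), m, p0).pvalue)
    return OccupancyResult(
        n_foci=n_foci,
        n_bins=n_bins,
        n_cells=m,
        observed_fraction=obs_frac,
        expected_probability=p0,
        chi2=chi2,
        df=1,
        p_value=p_value,
        low_expected_count=low,
        binomial_p_value=binom_p,
    )


def compare_binned(
    dist_a: BinnedDistribution,
    dist_b: BinnedDistribution,
    bin_subset: tuple[int, int] | None = None,
) -> tuple[float, int, float]:
    """χ² homogeneity test between two binned distributions.

    Builds the 2×m count table (m = number of selected bins) and applies
    the Pearson χ² test of homogeneity without continuity correction.
    ``bin_subset`` selects a contiguous half-open index range
    ``(start, stop)``, e.g. ``(2, 5)`` for the three central half-cell
    slices covering 0.2–0.5. Bins with zero total count across both
    distributions are merged into their left neighbour (the first such bin
    merges rightward).

    Returns ``(chi2, df, p_value)``.
    """
    if dist_a.edges != dist_b.edges:
        raise ValidationError("distributions have different bin edges")
    a = np.asarray(dist_a.counts, dtype=float)
    b = np.asarray(dist_b.counts, dtype=float)
    if bin_subset is not None:
        start, stop = bin_subset
        if not (0 <= start < stop <= len(a)):
            raise ValueError(f"bin_subset {bin_subset} out of range")
        a, b = a[start:stop], b[start:stop]
    totals = a + b
    if (totals == 0).any():
        keep = totals > 0
        if not keep.any():
            raise ValidationError("all selected bins are empty")
        # merge empty bins away; counts are zero so dropping == merging
        a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValidationError("need at least two non-empty bins to compare")
    table = np.vstack([a, b])
    chi2, p_value, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p_value)


def count_histogram(
    cells: Sequence[CellRecord],
) -> tuple[dict[int, float], float]:
    """Distribution of foci per cell and the population mean.

    Returns ``(proportions, mean)`` where ``proportions`` maps each observed
    focus count (zero included) to the fraction of cells showing it.
    """
    if not cells:
        raise ValidationError("population is empty")
    counts = np.array([c.n_foci for c in cells])
    values, freq = np.unique(counts, return_counts=True)
    props = {int(v): float(f) / len(cells) for v, f in zip(values, freq)}
    return props, float(counts.mean())


def one_sided_fraction(
    cells: Sequence[CellRecord], center_window: float = 0.1
) -> float:
    """Fraction of focus-bearing cells with all foci on one side of midcell.

    A cell counts as one-sided when every focus lies strictly on the same
    side of the midcell plane (all relative positions < 0.5 or all > 0.5)
    and none falls within ``center_window`` of midcell, i.e. within
    ``[0.5 - w, 0.5 + w]``. Such cells would yield a plasmid-free daughter
    if division occurred exactly at midcell with no focus movement.
    """
    if not 0.0 <= center_window < 0.5:
        raise ValueError(f"center_window must lie in [0, 0.5), got {center_window}")
    bearing = [c for c in cells if c.n_foci > 0]
    if not bearing:
        raise ValidationError("no focus-bearing cells in population")
    lo, hi = 0.5 - center_window, 0.5 + center_window
    n_one_sided = 0
    for cell in bearing:
        rel = cell.relative_foci()
        if ((rel >= lo) & (rel <= hi)).any():
            continue
        if (rel < 0.5).all() or (rel > 0.5).all():
            n_one_sided += 1
    return n_one_sided / len(bearing)
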