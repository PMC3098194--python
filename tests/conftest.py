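"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from plasfoci import CellRecord, generate_population, get_preset


def brute_force_occupancy(n_foci: int, n_bins: int) -> float:
    """Exact all-bins-occupied probability by enumerating k**n assignments.

    Every one of the k**n equiprobable ways of assigning n points to k
    equal-width bins is enumerated (as base-k digit strings) and the
    fraction leaving no bin empty is counted directly. Independent of the
    inclusion–exclusion formula it checks.
    """
    k, n = n_bins, n_foci
    if n == 0:
        return 1.0 if k == 0 else 0.0
    codes = np.arange(k**n, dtype=np.int64)
    digits = np.empty((k**n, n), dtype=np.int8)
    for d in range(n):
        digits[:, d] = codes % k
        codes //= k
    present = np.ones(k**n, dtype=bool)
    for b in range(k):
        present &= (digits == b).any(axis=1)
    return present.sum() / k**n


def flip_cell(cell: CellRecord) -> CellRecord:
    """Mirror a cell's coordinate system (swap which pole is 'first')."""
    return CellRecord(
        cell_id=cell.cell_id,
        length=cell.length,
        foci=tuple(cell.length - x for x in cell.foci),
    )


@pytest.fixture(scope="session")
def wt_population():
    return generate_population(get_preset("wt"), 5000, seed=11)


@pytest.fixture(scope="session")
def stba_population():
    return generate_population(get_preset("stbA"), 5000, seed=12)
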