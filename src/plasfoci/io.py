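"""TSV formats, analysis configuration, and the summary report.

All tables are tab-separated UTF-8 with ``.`` as the decimal separator.

Population format (one row per cell)::

    cell_id  length_um  focus_positions_um

with focus positions comma-joined in the third column (empty string for a
plasmid-free cell). Passage series have one row per checkpoint
(``generation  colonies_tested  colonies_positive``); mating counts one row
per assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import spatial
from .records import (
    CellRecord,
    MatingCounts,
    PassageCheckpoint,
    PassageSeries,
    ValidationError,
)

__all__ = [
    "FormatError",
    "AnalysisConfig",
    "read_population",
    "write_population",
    "read_passage",
    "write_passage",
    "read_mating",
    "write_mating",
    "report",
]

POPULATION_COLUMNS = ["cell_id", "length_um", "focus_positions_um"]
PASSAGE_COLUMNS = ["generation", "colonies_tested", "colonies_positive"]
MATING_COLUMNS = [
    "donor_cfu",
    "transconjugant_cfu",
    "dilution_factor_donor",
    "dilution_factor_transconjugant",
]


class FormatError(ValueError):
    """Raised when a file does not match its documented schema."""


@dataclass
class AnalysisConfig:
    """Thresholds and bin counts for the positional analysis."""

    quarters: int = 4
    half_cell_bins: int = 5
    polar_threshold: float = 0.1
    center_window: float = 0.1
    occupancy_strata: tuple[int, ...] = (4, 5, 6)
    seed: int = 0
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.quarters < 2:
            raise ValidationError("quarters must be >= 2")
        if self.half_cell_bins < 1:
            raise ValidationError("half_cell_bins must be >= 1")
        if not 0.0 < self.polar_threshold <= 0.5:
            raise ValidationError("polar_threshold must lie in (0, 0.5]")
        if not 0.0 <= self.center_window < 0.5:
            raise ValidationError("center_window must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "occupancy_strata" in data:
            data["occupancy_strata"] = tuple(data["occupancy_strata"])
        return cls(**data)


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    return df


def read_population(path: str | Path) -> list[CellRecord]:
    """Read a population TSV into validated cell records.

    Malformed rows raise with the offending line number and cell id.
    """
    df = _read_tsv(path, POPULATION_COLUMNS)
    cells: list[CellRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = row.focus_positions_um.strip()
        try:
            foci = tuple(float(x) for x in raw.split(",")) if raw else ()
            cells.append(
                CellRecord(
                    cell_id=row.cell_id, length=float(row.length_um), foci=foci
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return cells


def write_population(cells: Sequence[CellRecord], path: str | Path) -> None:
    rows = [
        {
            "cell_id": c.cell_id,
            "length_um": f"{c.length:.6g}",
            "focus_positions_um": ",".join(f"{x:.6g}" for x in c.foci),
        }
        for c in cells
    ]
    pd.DataFrame(rows, columns=POPULATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_passage(path: str | Path) -> PassageSeries:
    df = _read_tsv(path, PASSAGE_COLUMNS)
    try:
        checkpoints = tuple(
            PassageCheckpoint(
                generation=float(r.generation),
                colonies_tested=int(r.colonies_tested),
                colonies_positive=int(r.colonies_positive),
            )
            for r in df.itertuples(index=False)
        )
        return PassageSeries(checkpoints)
    except (ValueError, ValidationError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_passage(series: PassageSeries, path: str | Path) -> None:
    rows = [
        {
            "generation": f"{c.generation:g}",
            "colonies_tested": c.colonies_tested,
            "colonies_positive": c.colonies_positive,
        }
        for c in series.checkpoints
    ]
    pd.DataFrame(rows, columns=PASSAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mating(path: str | Path) -> list[MatingCounts]:
    df = _read_tsv(path, MATING_COLUMNS)
    try:
        return [
            MatingCounts(
                donor_cfu=float(r.donor_cfu),
                transconjugant_cfu=float(r.transconjugant_cfu),
                dilution_factor_donor=float(r.dilution_factor_donor),
                dilution_factor_transconjugant=float(
                    r.dilution_factor_transconjugant
                ),
            )
            for r in df.itertuples(index=False)
        ]
    except (ValueError, ValidationError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_mating(counts: Sequence[MatingCounts], path: str | Path) -> None:
    rows = [
        {
            "donor_cfu": f"{m.donor_cfu:.6g}",
            "transconjugant_cfu": f"{m.transconjugant_cfu:.6g}",
            "dilution_factor_donor": f"{m.dilution_factor_donor:.6g}",
            "dilution_factor_transconjugant": f"{m.dilution_factor_transconjugant:.6g}",
        }
        for m in counts
    ]
    pd.DataFrame(rows, columns=MATING_COLUMNS).to_csv(path, sep="\t", index=False)


def report(
    cells: Sequence[CellRecord], config: AnalysisConfig | None = None
) -> tuple[str, pd.DataFrame]:
    """Summarise a population: focus counts, half-cell bins, occupancy.

    Returns a human-readable text block and a tidy long-format table
    (``section  key  value``) with the same numbers. Deterministic given
    the population and config.
    """
    if not cells:
        raise ValidationError("population is empty; nothing to report")
    cfg = config or AnalysisConfig()
    rows: list[dict] = []
    lines: list[str] = []

    props, mean_foci = spatial.count_histogram(cells)
    lines.append(f"cells analysed: {len(cells)}")
    lines.append(f"mean foci per cell: {mean_foci:.3f}")
    rows.append({"section": "counts", "key": "n_cells", "value": len(cells)})
    rows.append({"section": "counts", "key": "mean_foci", "value": mean_foci})
    lines.append("focus-count distribution (count: fraction of cells):")
    for k in sorted(props):
        lines.append(f"  {k}: {props[k]:.4f}")
        rows.append({"section": "count_histogram", "key": str(k), "value": props[k]})

    folded = [
        x for c in cells for x in spatial.normalize_and_fold(c).folded_positions
    ]
    dist = spatial.bin_half_cell(folded, n_bins=cfg.half_cell_bins)
    lines.append(
        f"half-cell distribution ({cfg.half_cell_bins} slices, pole to midcell):"
    )
    for (lo, hi), frac in zip(
        zip(dist.edges[:-1], dist.edges[1:]), dist.fractions
    ):
        lines.append(f"  [{lo:.2f}, {hi:.2f}): {frac:.4f}")
        rows.append(
            {"section": "half_cell_bins", "key": f"{lo:.2f}-{hi:.2f}", "value": frac}
        )
    pf = spatial.polar_fraction(folded, threshold=cfg.polar_threshold)
    lines.append(f"polar fraction (< {cfg.polar_threshold:g}): {pf:.4f}")
    rows.append({"section": "polar", "key": "polar_fraction", "value": pf})

    lines.append(f"all-quarters occupancy (k = {cfg.quarters}):")
    for n in cfg.occupancy_strata:
        try:
            res = spatial.occupancy_test(cells, n_foci=n, n_bins=cfg.quarters)
        except ValidationError:
            continue
        lines.append(
            f"  n={n}: observed {res.observed_fraction:.3f} vs expected "
            f"{res.expected_probability:.4f} (chi2={res.chi2:.2f}, "
            f"p={res.p_value:.3g}, cells={res.n_cells})"
        )
        rows.append(
            {"section": "occupancy", "key": f"observed_n{n}", "value": res.observed_fraction}
        )
        rows.append(
            {"section": "occupancy", "key": f"expected_n{n}", "value": res.expected_probability}
        )
        rows.append({"section": "occupancy", "key": f"p_n{n}", "value": res.p_value})

    try:
        osf = spatial.one_sided_fraction(cells, center_window=cfg.center_window)
        lines.append(f"one-sided focus-bearing cells: {osf:.4f}")
        rows.append({"section": "one_sided", "key": "fraction", "value": osf})
    except ValidationError:
        lines.append("one-sided fraction: no focus-bearing cells")

    return "\n".join(lines) + "\n", pd.DataFrame(rows, columns=["section", "key", "value"])
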