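"""Load, validate, filter and summarize cells × species incidence matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IncidenceMatrix:
    """A validated cells × species presence–absence matrix.

    ``table`` is a 0/1 integer DataFrame indexed by cell_id with species_id
    columns; identifier order is preserved from the source.  Duplicated cell or
    species identifiers and non-binary values are rejected at construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dupes = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated cell identifiers: {dupes}")
        if t.columns.duplicated().any():
            dupes = t.columns[t.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated species identifiers: {dupes}")
        vals = t.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary value {vals[i, j]!r} at cell {t.index[i]!r}, "
                f"species {t.columns[j]!r}"
            )
        empty = t.columns[vals.sum(axis=0) == 0].tolist()
        if empty:
            logger.warning("species with no occurrences: %s", empty)

    @property
    def cell_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def species_ids(self) -> list[str]:
        return self.table.columns.tolist()

    @property
    def n_cells(self) -> int:
        return self.table.shape[0]

    @property
    def n_species(self) -> int:
        return self.table.shape[1]

    def richness(self) -> pd.Series:
        """Species count per cell (row sums)."""
        return self.table.sum(axis=1)

    def range_sizes(self) -> pd.Series:
        """Occupied-cell count per species (column sums)."""
        return self.table.sum(axis=0)

    def species_set(self, cell_id: str) -> set[str]:
        row = self.table.loc[cell_id]
        return set(row.index[row == 1])


@dataclass(frozen=True)
class CellSummary:
    """Per-cell richness and mean range size of the species present.

    mean_range_size is NaN for cells with zero richness.
    """

    table: pd.DataFrame  # columns: richness, mean_range_size; index cell_id


def read_incidence(path) -> IncidenceMatrix:
    """Read an incidence CSV (first column cell_id, one column per species)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "cell_id"
    return IncidenceMatrix(df.astype(np.int8, errors="ignore"))


def write_incidence(m: IncidenceMatrix, path) -> None:
    m.table.to_csv(path)


def filter_small_ranges(m: IncidenceMatrix, max_cells_excluded: int) -> IncidenceMatrix:
    """Drop species occupying at most ``max_cells_excluded`` cells.

    The small-range sensitivity design: rerunning the regionalization after
    excluding species known from only 1, 2, 3… cells probes robustness to
    undersampled or recently described species.  ``max_cells_excluded = 0`` is
    the identity.
    """
    if max_cells_excluded < 0:
        raise ValueError("max_cells_excluded must be >= 0")
    keep = m.range_sizes() > max_cells_excluded
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "filter_small_ranges(<=%d): dropped %d of %d species",
            max_cells_excluded, dropped, m.n_species,
        )
    return IncidenceMatrix(m.table.loc[:, keep])


def drop_empty_cells(m: IncidenceMatrix) -> tuple[IncidenceMatrix, list[str]]:
    """Remove cells with zero richness (Simpson turnover is undefined there)."""
    rich = m.richness()
    removed = rich.index[rich == 0].tolist()
    if len(removed) == m.n_cells:
        raise ValueError("all cells are empty; nothing left to analyze")
    if removed:
        logger.warning("dropping %d empty cells: %s", len(removed), removed)
    return IncidenceMatrix(m.table.loc[rich > 0]), removed


def summarize_cells(m: IncidenceMatrix) -> CellSummary:
    """Richness and mean range size per cell.

    mean_range_size(cell) averages the global occupied-cell counts of the
    species present in that cell; it is reported missing for empty cells.
    """
    occ = m.table.to_numpy(dtype=float)
    richness = occ.sum(axis=1)
    sizes = occ.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rs = (occ @ sizes) / richness
    mean_rs[richness == 0] = np.nan
    out = pd.DataFrame(
        {"richness": richness.astype(int), "mean_range_size": mean_rs},
        index=m.table.index,
    )
    return CellSummary(out)
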