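"""Table ingestion and nearest-neighbour imputation of missing cells.

CSV files are RFC-4180, UTF-8, with a header row; the missing marker
defaults to "NULL".  Missing cells are filled by the modal value among the
k nearest records, where distance is the fraction of disagreements over
the columns both records have observed (pairwise-complete Hamming).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .bn import DEFAULT_MISSING, DataTable, DiscreteVariable
from .errors import ImputationError

__all__ = ["read_table", "nn_impute"]

logger = logging.getLogger(__name__)


def read_table(
    path: str | Path,
    schema: Sequence[DiscreteVariable] | None = None,
    missing_marker: str = DEFAULT_MISSING,
) -> DataTable:
    """Read a CSV into a validated table.

    With a schema, every non-missing cell must be a listed state (offending
    cells are reported); without one, each column's state list is inferred
    as the sorted distinct observed values.
    """
    return DataTable.read_csv(path, schema, missing_marker)


def nn_impute(data: DataTable, k_neighbors: int = 5) -> DataTable:
    """Fill every missing cell with its k-nearest-neighbour modal value.

    Distance between two records is the disagreement fraction over their
    mutually observed columns (records sharing no observed column are at
    infinite distance).  For each missing cell, the k nearest records with
    that column observed vote; distance ties are broken by record order
    and modal ties by state order, so the result is deterministic.
    Non-missing cells are never altered; imputation reads only original
    values, never freshly imputed ones.

    Raises :class:`ImputationError` for a record with no observed cell, or
    a cell with no observed donor anywhere in its column.
    """
    if k_neighbors < 1:
        raise ImputationError("k_neighbors must be >= 1")
    codes = data.codes()
    n, m = codes.shape
    observed = codes >= 0
    if not (~observed).any():
        return DataTable(data.variables, data.df.copy(), data.missing_marker)
    if (observed.sum(axis=1) == 0).any():
        bad = int(np.flatnonzero(observed.sum(axis=1) == 0)[0])
        raise ImputationError(f"record {bad} has no observed cell")

    filled = data.df.copy()
    n_imputed = 0
    for i in np.flatnonzero(~observed.all(axis=1)):
        shared = observed[i] & observed  # (n, m)
        n_shared = shared.sum(axis=1)
        disagree = (codes[i] != codes) & shared
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(
                n_shared > 0, disagree.sum(axis=1) / n_shared, np.inf
            )
        dist[i] = np.inf
        for c in np.flatnonzero(~observed[i]):
            donors = np.flatnonzero(observed[:, c] & np.isfinite(dist))
            if donors.size == 0:
                raise ImputationError(
                    f"no donor for record {i}, column "
                    f"{data.variables[c].name!r}"
                )
            order = donors[np.argsort(dist[donors], kind="stable")]
            top = order[:k_neighbors]
            votes = np.bincount(
                codes[top, c], minlength=data.variables[c].n_states
            )
            state = data.variables[c].states[int(votes.argmax())]
            filled.iloc[i, c] = state
            n_imputed += 1
    logger.info("nn_impute: filled %d cells in %d records", n_imputed, n)
    return DataTable(data.variables, filled, data.missing_marker)
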