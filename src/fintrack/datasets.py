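"""Packaged reference tables from the published assay.

Two small CSVs ship with the package, transcribed verbatim from the
published study so the statistical endpoints can be recomputed without
any recording:

* ``load_velocity_table`` — the 12 per-clip average swimming velocities
  (pixel/frame) of the control and the treated (exposed) groups, each
  column sorted ascending as printed.
* ``load_hatch_table`` — the per-dish hatch endpoints (dishes 1-5
  treated, 6-8 control; 15 embryos each): total hatched, hatchability %
  and mean days to hatch, as printed.

The printed hatch table contains one internal inconsistency (dish 5:
14 of 15 hatched but a printed hatchability of 100%); the values are
preserved verbatim and :func:`hatch_table_consistency` flags such rows.
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("fintrack.data") / name) as path:
        return pd.read_csv(path)


def load_velocity_table() -> pd.DataFrame:
    """Per-clip velocities: columns ``video``, ``control``, ``treated``
    (pixel/frame), 12 rows, each group column sorted ascending."""
    return _read_packaged("table3.csv")


def load_hatch_table() -> pd.DataFrame:
    """Per-dish hatch endpoints: columns ``dish``, ``group``, ``total``,
    ``hatched``, ``hatchability_pct``, ``mean_days_to_hatch``."""
    return _read_packaged("table1.csv")


def hatch_table_consistency(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute hatchability from counts and flag printed mismatches.

    Returns the table with ``recomputed_pct`` and ``consistent`` columns;
    inconsistent rows are logged.
    """
    table = load_hatch_table() if table is None else table.copy()
    table["recomputed_pct"] = (100.0 * table["hatched"] / table["total"]).round(1)
    table["consistent"] = table["recomputed_pct"] == table["hatchability_pct"]
    for row in table[~table["consistent"]].itertuples(index=False):
        logger.warning(
            "hatch table dish %s: printed hatchability %.1f%% but %d/%d = %.1f%%",
            row.dish, row.hatchability_pct, row.hatched, row.total, row.recomputed_pct,
        )
    return table
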