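"""Index-versus-heat-dissipation correlation and ranking.

Each index is evaluated at every sow's local air state and regressed (OLS,
index as predictor) against that sow's convective heat dissipation; the
coefficient of determination R² says how much of the spatial variation in
heat loss the index explains.  Velocity-aware indices (ET, ETIS) see the
local air speed and come out on top — the pure temperature–humidity
indices are blind to the ventilation gradient that actually drives the
convective loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .barn import SowRecord
from .indices import IndexId, compute_index

__all__ = ["CorrelationReport", "heat_dissipation_correlation", "rank_indices"]

_ENUM_ORDER = {id: k for k, id in enumerate(IndexId)}


@dataclass(frozen=True)
class CorrelationReport:
    """Per-index OLS fit of Q_conv on the index value.

    ``table`` columns: index, r2, slope, intercept, rank; one row per
    evaluated index, NaN r2 (and no rank) where the index was degenerate
    (zero variance across sows).
    """

    table: pd.DataFrame
    n: int

    def r2(self, id: IndexId) -> float:
        row = self.table.loc[self.table["index"] == IndexId(id).value, "r2"]
        return float(row.iloc[0])

    @property
    def ranking(self) -> list[IndexId]:
        ranked = self.table.dropna(subset=["r2"]).sort_values("rank")
        return [IndexId(v) for v in ranked["index"]]


def heat_dissipation_correlation(
    records: list[SowRecord],
    ids: list[IndexId] | None = None,
) -> CorrelationReport:
    """OLS of per-sow heat dissipation on each index.

    Needs at least 3 records.  R² = 1 − SS_res/SS_tot; an index with zero
    variance across sows has no defined R² and is reported as missing.
    Ranks are dense over the defined R² values, ties broken by enum order.
    """
    if len(records) < 3:
        raise ValueError(f"need >= 3 sow records, got {len(records)}")
    ids = list(IndexId) if ids is None else [IndexId(i) for i in ids]
    Q = np.array([r.Q_conv for r in records], dtype=float)

    rows = []
    for id in ids:
        x = np.array(
            [compute_index(id, r.local_state).value for r in records], dtype=float
        )
        if np.ptp(x) == 0.0:
            rows.append(
                {"index": id.value, "r2": np.nan, "slope": np.nan, "intercept": np.nan}
            )
            continue
        fit = stats.linregress(x, Q)
        rows.append(
            {
                "index": id.value,
                "r2": fit.rvalue**2,
                "slope": fit.slope,
                "intercept": fit.intercept,
            }
        )
    table = pd.DataFrame(rows)

    defined = table.dropna(subset=["r2"])
    order = sorted(
        defined.index, key=lambda i: (-defined.loc[i, "r2"], _ENUM_ORDER[IndexId(defined.loc[i, "index"])])
    )
    table["rank"] = pd.Series(
        {idx: rank for rank, idx in enumerate(order, start=1)}, dtype="Int64"
    )
    return CorrelationReport(table=table, n=len(records))


def rank_indices(report: CorrelationReport) -> list[IndexId]:
    """Indices sorted by descending R² (ties by enum order)."""
    return report.ranking
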