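"""Spearman rank correlation between index scores and demographic
composition — the ethnic-concentration analysis.

rho is the Pearson correlation of midrank vectors (the universal tie
convention).  The default p-value uses the t approximation
``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of freedom, which is
standard at the study's scale (hundreds of counties); ``method="exact"``
enumerates all rank permutations and is available for n <= 10.  Raw
p-values are reported Table-style; a Holm-adjusted column is emitted
alongside for good practice but never drives the headline flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountyTable, IndexScores, SCORE_COLUMNS

__all__ = ["spearman", "correlation_report", "CorrelationReport"]

_EXACT_MAX_N = 10


def _validate_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman requires 1-d vectors of length >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("spearman requires complete data; drop missing pairs first")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman is undefined for a constant vector")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(
    x: np.ndarray, y: np.ndarray, method: str = "t"
) -> tuple[float, float]:
    """Spearman rho and two-sided p for a pair of vectors.

    ``method="t"`` (default) uses the t approximation; perfectly monotone
    pairs (|rho| = 1) get p = 0.  ``method="exact"`` enumerates every
    permutation of the second vector's ranks (n <= 10) and reports the
    fraction with |rho| at least as extreme — the exact null distribution,
    ties included.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair(x, y)
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    rho = float(np.clip(rho, -1.0, 1.0))
    n = len(x)

    if method == "t":
        if abs(rho) == 1.0:
            return rho, 0.0
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        return rho, min(p, 1.0)
    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError(f"exact method limited to n <= {_EXACT_MAX_N}, got {n}")
        observed = abs(rho)
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rho_of_ranks(rx, np.array(perm))) >= observed - 1e-12:
                count += 1
        return rho, count / total
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CorrelationReport:
    """Grid of (index, demographic) Spearman results.

    ``cells`` is long-form with columns [index, demographic, rho, p, n,
    significant, p_holm]; ``rho_matrix()``/``p_matrix()`` pivot to the
    index-by-demographic layout.
    """

    cells: pd.DataFrame
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)

    def rho_matrix(self) -> pd.DataFrame:
        return self._pivot("rho")

    def p_matrix(self) -> pd.DataFrame:
        return self._pivot("p")

    def _pivot(self, value: str) -> pd.DataFrame:
        wide = self.cells.pivot(index="index", columns="demographic", values=value)
        order = [i for i in SCORE_COLUMNS if i in wide.index]
        return wide.loc[order]


def correlation_report(
    scores: IndexScores,
    table: CountyTable,
    alpha: float = 0.05,
) -> CorrelationReport:
    """Correlate every index score with every demographic column.

    Counties are matched by id; for each pair, counties missing the
    demographic value are dropped (n records the pairs actually used).
    A demographic column with fewer than 3 observed values is omitted with
    a warning.  Holm adjustment is computed across the full grid.
    """
    demo = table.demographics()
    demo = demo.loc[demo.index.intersection(scores.data.index)]
    rows: list[dict] = []
    warns: list[str] = []
    for dem_name in table.demographic_names:
        col = demo[dem_name]
        present = col.notna()
        if present.sum() < 3:
            warns.append(f"demographic {dem_name!r} has <3 observed values; omitted")
            continue
        for index_name in SCORE_COLUMNS:
            x = scores.data.loc[col.index[present], index_name].to_numpy()
            y = col[present].to_numpy()
            rho, p = spearman(x, y)
            rows.append(
                {
                    "index": index_name,
                    "demographic": dem_name,
                    "rho": rho,
                    "p": p,
                    "n": int(present.sum()),
                    "significant": p < alpha,
                }
            )
    cells = pd.DataFrame(rows)
    if len(cells):
        order = np.argsort(cells["p"].to_numpy())
        m = len(cells)
        holm = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * cells["p"].iloc[idx])
            holm[idx] = min(running, 1.0)
        cells["p_holm"] = holm
    return CorrelationReport(cells=cells, alpha=alpha, warnings=warns)
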