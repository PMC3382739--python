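"""Data preparation: population filter, log transform, imputation,
z-standardization, and directional reverse coding.

Pipeline order is fixed as filter -> log -> impute -> zscore -> reverse:
median imputation before standardization keeps the mean-0/sd-1 invariant
exact over the full column, and reverse coding last makes it a pure sign
flip.  After preparation every retained indicator points toward insecurity
(higher = worse) and is on a common +/- standard-deviation scale, so
indicators can be added across heterogeneous raw metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import Direction, IndicatorSpec, LogPolicy, RunConfig, validate_specs
from .io import CountyTable

__all__ = [
    "PrepRecord",
    "StandardizedTable",
    "filter_by_population",
    "log_transform",
    "impute_or_drop",
    "zscore",
    "reverse_code",
    "prepare",
    "CountyStandardizer",
]


@dataclass(frozen=True)
class PrepRecord:
    """What happened to one variable during preparation."""

    applied_log: bool = False
    applied_reverse: bool = False
    n_imputed: int = 0
    dropped: bool = False
    drop_reason: str | None = None


@dataclass
class StandardizedTable:
    """Counties x standardized, insecurity-aligned indicator columns.

    Retained columns jointly (imputed values included) have sample mean 0 and
    sample standard deviation 1 (n-1 denominator).  Dropped variables carry
    no column but keep a :class:`PrepRecord` explaining why.
    """

    county_ids: list[str]
    data: pd.DataFrame  # indexed by county_id, config column order
    records: dict[str, PrepRecord] = field(default_factory=dict)
    n_filtered: int = 0

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


def filter_by_population(
    table: CountyTable, min_population: int
) -> tuple[CountyTable, int]:
    """Drop counties below the population threshold.

    Retains exactly the rows with ``population >= min_population`` (the
    under-threshold counties are omitted), preserving row order.  Returns the
    filtered table and the number of removed rows.
    """
    keep = table.data["population"] >= min_population
    n_removed = int((~keep).sum())
    filtered = dataclasses.replace(
        table, data=table.data.loc[keep].reset_index(drop=True)
    )
    return filtered, n_removed


def log_transform(
    values: np.ndarray,
    policy: LogPolicy | str,
    name: str = "<unnamed>",
    county_ids: list[str] | None = None,
) -> np.ndarray:
    """Apply a per-variable logarithmic pre-transform; NaN passes through.

    ``natural_log`` is ln(x) and requires every non-missing value positive;
    ``log_shift`` is ln(x - min(x) + 1), defined for any finite values.
    """
    policy = LogPolicy(policy)
    values = np.asarray(values, dtype=float)
    if policy is LogPolicy.NONE:
        return values.copy()
    out = np.full_like(values, np.nan)
    present = ~np.isnan(values)
    if policy is LogPolicy.NATURAL_LOG:
        bad = present & (values <= 0)
        if bad.any():
            where = np.flatnonzero(bad)[0]
            county = county_ids[where] if county_ids is not None else f"row {where}"
            raise ValueError(
                f"variable {name!r}: natural_log undefined for value "
                f"{values[where]!r} (county {county})"
            )
        out[present] = np.log(values[present])
    else:  # LOG_SHIFT
        if present.any():
            shift = np.nanmin(values)
            out[present] = np.log(values[present] - shift + 1.0)
    return out


def impute_or_drop(
    values: np.ndarray, max_missing_fraction: float
) -> tuple[np.ndarray, int, bool]:
    """Median-impute sparse missingness, or drop the variable entirely.

    If the missing fraction exceeds ``max_missing_fraction`` (or every value
    is missing) the variable is flagged dropped and returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    missing = np.isnan(values)
    n_missing = int(missing.sum())
    if len(values) == 0 or n_missing == len(values):
        return values.copy(), 0, True
    if n_missing / len(values) > max_missing_fraction:
        return values.copy(), 0, True
    out = values.copy()
    if n_missing:
        out[missing] = np.median(values[~missing])
    return out, n_missing, False


def zscore(values: np.ndarray, name: str = "<unnamed>") -> np.ndarray:
    """Center and scale to sample (n-1 denominator) standard deviation 1."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError(f"variable {name!r}: need at least 2 values to standardize")
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"variable {name!r}: constant column cannot be standardized")
    return (values - values.mean()) / sd


def reverse_code(z: np.ndarray, direction: Direction | str) -> np.ndarray:
    """Negate security-aligned columns so higher always means more insecure."""
    direction = Direction(direction)
    z = np.asarray(z, dtype=float)
    return -z if direction is Direction.SECURITY else z.copy()


def prepare(
    table: CountyTable, specs: list[IndicatorSpec], cfg: RunConfig
) -> StandardizedTable:
    """Full preparation: filter -> log -> impute/drop -> zscore -> reverse.

    Column order follows the configuration order.  Variables that cannot be
    standardized (too much missingness, constant after transform) are dropped
    with a reason in their :class:`PrepRecord`; the rest are unaffected.
    """
    validate_specs(specs)
    filtered, n_removed = filter_by_population(table, cfg.min_population)
    ids = filtered.county_ids
    records: dict[str, PrepRecord] = {}
    columns: dict[str, np.ndarray] = {}
    for spec in specs:
        raw = filtered.data[spec.name].to_numpy(dtype=float)
        vals = log_transform(raw, spec.log_transform, spec.name, ids)
        vals, n_imputed, dropped = impute_or_drop(vals, cfg.max_missing_fraction)
        if dropped:
            records[spec.name] = PrepRecord(
                applied_log=spec.log_transform is not LogPolicy.NONE,
                dropped=True,
                drop_reason="insufficient data (missing fraction above threshold)",
            )
            continue
        try:
            vals = zscore(vals, spec.name)
        except ValueError as exc:
            records[spec.name] = PrepRecord(
                applied_log=spec.log_transform is not LogPolicy.NONE,
                n_imputed=n_imputed,
                dropped=True,
                drop_reason=str(exc),
            )
            continue
        vals = reverse_code(vals, spec.direction)
        records[spec.name] = PrepRecord(
            applied_log=spec.log_transform is not LogPolicy.NONE,
            applied_reverse=spec.direction is Direction.SECURITY,
            n_imputed=n_imputed,
        )
        columns[spec.name] = vals
    data = pd.DataFrame(columns, index=pd.Index(ids, name="county_id"))
    return StandardizedTable(
        county_ids=ids, data=data, records=records, n_filtered=n_removed
    )


class CountyStandardizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping :func:`prepare`.

    ``fit`` learns the per-variable transform parameters (log shift, median,
    mean, standard deviation, drop set) from a county table; ``transform``
    applies them to produce the standardized, insecurity-aligned matrix.
    ``fit_transform`` on one table reproduces :func:`prepare` exactly.

    Parameters
    ----------
    specs : list of IndicatorSpec
        The variable dictionary (direction, transform, grouping).
    min_population, max_missing_fraction :
        See :class:`~hsindex.config.RunConfig`.
    """

    def __init__(
        self,
        specs: list[IndicatorSpec] | None = None,
        min_population: int = 2000,
        max_missing_fraction: float = 0.25,
    ) -> None:
        self.specs = specs
        self.min_population = min_population
        self.max_missing_fraction = max_missing_fraction

    def _cfg(self) -> RunConfig:
        return RunConfig(
            min_population=self.min_population,
            max_missing_fraction=self.max_missing_fraction,
        )

    def fit(self, X: CountyTable, y=None) -> "CountyStandardizer":
        if self.specs is None:
            raise ValueError("CountyStandardizer requires indicator specs")
        validate_specs(self.specs)
        filtered, _ = filter_by_population(X, self.min_population)
        ids = filtered.county_ids
        self.params_: dict[str, dict] = {}
        self.dropped_: dict[str, str] = {}
        for spec in self.specs:
            raw = filtered.data[spec.name].to_numpy(dtype=float)
            vals = log_transform(raw, spec.log_transform, spec.name, ids)
            present = ~np.isnan(vals)
            shift = float(np.nanmin(vals)) if present.any() else np.nan
            vals, _, dropped = impute_or_drop(vals, self.max_missing_fraction)
            if dropped:
                self.dropped_[spec.name] = "insufficient data"
                continue
            sd = float(vals.std(ddof=1))
            if sd == 0 or not np.isfinite(sd):
                self.dropped_[spec.name] = "constant column"
                continue
            self.params_[spec.name] = {
                "median": float(np.median(vals)),
                "mean": float(vals.mean()),
                "sd": sd,
                "log_shift_min": shift,
                "sign": -1.0 if spec.direction is Direction.SECURITY else 1.0,
                "log": spec.log_transform,
            }
        self.n_features_in_ = len(self.specs)
        return self

    def transform(self, X: CountyTable) -> pd.DataFrame:
        if not hasattr(self, "params_"):
            raise ValueError("CountyStandardizer is not fitted")
        filtered, _ = filter_by_population(X, self.min_population)
        out: dict[str, np.ndarray] = {}
        for spec in self.specs:
            p = self.params_.get(spec.name)
            if p is None:
                continue
            vals = np.asarray(filtered.data[spec.name].to_numpy(dtype=float))
            if p["log"] is LogPolicy.NATURAL_LOG:
                vals = log_transform(vals, p["log"], spec.name, filtered.county_ids)
            elif p["log"] is LogPolicy.LOG_SHIFT:
                present = ~np.isnan(vals)
                shifted = np.full_like(vals, np.nan)
                shifted[present] = np.log(vals[present] - p["log_shift_min"] + 1.0)
                vals = shifted
            vals = np.where(np.isnan(vals), p["median"], vals)
            out[spec.name] = p["sign"] * (vals - p["mean"]) / p["sd"]
        return pd.DataFrame(
            out, index=pd.Index(filtered.county_ids, name="county_id")
        )
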