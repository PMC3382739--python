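"""Reading and writing county tables, score tables, and map-ready GeoJSON.

County tables are CSV/TSV with a header row: a FIPS-style ``county_id``
column (kept as an opaque string so leading zeros survive), a ``population``
count, optional demographic-composition columns, and one column per raw
indicator.  Heterogeneous missing-value dialects (empty cell, ``NA``,
``N/A``, ``.``) are normalized to NaN on input.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import IndicatorSpec

__all__ = [
    "CountyTable",
    "IndexScores",
    "DEMOGRAPHIC_COLUMNS",
    "SCORE_COLUMNS",
    "MISSING_MARKERS",
    "read_county_table",
    "write_scores",
    "read_scores",
    "export_geojson",
]

#: demographic-composition columns recognized on input (percent scale, 0-100)
DEMOGRAPHIC_COLUMNS = ("pct_hispanic", "pct_african_american", "pct_foreign_born")

#: deterministic output order: four subfabrics, three fabrics, total
SCORE_COLUMNS = (
    "education",
    "health",
    "crime",
    "social_stress",
    "economic",
    "environmental",
    "social",
    "total_hsi",
)

#: cell values treated as missing, besides the empty cell
MISSING_MARKERS = ("", "NA", "N/A", ".")


@dataclass
class CountyTable:
    """Counties x (population, demographics, raw indicators).

    ``data`` is indexed 0..n-1 with a string ``county_id`` column; indicator
    and demographic columns are float64 with NaN for missing.  ``meta`` holds
    provenance (parse reports, simulation ground truth) and never affects
    computation.
    """

    data: pd.DataFrame
    indicator_names: list[str]
    demographic_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "county_id" not in self.data.columns:
            raise ValueError("county table requires a 'county_id' column")
        if "population" not in self.data.columns:
            raise ValueError("county table requires a 'population' column")
        ids = self.data["county_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate county_id values: {dupes}")
        missing = [c for c in self.indicator_names if c not in self.data.columns]
        if missing:
            raise ValueError(f"indicator column(s) absent from table: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def county_ids(self) -> list[str]:
        return self.data["county_id"].tolist()

    def indicators(self) -> pd.DataFrame:
        """Indicator block, indexed by county_id, in declared order."""
        out = self.data.set_index("county_id")[self.indicator_names]
        return out.astype(float)

    def demographics(self) -> pd.DataFrame:
        out = self.data.set_index("county_id")[self.demographic_names]
        return out.astype(float)


@dataclass
class IndexScores:
    """Per-county subfabric, fabric, and total cumulative-risk scores.

    ``data`` is indexed by county_id with the eight :data:`SCORE_COLUMNS`;
    ``provenance`` maps each score name to the signed variables that entered
    it, e.g. ``{"economic": [("poverty", +1.0), ...]}``.
    """

    data: pd.DataFrame
    provenance: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"score table missing column(s): {missing}")
        self.data = self.data[list(SCORE_COLUMNS)]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def county_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )


def _to_numeric(raw: pd.Series) -> tuple[pd.Series, int]:
    """Parse strings to float; returns (values, count of unparseable cells).

    Declared missing markers become NaN silently; anything else that fails to
    parse also becomes NaN but is counted for the parse report.
    """
    stripped = raw.str.strip()
    is_marker = stripped.isin(MISSING_MARKERS)
    values = pd.to_numeric(stripped.mask(is_marker), errors="coerce")
    n_bad = int((values.isna() & ~is_marker).sum())
    return values.astype(float), n_bad


def read_county_table(path: str | Path, specs: list[IndicatorSpec]) -> CountyTable:
    """Load a CSV/TSV county table against a declared indicator dictionary.

    Every indicator named in ``specs`` must be present as a column; missing
    required columns are fatal and named.  Unparseable numeric cells become
    missing markers and are tallied in ``meta["parse_report"]``.
    """
    raw = _read_delimited(path)
    raw.columns = [c.strip() for c in raw.columns]
    for required in ("county_id", "population"):
        if required not in raw.columns:
            raise ValueError(f"{path}: required column {required!r} not found")
    declared = [s.name for s in specs]
    absent = [name for name in declared if name not in raw.columns]
    if absent:
        raise ValueError(f"{path}: declared indicator column(s) absent: {absent}")

    data = pd.DataFrame({"county_id": raw["county_id"].str.strip()})
    population, n_bad_pop = _to_numeric(raw["population"])
    if population.isna().any():
        bad = data.loc[population.isna(), "county_id"].tolist()
        raise ValueError(f"{path}: population missing or unparseable for counties {bad}")
    data["population"] = population

    parse_report: dict[str, int] = {}
    if n_bad_pop:
        parse_report["population"] = n_bad_pop
    demographic_names = [c for c in DEMOGRAPHIC_COLUMNS if c in raw.columns]
    for col in demographic_names + declared:
        values, n_bad = _to_numeric(raw[col])
        data[col] = values
        if n_bad:
            parse_report[col] = n_bad

    return CountyTable(
        data=data,
        indicator_names=declared,
        demographic_names=demographic_names,
        meta={"source": str(path), "parse_report": parse_report},
    )


def write_scores(scores: IndexScores, path: str | Path) -> None:
    """Write one row per county with the eight score columns in fixed order.

    Floats are written at full precision (repr round-trip), so a read-back
    compares equal to the in-memory values.
    """
    out = scores.data.copy()
    out.insert(0, "county_id", scores.county_ids)
    out.to_csv(path, index=False)


def read_scores(path: str | Path) -> IndexScores:
    """Read back a score table written by :func:`write_scores`."""
    raw = pd.read_csv(path, dtype={"county_id": str})
    if "county_id" not in raw.columns:
        raise ValueError(f"{path}: required column 'county_id' not found")
    data = raw.set_index("county_id").astype(float)
    return IndexScores(data=data)


def export_geojson(
    scores: IndexScores,
    geometry: dict,
    index_name: str,
    id_property: str = "county_id",
) -> tuple[dict, dict]:
    """Join one score column onto a GeoJSON FeatureCollection by county id.

    Each feature whose ``id_property`` matches a scored county gains a
    property named ``index_name``; features with no score are annotated with
    ``null``.  Returns ``(feature_collection, report)`` where the report lists
    unmatched ids on both sides.  The input collection is not mutated.
    """
    if not isinstance(geometry, dict) or geometry.get("type") != "FeatureCollection":
        raise ValueError("geometry must be a GeoJSON FeatureCollection")
    if index_name not in scores.data.columns:
        raise ValueError(f"unknown index {index_name!r}; choose from {list(SCORE_COLUMNS)}")

    lookup = dict(zip(scores.county_ids, scores.data[index_name].tolist()))
    out = copy.deepcopy(geometry)
    matched: set[str] = set()
    features_without_score: list[str] = []
    for feature in out.get("features", []):
        props = feature.setdefault("properties", {})
        if id_property not in props:
            raise ValueError(f"feature lacks the {id_property!r} property")
        cid = str(props[id_property])
        if cid in lookup:
            value = lookup[cid]
            props[index_name] = None if (isinstance(value, float) and np.isnan(value)) else value
            matched.add(cid)
        else:
            props[index_name] = None
            features_without_score.append(cid)
    report = {
        "index": index_name,
        "n_matched": len(matched),
        "features_without_score": features_without_score,
        "scores_without_feature": sorted(set(lookup) - matched),
    }
    return out, report


def write_geojson(collection: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(collection, fh)
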