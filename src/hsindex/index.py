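"""Assembly of subfabric, fabric, and total index scores per county.

Scores are aggregations (sum by default, mean optional) of the selected,
prepared variables.  The social fabric score aggregates the union of its
four subfabrics' selected variables — no variable is double-counted — and
the total index aggregates every constituent variable across the three
fabrics; in sum mode that equals the sum of the three fabric sums.  Higher
always means more insecure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import IndicatorSpec, RunConfig
from .factor import FactorResult, analyze_all_groups
from .io import CountyTable, IndexScores
from .preprocess import StandardizedTable, prepare

__all__ = [
    "component_score",
    "build_all",
    "rank_extremes",
    "HumanSecurityIndex",
]

_SUBFABRICS = ("education", "health", "crime", "social_stress")


def component_score(
    z: pd.DataFrame,
    selected: list[str],
    aggregation: str = "sum",
    align_by_loading_sign: bool = False,
    loadings: dict[str, float] | None = None,
    group: str = "<unnamed>",
) -> pd.Series:
    """Aggregate the selected prepared columns into one score per county.

    With ``align_by_loading_sign`` each variable is multiplied by the sign of
    its factor loading before aggregation (a sensitivity option; by default
    the direction metadata is the sole orientation authority).
    """
    if not selected:
        raise ValueError(f"group {group!r}: no variables selected, cannot score")
    missing = [v for v in selected if v not in z.columns]
    if missing:
        raise ValueError(f"group {group!r}: selected variable(s) not prepared: {missing}")
    block = z[selected].copy()
    if align_by_loading_sign:
        if loadings is None:
            raise ValueError("align_by_loading_sign requires loadings")
        for name in selected:
            if loadings.get(name, 1.0) < 0:
                block[name] = -block[name]
    if aggregation == "sum":
        return block.sum(axis=1)
    if aggregation == "mean":
        return block.mean(axis=1)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _signed_vars(
    selected: list[str],
    align_by_loading_sign: bool,
    loadings: dict[str, float],
) -> list[tuple[str, float]]:
    if not align_by_loading_sign:
        return [(v, 1.0) for v in selected]
    return [(v, -1.0 if loadings.get(v, 1.0) < 0 else 1.0) for v in selected]


def build_all(
    z: StandardizedTable,
    factor_results: dict[str, FactorResult],
    cfg: RunConfig,
) -> IndexScores:
    """Build the full score hierarchy from per-group factor results.

    Subfabric and flat-fabric scores come from their own selected variables;
    the social score from the union of the four subfabric selections; the
    total from all constituent variables.  Provenance records the signed
    variable list behind every score.
    """
    scores: dict[str, pd.Series] = {}
    provenance: dict[str, list[tuple[str, float]]] = {}

    def score_of(name: str, selected: list[str], loadings: dict[str, float]) -> None:
        scores[name] = component_score(
            z.data,
            selected,
            aggregation=cfg.aggregation,
            align_by_loading_sign=cfg.align_by_loading_sign,
            loadings=loadings,
            group=name,
        )
        provenance[name] = _signed_vars(selected, cfg.align_by_loading_sign, loadings)

    social_union: list[str] = []
    all_loadings: dict[str, float] = {}
    for group in _SUBFABRICS:
        result = factor_results[group]
        score_of(group, result.selected, result.loadings)
        social_union.extend(v for v in result.selected if v not in social_union)
        all_loadings.update(result.loadings)
    for fabric in ("economic", "environmental"):
        result = factor_results[fabric]
        score_of(fabric, result.selected, result.loadings)
        all_loadings.update(result.loadings)

    score_of("social", social_union, all_loadings)
    total_vars = (
        factor_results["economic"].selected
        + factor_results["environmental"].selected
        + social_union
    )
    score_of("total_hsi", total_vars, all_loadings)

    data = pd.DataFrame(scores, index=z.data.index)
    return IndexScores(data=data, provenance=provenance)


def rank_extremes(
    scores: IndexScores, index_name: str, k: int
) -> tuple[list[str], list[str]]:
    """Top-k (most insecure) and bottom-k county ids for one index.

    Ties are broken by county_id in lexicographic order, so the ranking is
    deterministic.
    """
    if index_name not in scores.data.columns:
        raise ValueError(f"unknown index {index_name!r}")
    n = len(scores)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} scored counties")
    frame = pd.DataFrame(
        {"score": scores.data[index_name].to_numpy(), "county_id": scores.county_ids}
    )
    top = frame.sort_values(
        ["score", "county_id"], ascending=[False, True], kind="mergesort"
    )["county_id"].head(k).tolist()
    bottom = frame.sort_values(
        ["score", "county_id"], ascending=[True, True], kind="mergesort"
    )["county_id"].head(k).tolist()
    return top, bottom


class HumanSecurityIndex(BaseEstimator):
    """End-to-end index constructor in sklearn estimator form.

    ``fit`` runs preparation (population filter, log, impute, standardize,
    reverse-code), factors every fabric/subfabric, and applies the
    loading-threshold selection; ``transform`` assembles the per-county
    score hierarchy.  This is a descriptive analysis, so ``transform`` with
    no argument scores the counties the estimator was fitted on.

    Fitted attributes: ``standardized_`` (:class:`StandardizedTable`),
    ``factor_results_`` (dict group -> :class:`FactorResult`), ``scores_``
    (:class:`IndexScores`, populated by ``transform``).

    Examples
    --------
    >>> from hsindex.simulate import study_like_spec, generate
    >>> from hsindex.simulate import study_indicator_specs
    >>> table = generate(study_like_spec(seed=1))
    >>> hsi = HumanSecurityIndex(specs=study_indicator_specs())
    >>> scores = hsi.fit_transform(table)
    >>> len(scores.county_ids)
    234
    """

    def __init__(
        self,
        specs: list[IndicatorSpec] | None = None,
        min_population: int = 2000,
        loading_threshold: float = 0.5,
        threshold_mode: str = "strict",
        use_absolute_loading: bool = True,
        aggregation: str = "sum",
        align_by_loading_sign: bool = False,
        max_missing_fraction: float = 0.25,
    ) -> None:
        self.specs = specs
        self.min_population = min_population
        self.loading_threshold = loading_threshold
        self.threshold_mode = threshold_mode
        self.use_absolute_loading = use_absolute_loading
        self.aggregation = aggregation
        self.align_by_loading_sign = align_by_loading_sign
        self.max_missing_fraction = max_missing_fraction

    def _cfg(self) -> RunConfig:
        return RunConfig(
            min_population=self.min_population,
            loading_threshold=self.loading_threshold,
            threshold_mode=self.threshold_mode,
            use_absolute_loading=self.use_absolute_loading,
            aggregation=self.aggregation,
            align_by_loading_sign=self.align_by_loading_sign,
            max_missing_fraction=self.max_missing_fraction,
        )

    def fit(self, X: CountyTable, y=None) -> "HumanSecurityIndex":
        if self.specs is None:
            raise ValueError("HumanSecurityIndex requires indicator specs")
        cfg = self._cfg()
        self.standardized_ = prepare(X, self.specs, cfg)
        self.factor_results_ = analyze_all_groups(self.standardized_, cfg, self.specs)
        return self

    def transform(self, X: CountyTable | None = None) -> IndexScores:
        if not hasattr(self, "factor_results_"):
            raise ValueError("HumanSecurityIndex is not fitted")
        cfg = self._cfg()
        z = self.standardized_ if X is None else prepare(X, self.specs, cfg)
        self.scores_ = build_all(z, self.factor_results_, cfg)
        return self.scores_

    def fit_transform(self, X: CountyTable, y=None) -> IndexScores:
        return self.fit(X).transform()
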