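"""Principal-component factor analysis per fabric/subfabric and the
loading-threshold variable-selection rule.

One factor is extracted per group: the first principal component of the
group's correlation matrix.  Loadings are the first eigenvector scaled by
the square root of the first eigenvalue, i.e. the correlation of each
variable with the extracted factor, so they live in [-1, 1] and satisfy
sum(loading^2) = eigenvalue.  A variable enters the final instrument when
its absolute loading exceeds the threshold (default 0.5, strict), unless a
per-variable override forces it in or out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import IndicatorSpec, Override, RunConfig
from .preprocess import StandardizedTable

__all__ = [
    "FactorResult",
    "correlation_matrix",
    "principal_factor",
    "select_variables",
    "analyze_group",
    "analyze_all_groups",
    "GROUPS",
    "PrincipalFactorSelector",
]

#: factoring groups in report order: two flat fabrics, then the four
#: subfabrics of the social fabric
GROUPS = ("economic", "environmental", "education", "health", "crime", "social_stress")


@dataclass
class FactorResult:
    """First-factor summary for one fabric or subfabric."""

    group: str
    eigenvalue: float | None
    loadings: dict[str, float]
    selected: list[str]
    selection_rule: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "eigenvalue": self.eigenvalue,
            "loadings": self.loadings,
            "selected": self.selected,
            "selection_rule": self.selection_rule,
            "degenerate": self.degenerate,
        }


def correlation_matrix(z: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of prepared (complete) columns.

    Requires at least two variables and three counties; rows must already be
    listwise complete (imputation happens upstream).
    """
    if z.shape[1] < 2:
        raise ValueError(f"need at least 2 variables, got {z.shape[1]}")
    if z.shape[0] < 3:
        raise ValueError(f"need at least 3 counties, got {z.shape[0]}")
    if np.isnan(z.to_numpy()).any():
        raise ValueError("correlation matrix requires complete data; impute first")
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=z.columns, columns=z.columns)


def principal_factor(corr: np.ndarray | pd.DataFrame) -> tuple[float, np.ndarray]:
    """First eigenvalue and loading vector of a correlation matrix.

    The loading vector is the leading unit eigenvector scaled by
    sqrt(eigenvalue), oriented so the loadings sum positive (if the sum is
    exactly zero, so the largest-magnitude loading is positive).  That sign
    convention makes repeated runs deterministic; an eigenvector is otherwise
    only defined up to sign.
    """
    mat = np.asarray(corr, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"correlation matrix must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    eigenvalues, eigenvectors = np.linalg.eigh(mat)
    eigenvalue = float(eigenvalues[-1])
    vec = eigenvectors[:, -1]
    total = vec.sum()
    if total < 0 or (total == 0 and vec[np.argmax(np.abs(vec))] < 0):
        vec = -vec
    loadings = vec * np.sqrt(max(eigenvalue, 0.0))
    return eigenvalue, loadings


def select_variables(
    loadings: dict[str, float],
    cfg: RunConfig,
    overrides: dict[str, Override] | None = None,
) -> list[str]:
    """Apply the loading-threshold rule, honoring per-variable overrides.

    In the default strict/absolute mode a variable is kept iff
    ``|loading| > threshold``; inclusive mode uses >=; with
    ``use_absolute_loading=False`` the signed loading is compared.  Variables
    with ``force_include``/``force_exclude`` bypass the rule.  Output
    preserves the input (configuration) order.
    """
    if not loadings:
        raise ValueError("select_variables requires a nonempty loading map")
    overrides = overrides or {}
    selected: list[str] = []
    for name, loading in loadings.items():
        override = overrides.get(name, Override.AUTO)
        if override is Override.FORCE_INCLUDE:
            selected.append(name)
            continue
        if override is Override.FORCE_EXCLUDE:
            continue
        value = abs(loading) if cfg.use_absolute_loading else loading
        keep = value > cfg.loading_threshold if cfg.threshold_mode == "strict" \
            else value >= cfg.loading_threshold
        if keep:
            selected.append(name)
    return selected


def analyze_group(
    z: StandardizedTable,
    group: str,
    cfg: RunConfig,
    specs: list[IndicatorSpec],
) -> FactorResult:
    """Factor one fabric/subfabric and select its instrument variables.

    Groups reduced below two surviving variables cannot be factored: they
    yield a degenerate result (eigenvalue None, empty loadings, only
    force-included variables selected) with a warning.
    """
    group_specs = [s for s in specs if s.group == group]
    if not group_specs:
        raise ValueError(f"no indicators declared for group {group!r}")
    overrides = {s.name: s.selection_override for s in group_specs}
    survivors = [s.name for s in group_specs if s.name in z.data.columns]
    rule = {
        "threshold": cfg.loading_threshold,
        "mode": cfg.threshold_mode,
        "absolute": cfg.use_absolute_loading,
        "overrides": {
            k: v.value for k, v in overrides.items() if v is not Override.AUTO
        },
    }
    if len(survivors) < 2:
        warnings.warn(
            f"group {group!r} has {len(survivors)} surviving variable(s); "
            "factor analysis skipped (degenerate result)",
            stacklevel=2,
        )
        forced = [
            n for n in survivors if overrides.get(n) is Override.FORCE_INCLUDE
        ]
        return FactorResult(
            group=group,
            eigenvalue=None,
            loadings={},
            selected=forced,
            selection_rule=rule,
            degenerate=True,
        )
    corr = correlation_matrix(z.data[survivors])
    eigenvalue, loading_vec = principal_factor(corr)
    loadings = {name: float(v) for name, v in zip(survivors, loading_vec)}
    selected = select_variables(loadings, cfg, overrides)
    return FactorResult(
        group=group,
        eigenvalue=eigenvalue,
        loadings=loadings,
        selected=selected,
        selection_rule=rule,
    )


def analyze_all_groups(
    z: StandardizedTable, cfg: RunConfig, specs: list[IndicatorSpec]
) -> dict[str, FactorResult]:
    """Factor every group that has declared indicators, in report order."""
    present = {s.group for s in specs}
    return {g: analyze_group(z, g, cfg, specs) for g in GROUPS if g in present}


class PrincipalFactorSelector(BaseEstimator):
    """Sklearn-style selector: first-principal-factor loadings + threshold.

    ``fit`` computes the correlation matrix of the columns of ``X``, extracts
    the first principal factor, and applies the loading-threshold rule.
    Fitted attributes: ``eigenvalue_``, ``loadings_`` (array, input column
    order), ``support_`` (boolean mask), ``selected_`` (names when ``X`` is a
    DataFrame).  ``transform`` subsets columns to the selected set.
    """

    def __init__(
        self,
        threshold: float = 0.5,
        mode: str = "strict",
        absolute: bool = True,
    ) -> None:
        self.threshold = threshold
        self.mode = mode
        self.absolute = absolute

    def fit(self, X, y=None) -> "PrincipalFactorSelector":
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        corr = correlation_matrix(frame)
        self.eigenvalue_, self.loadings_ = principal_factor(corr)
        cfg = RunConfig(
            loading_threshold=self.threshold,
            threshold_mode=self.mode,
            use_absolute_loading=self.absolute,
        )
        names = [str(c) for c in frame.columns]
        self.selected_ = select_variables(dict(zip(names, self.loadings_)), cfg)
        self.support_ = np.array([n in self.selected_ for n in names])
        self.feature_names_in_ = np.array(names)
        self.n_features_in_ = frame.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        return frame.loc[:, self.support_]
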