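"""Synthetic county tables with the statistical structure the index
analysis assumes.

Each fabric/subfabric group follows a single-latent-factor model: one
standard-normal factor f per county, indicators
``x_j = lambda_j * f + sqrt(1 - lambda_j^2) * eps_j`` with independent
standard-normal noise, so corr(x_j, x_k) = lambda_j * lambda_k and the
first principal factor recovers the planted loadings as n grows.
Security-aligned variables are emitted with flipped sign (the preparation
step's reverse coding undoes it), and every variable is pushed through a
fixed positive affine map so raw columns look like heterogeneous
agency-sourced metrics; the maps are recorded in the table metadata.

Demographic-composition columns are monotone functions of a chosen group's
latent factor blended with independent noise.  The blend weight is the
Pearson correlation r = 2 sin(pi * rho_s / 6) that, for a bivariate normal,
yields the requested Spearman rho_s (rank correlations are preserved by the
monotone map to the percent scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import Direction, Fabric, IndicatorSpec, LogPolicy, Override, Subfabric
from .io import CountyTable, DEMOGRAPHIC_COLUMNS

__all__ = [
    "GroupSim",
    "SimSpec",
    "generate",
    "study_like_spec",
    "study_indicator_specs",
    "POPULATION_THRESHOLD",
]

#: boundary used when planting small counties (the analysis-exclusion cutoff)
POPULATION_THRESHOLD = 2000


@dataclass(frozen=True)
class GroupSim:
    """One latent factor and the indicators loading on it."""

    variables: tuple[str, ...]
    loadings: tuple[float, ...]
    directions: tuple[Direction, ...]

    def __post_init__(self) -> None:
        if not (len(self.variables) == len(self.loadings) == len(self.directions)):
            raise ValueError("variables, loadings, directions must align")
        for name, lam in zip(self.variables, self.loadings):
            if abs(lam) > 1.0:
                raise ValueError(f"variable {name!r}: |loading| must be <= 1, got {lam}")


@dataclass(frozen=True)
class SimSpec:
    """A complete stated world for one synthetic county table."""

    n_counties: int
    groups: dict[str, GroupSim]
    demographic_links: dict[str, tuple[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    n_small_counties: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_small_counties > self.n_counties:
            raise ValueError("n_small_counties cannot exceed n_counties")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for dem, (group, rho) in self.demographic_links.items():
            if group not in self.groups:
                raise ValueError(f"demographic {dem!r} linked to unknown group {group!r}")
            if abs(rho) >= 1.0:
                raise ValueError(
                    f"demographic {dem!r}: planted Spearman rho must satisfy |rho| < 1"
                )


def _county_ids(n: int) -> list[str]:
    # Texas-style FIPS: state 48, odd county codes 001..507 cover n <= 254
    if n <= 254:
        return [f"48{2 * i + 1:03d}" for i in range(n)]
    return [f"{i + 1:05d}" for i in range(n)]


def _populations(rng: np.random.Generator, n: int, n_small: int) -> np.ndarray:
    """Log-uniform county sizes with exactly ``n_small`` below the cutoff."""
    small = np.exp(rng.uniform(np.log(200), np.log(POPULATION_THRESHOLD), size=n_small))
    small = np.minimum(small, POPULATION_THRESHOLD - 1)
    large = np.exp(
        rng.uniform(np.log(POPULATION_THRESHOLD), np.log(2_000_000), size=n - n_small)
    )
    pops = np.concatenate([small, large])
    return np.floor(pops[rng.permutation(n)]).astype(int)


def generate(spec: SimSpec) -> CountyTable:
    """Draw one county table from the stated world.

    Deterministic in ``spec.seed``: identical specs yield identical tables.
    Ground truth (planted loadings, planted rank correlations, the Pearson
    blend weights, affine maps, seed) lands in ``table.meta["truth"]``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_counties
    ids = _county_ids(n)
    populations = _populations(rng, n, spec.n_small_counties)

    factors = {name: rng.standard_normal(n) for name in spec.groups}
    columns: dict[str, np.ndarray] = {}
    affine: dict[str, tuple[float, float]] = {}
    order: list[str] = []
    for gname, group in spec.groups.items():
        f = factors[gname]
        for var, lam, direction in zip(group.variables, group.loadings, group.directions):
            x = lam * f + np.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
            if direction is Direction.SECURITY:
                x = -x
            scale = float(rng.uniform(2.0, 30.0))
            offset = float(6.0 * scale + rng.uniform(0.0, 50.0))
            columns[var] = scale * x + offset
            affine[var] = (scale, offset)
            order.append(var)

    demo_r: dict[str, float] = {}
    demographics: dict[str, np.ndarray] = {}
    for dem in DEMOGRAPHIC_COLUMNS:
        noise = rng.standard_normal(n)
        link = spec.demographic_links.get(dem)
        if link is None:
            g = noise
            demo_r[dem] = 0.0
        else:
            gname, rho_s = link
            r = 2.0 * np.sin(np.pi * rho_s / 6.0)
            if abs(r) >= 1.0:
                raise ValueError(f"demographic {dem!r}: planted rho {rho_s} infeasible")
            g = r * factors[gname] + np.sqrt(1.0 - r * r) * noise
            demo_r[dem] = r
        demographics[dem] = 100.0 * stats.norm.cdf(g)

    if spec.missing_rate > 0:
        mask = rng.random((n, len(order))) < spec.missing_rate
        for j, var in enumerate(order):
            col = columns[var]
            col[mask[:, j]] = np.nan
            columns[var] = col

    data = pd.DataFrame({"county_id": ids, "population": populations})
    for dem in DEMOGRAPHIC_COLUMNS:
        data[dem] = demographics[dem]
    for var in order:
        data[var] = columns[var]

    truth = {
        "seed": spec.seed,
        "n_counties": n,
        "n_small_counties": spec.n_small_counties,
        "missing_rate": spec.missing_rate,
        "groups": {
            gname: {
                "variables": list(g.variables),
                "loadings": list(g.loadings),
                "directions": [d.value for d in g.directions],
            }
            for gname, g in spec.groups.items()
        },
        "demographic_links": {
            dem: {"group": link[0], "spearman_rho": link[1], "pearson_r": demo_r[dem]}
            for dem, link in spec.demographic_links.items()
        },
        "affine_maps": {var: list(ab) for var, ab in affine.items()},
    }
    return CountyTable(
        data=data,
        indicator_names=order,
        demographic_names=list(DEMOGRAPHIC_COLUMNS),
        # latent factor draws are kept out of "truth" (which is JSON-exported)
        # but exposed for planted-correlation recovery checks
        meta={"truth": truth, "latent": factors},
    )


# ---------------------------------------------------------------------------
# The published-study-like world: 254 counties, 20 below the population
# cutoff, groups and planted loadings mirroring the printed factor table.
# ---------------------------------------------------------------------------

_INS = Direction.INSECURITY
_SEC = Direction.SECURITY

# (variable, printed loading, direction, fabric, subfabric)
_STUDY_VARIABLES: list[tuple[str, float, Direction, Fabric, Subfabric | None]] = [
    ("poverty_pct", 0.94, _INS, Fabric.ECONOMIC, None),
    ("unemployment_pct", 0.50, _INS, Fabric.ECONOMIC, None),
    ("median_household_income", 0.92, _SEC, Fabric.ECONOMIC, None),
    ("gini_coefficient", -0.77, _INS, Fabric.ECONOMIC, None),
    ("food_stamps_pct", 0.80, _INS, Fabric.ECONOMIC, None),
    ("particulate_days", 0.41, _INS, Fabric.ENVIRONMENTAL, None),
    ("ozone_days", 0.75, _INS, Fabric.ENVIRONMENTAL, None),
    ("co2_emissions", -0.20, _INS, Fabric.ENVIRONMENTAL, None),
    ("natural_amenity_rank", 0.17, _SEC, Fabric.ENVIRONMENTAL, None),
    ("population_change", 0.79, _INS, Fabric.ENVIRONMENTAL, None),
    ("freshman_graduation_rate", 0.30, _SEC, Fabric.SOCIAL, Subfabric.EDUCATION),
    ("hs_graduate_pct", 0.96, _SEC, Fabric.SOCIAL, Subfabric.EDUCATION),
    ("some_college_pct", 0.68, _SEC, Fabric.SOCIAL, Subfabric.EDUCATION),
    ("bachelors_pct", 0.58, _SEC, Fabric.SOCIAL, Subfabric.EDUCATION),
    ("adult_literacy_below_pct", 0.95, _INS, Fabric.SOCIAL, Subfabric.EDUCATION),
    ("not_english_proficient_pct", 0.73, _INS, Fabric.SOCIAL, Subfabric.EDUCATION),
    ("life_expectancy", 0.84, _SEC, Fabric.SOCIAL, Subfabric.HEALTH),
    ("life_expectancy_change", -0.40, _SEC, Fabric.SOCIAL, Subfabric.HEALTH),
    ("premature_death_rate", 0.84, _INS, Fabric.SOCIAL, Subfabric.HEALTH),
    ("adult_obesity_pct", 0.65, _INS, Fabric.SOCIAL, Subfabric.HEALTH),
    ("motor_vehicle_mortality", 0.60, _INS, Fabric.SOCIAL, Subfabric.HEALTH),
    ("chlamydia_rate", 0.14, _INS, Fabric.SOCIAL, Subfabric.HEALTH),
    ("adult_uninsured_pct", -0.35, _INS, Fabric.SOCIAL, Subfabric.HEALTH),
    ("healthy_food_access_pct", 0.09, _SEC, Fabric.SOCIAL, Subfabric.HEALTH),
    ("violent_crime_rate", 0.82, _INS, Fabric.SOCIAL, Subfabric.CRIME),
    ("property_crime_rate", -0.10, _INS, Fabric.SOCIAL, Subfabric.CRIME),
    ("incarceration_rate", 0.79, _INS, Fabric.SOCIAL, Subfabric.CRIME),
    ("child_poverty_pct", 0.85, _INS, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
    ("mentally_unhealthy_days", 0.59, _INS, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
    ("teen_birth_rate", 0.80, _INS, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
    ("mortgage_foreclosure_rate", 0.25, _INS, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
    ("housing_vacancy_pct", -0.12, _INS, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
    ("insufficient_social_support_pct", 0.32, _INS, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
    ("grandparent_parental_role_pct", 0.60, _INS, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
    ("creative_share_pct", 0.87, _SEC, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
    ("commute_index", -0.06, _INS, Fabric.SOCIAL, Subfabric.SOCIAL_STRESS),
]


def study_indicator_specs() -> list[IndicatorSpec]:
    """The indicator dictionary matching :func:`study_like_spec`'s table."""
    return [
        IndicatorSpec(
            name=name,
            direction=direction,
            fabric=fabric,
            subfabric=subfabric,
            log_transform=LogPolicy.NONE,
            selection_override=Override.AUTO,
        )
        for name, _, direction, fabric, subfabric in _STUDY_VARIABLES
    ]


def study_like_spec(
    seed: int = 0,
    n_counties: int = 254,
    n_small_counties: int = 20,
    missing_rate: float = 0.02,
) -> SimSpec:
    """A ready-made world mirroring the published study's shape.

    254 Texas-like counties of which 20 fall below the population-2,000
    analysis cutoff; six factor groups carrying the printed loadings; mild
    missingness standing in for multi-agency gaps; demographic columns rank-
    linked to the economic, crime, and education factors with strengths in
    the range the study reports.
    """
    groups: dict[str, GroupSim] = {}
    for name, loading, direction, fabric, subfabric in _STUDY_VARIABLES:
        gname = subfabric.value if subfabric is not None else fabric.value
        prev = groups.get(gname, GroupSim((), (), ()))
        groups[gname] = GroupSim(
            prev.variables + (name,),
            prev.loadings + (loading,),
            prev.directions + (direction,),
        )
    return SimSpec(
        n_counties=n_counties,
        groups=groups,
        demographic_links={
            "pct_hispanic": ("economic", 0.43),
            "pct_african_american": ("crime", 0.33),
            "pct_foreign_born": ("education", 0.70),
        },
        missing_rate=missing_rate,
        n_small_counties=n_small_counties,
        seed=seed,
    )
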