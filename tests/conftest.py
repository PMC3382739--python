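import numpy as np
import pandas as pd
import pytest

from hsindex import CountyTable, Direction, Fabric, IndicatorSpec
from hsindex.simulate import generate, study_indicator_specs, study_like_spec

# printed first-factor loadings of the published study's factor table,
# keyed by group; the education block additionally declares one variable
# ("high school graduate, incl. equivalency") with no printed loading,
# bringing its declared row count to seven
PUBLISHED_LOADINGS = {
    "economic": {
        "poverty_pct": 0.94,
        "unemployment_pct": 0.50,
        "median_household_income": 0.92,
        "gini_coefficient": -0.77,
        "food_stamps_pct": 0.80,
    },
    "environmental": {
        "particulate_days": 0.41,
        "ozone_days": 0.75,
        "co2_emissions": -0.20,
        "natural_amenity_rank": 0.17,
        "population_change": 0.79,
    },
    "education": {
        "freshman_graduation_rate": 0.30,
        "hs_graduate_pct": 0.96,
        "some_college_pct": 0.68,
        "bachelors_pct": 0.58,
        "adult_literacy_below_pct": 0.95,
        "not_english_proficient_pct": 0.73,
    },
    "health": {
        "life_expectancy": 0.84,
        "life_expectancy_change": -0.40,
        "premature_death_rate": 0.84,
        "adult_obesity_pct": 0.65,
        "motor_vehicle_mortality": 0.60,
        "chlamydia_rate": 0.14,
        "adult_uninsured_pct": -0.35,
        "healthy_food_access_pct": 0.09,
    },
    "crime": {
        "violent_crime_rate": 0.82,
        "property_crime_rate": -0.10,
        "incarceration_rate": 0.79,
    },
    "social_stress": {
        "child_poverty_pct": 0.85,
        "mentally_unhealthy_days": 0.59,
        "teen_birth_rate": 0.80,
        "mortgage_foreclosure_rate": 0.25,
        "housing_vacancy_pct": -0.12,
        "insufficient_social_support_pct": 0.32,
        "grandparent_parental_role_pct": 0.60,
        "creative_share_pct": 0.87,
        "commute_index": -0.06,
    },
}


def population_pcf_loadings(lam: np.ndarray) -> tuple[float, np.ndarray]:
    """Infinite-n value of principal-component factoring under the
    single-factor model: leading eigenpair of lam lam' + diag(1 - lam^2)."""
    lam = np.asarray(lam, dtype=float)
    corr = np.outer(lam, lam) + np.diag(1.0 - lam**2)
    eigenvalues, eigenvectors = np.linalg.eigh(corr)
    vec = eigenvectors[:, -1]
    if vec.sum() < 0:
        vec = -vec
    return float(eigenvalues[-1]), vec * np.sqrt(eigenvalues[-1])


def make_table(indicators: dict[str, list[float]], populations=None,
               demographics: dict[str, list[float]] | None = None) -> CountyTable:
    """Small hand-built county table for unit tests."""
    n = len(next(iter(indicators.values())))
    data = pd.DataFrame({
        "county_id": [f"48{2 * i + 1:03d}" for i in range(n)],
        "population": populations if populations is not None else [10_000] * n,
    })
    demographics = demographics or {}
    for name, vals in demographics.items():
        data[name] = vals
    for name, vals in indicators.items():
        data[name] = vals
    return CountyTable(
        data=data,
        indicator_names=list(indicators),
        demographic_names=list(demographics),
    )


def flat_specs(names, direction=Direction.INSECURITY, fabric=Fabric.ECONOMIC):
    return [IndicatorSpec(name=n, direction=direction, fabric=fabric) for n in names]


@pytest.fixture(scope="session")
def study_specs():
    return study_indicator_specs()


@pytest.fixture(scope="session")
def study_table():
    return generate(study_like_spec(seed=11))


@pytest.fixture(scope="session")
def big_clean_table():
    """Large study-shaped panel, no small counties, no missingness."""
    return generate(
        study_like_spec(seed=5, n_counties=5000, n_small_counties=0, missing_rate=0.0)
    )
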