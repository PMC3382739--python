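# Methods

## The index model

The Human Security Index treats county-level insecurity as a hierarchy of
latent conditions. Three fabrics — Economic, Environmental, Social — each
summarize a handful of observed indicators; the Social Fabric is further
split into Education, Health, Crime & Punishment, and Social Stress
subcomponents. Each fabric/subfabric is modeled as one factor: the first
principal component of the correlation matrix of its prepared indicators.
Indicators that correlate strongly with that factor (|loading| above a
threshold) form the final instrument; scores are unweighted aggregations
of the selected, standardized, insecurity-aligned indicators. Higher
scores always mean higher insecurity.

This is deliberately the simplest defensible construction: one factor per
group, no rotation, no regression-weighted factor scores, no cross-fabric
weighting. The value of the package is that every rule in the chain is
explicit, configurable, and property-tested.

## Preparation pipeline and its order

Steps run as **filter → log → impute → z-score → reverse-code**. The
order is a design choice (the construction is usually described as a set
of steps, not a sequence):

- imputing before standardizing keeps the mean-0/sd-1 invariant exact over
  the full column, imputed cells included;
- reverse coding last makes it a pure sign flip of a standardized column,
  which gives the clean equivariance property (flipping a variable's
  direction flag exactly negates its prepared column).

Details:

- **Population filter**: counties with population < `min_population`
  (default 2,000) are removed; ≥ is retained.
- **Log transform**: off by default per variable. `natural_log` demands
  positive values and fails loudly (naming variable and county);
  `log_shift` uses ln(x − min + 1) for metrics that can touch zero. Which
  real-world variables warrant a log is a data-dictionary decision, so it
  lives in the indicator configuration, not in code.
- **Missingness**: a variable whose missing fraction exceeds
  `max_missing_fraction` (default 0.25) is dropped — the "insufficient
  data" exclusion — and recorded with a reason; sparser gaps are filled
  with the column median (robust for skewed county metrics; the mean
  would be pulled by the large-county tail).
- **Standardization** uses the sample (n−1) standard deviation. Constant
  columns cannot be standardized and are dropped with a recorded reason
  rather than failing the whole run.

Affine invariance (a·x+b, a>0, leaves a prepared column unchanged) holds
whenever no log transform is applied, and is exercised by tests because
the synthetic generator deliberately emits each indicator through a
random positive affine map.

## Factoring and selection

`principal_factor` returns the leading eigenpair of the group correlation
matrix, with loadings **ℓ** = √λ₁·**v₁** so that Σℓⱼ² = λ₁ and each ℓⱼ is
the correlation between indicator j and the component. Eigenvectors are
defined only up to sign, so a deterministic orientation is imposed:
loadings sum positive; on an exact zero sum, the largest-magnitude
loading is made positive.

Selection defaults to **strict** comparison on **absolute** loadings
(|ℓ| > 0.5). The strict-absolute combination is the only rule consistent
with all the published per-group selection counts simultaneously (it
excludes a printed 0.50 while keeping a −0.77). Inclusive (≥) and
signed-comparison variants are configurable for sensitivity analysis.
Post-hoc editorial departures from the rule are expressed through
per-variable `force_include` / `force_exclude` overrides in the indicator
configuration — never hard-coded.

Groups reduced below two surviving variables yield a degenerate result
(no eigenvalue, only force-included variables selected) with a warning
instead of an exception, so one bad variable cannot silently sink a run.

## Aggregation

Default aggregation is the **sum** of selected prepared variables; mean
is offered because group sizes differ (2–5 variables post-selection) and
a user may want cross-fabric comparability. Because both are strictly
increasing functions of the same variable set per score, downstream
rank-based conclusions are identical under either mode (asserted to
1e-12 in tests). The total HSI aggregates all constituent variables,
which in sum mode equals the sum of the three fabric sums. By default no
loading-sign realignment is applied at aggregation time: the direction
metadata fixed at recoding is treated as the sole orientation authority,
and a variable with a negative loading still enters with its recoded
sign (an `align_by_loading_sign` flag exists for sensitivity analysis).

## Association analysis

Spearman's ρ is the Pearson correlation of midrank vectors. The default
p-value is the two-sided t approximation (t = ρ√((n−2)/(1−ρ²)), n−2 df),
the standard choice at a few hundred observations; |ρ| = 1 maps to p = 0.
For n ≤ 10 an exact permutation p (full enumeration over orderings of one
vector, ties preserved) is available as `method="exact"` and is used to
validate the machinery. Raw p-values are the headline numbers, as is
conventional for this kind of descriptive correlation table; a
Holm-adjusted column is emitted alongside but never drives the
significance flags. Demographic percentages are used raw: Spearman is
invariant to monotone transforms, so standardizing them would change
nothing.

## Synthetic data: what it emulates and what it does not

`generate` draws, per group, one standard-normal latent factor f per
county and indicators xⱼ = λⱼ·f + √(1−λⱼ²)·εⱼ with independent
standard-normal noise, so corr(xⱼ, xₖ) = λⱼλₖ. Security-aligned
variables are emitted with flipped sign (preparation's reverse coding
restores them), and each indicator passes through a fixed positive affine
map (recorded in the output metadata) to mimic heterogeneous agency
metrics. Populations are log-uniform with an exact planted count below
the 2,000 cutoff; missing cells are placed uniformly at random.

Demographic columns are monotone images (100·Φ) of a blend
r·f + √(1−r²)·η, with the Pearson blend weight r = 2·sin(π·ρₛ/6) chosen
so the (factor, demographic) pair of a bivariate normal has exactly the
planted Spearman ρₛ. The generator exposes the latent factor draws in
`table.meta["latent"]` so planted-correlation recovery can be checked
against the quantity the correlation is actually planted for.

The ready-made `study_like_spec()` world: 254 counties, 20 small, six
groups carrying the published printed loadings, 2% missingness (a mild
stand-in for multi-agency gaps), and demographic links
(% Hispanic ↔ economic ρₛ=0.43, % African American ↔ crime ρₛ=0.33,
% foreign born ↔ education ρₛ=0.70) mirroring the sign and rough
magnitude of the strongest published associations.

Not emulated: spatial autocorrelation between neighboring counties,
realistic marginal shapes of specific indicators, cross-group factor
correlations, and informative (non-random) missingness. A green test on
this generator therefore establishes the pipeline's algebra and its
statistical calibration under a clean single-factor world — not fidelity
to any real county system.

## Known bias of principal-component loadings (important)

Under the single-factor model the population correlation matrix is
**R** = λλᵀ + diag(1−λ²). Its leading eigenvector is proportional to λ
only when all |λⱼ| are equal; otherwise the principal-component loadings
√λ₁·v₁ are asymptotically **biased away from the planted λ** — the
well-known tendency of PCA-style loadings to overstate factor loadings,
strongest for small loadings in groups with a weak factor. For the
printed loading sets used by `study_like_spec()` the asymptotic
discrepancy ranges from ≈0.09 (social stress) to ≈0.20 (environmental).
Two consequences, both verified by tests:

- estimated loadings converge to the *population principal-component
  value* (the leading eigenpair of **R**), not to λ; recovery of λ itself
  to within 0.05 is impossible for these loading sets no matter the
  sample size, and the acceptance test stating that bound fails honestly;
- at large n the selection rule resolves against the population
  principal-component loadings: e.g. a planted λ = 0.50 has population
  loading ≈ 0.61 and is selected, and a planted 0.41 in a weak group can
  cross 0.5 the same way.

Anyone using this package to *design* an instrument should read observed
loadings as correlations with the extracted component, not as estimates
of latent-factor loadings; an iterated principal-axis or maximum-
likelihood factoring would be needed for the latter.

## Numerical choices

- Eigen-decomposition via symmetric `eigh`; symmetry of inputs enforced
  to 1e-10, exact symmetrization of computed correlation matrices.
- Ranking ties in `rank_extremes` broken lexicographically by county id
  (stable mergesort), making reports deterministic.
- Score CSVs round-trip at full float precision (repr-based writing).
- County ids are opaque strings throughout; leading zeros survive I/O.
- All generator randomness flows from one `numpy` Generator seeded by the
  spec, so equal specs give byte-identical CSV output.

## Limitations

- One factor per group by construction; no rotation or multi-factor
  extraction.
- The p-value t approximation is poor below n ≈ 10; exact mode exists but
  is capped at n = 10 by cost.
- Imputation is unconditional-median; no model-based or neighbor-informed
  filling.
- GeoJSON export joins scores onto supplied geometry only; no projection,
  rendering, or topology validation beyond structural checks.
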