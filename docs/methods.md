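# Methods

`nsurplus` implements a regional nitrogen-surplus accounting and scenario
pipeline for EU-style agricultural landscapes: soil-surface N budgets at
sub-national (NUTS-2-like) resolution, unsupervised classification of
regions into four N-surplus typologies, a one-parameter yield-response
model of technology, and 2030 projection of surplus under input-reduction
scenarios against the Green Deal Farm-to-Fork goal of halving nutrient
losses.

## Budget model

The accounting boundary is the soil–plant system (soil-surface or gross
balance).  For region *i*, year *y* and ensemble member *m*:

    Surp(i,y,m) = In_fert + In_man + In_dep + In_bnf − Out_crops − Out_past

with all fluxes in kgN ha⁻¹ yr⁻¹ on the area basis of their sector:
agricultural fluxes per hectare of agricultural area, non-agricultural
(deposition, fixation, forest harvest) per hectare of non-agricultural
area.  Manure is counted as applied to soil (storage losses excluded
upstream).  Nitrogen use efficiency is `NUE = 100·Out/In` (%).  Negative
surpluses (soil N mining) are retained, never clipped; `flag_negative`
locates them.

Aggregation to typology, country or EU level takes area-weighted means of
the per-ha fluxes with the sector's own (year-specific) area as weight,
which makes mass closure exact at every scope: aggregate surplus equals
aggregate inputs minus aggregate outputs, and aggregation is associative
(region→country→EU equals region→EU).  Mass totals use 1 Tg = 10⁹ kg.
Because areas are ordinary per-record columns, a user who prefers fixed
(e.g. modern) areas can simply supply them; nothing in the pipeline
assumes areas vary or stay constant.

Uncertainty enters through a 16-member ensemble formed as the product of
2 fertilizer × 4 manure × 2 pasture-removal data variants.  Headline
results use the member-mean series; min–max bands rerun the full pipeline
per member.  The budget is linear, so the ensemble mean of the surplus
equals the surplus of the ensemble-mean components — asserted in tests.

Development-phase summaries split the record into an early development
phase (1940–1985) and a sustainable intensification phase (1986–2019) and
report mean component masses (TgN yr⁻¹), input shares (%) and NUE per
phase.  Shares are rounded only in reports, never internally.

## Typology classification

Each region's feature vector is the decadal mean (1850s–2010s, 17
decades) of twelve variables: the two fertilizer-input variants, the four
manure-input variants, fixation, deposition, the two total-output
(pasture-removal) variants, and the agricultural and non-agricultural
areas.  Flux variables are first converted to the per-total-area mass
basis so that regions with small agricultural fractions are not inflated.
Columns are z-scored (population sd); effectively constant columns are
dropped with a warning.  Keeping the full decadal trajectory (12 × 17 =
204 columns) rather than centennial means preserves the *shape* of each
region's development, which is what distinguishes the typologies; a
`collapse_decades` switch provides the 12-column alternative.

Clustering uses a 2 × 2 self-organizing map (Kohonen network) trained in
blended-batch mode: every epoch assigns all regions to their best-matching
unit (BMU) by Euclidean distance, forms Gaussian-neighborhood-weighted
batch targets per node, and moves node weights a learning-rate step toward
them.  Defaults: 500 epochs, neighborhood radius decaying 1 → 0.1,
learning rate 0.5 → 0.01 (both geometric), weights initialized on the
first principal plane with a deterministic SVD sign convention.  Batch
updates make the partition independent of region order, and fixed inputs
plus seed give bit-identical weights.  Empty nodes are warned about and
retained.

Cluster-count selection is diagnosed with the Davies–Bouldin index
(mean over clusters of `max_j (S_i + S_j)/M_ij`, S = mean distance to
centroid, M = centroid distance; lower = better separated), computed for
k = 2…6 (2×2 lattice for k = 4, 1×k chains otherwise).  The minimum is
flagged, not silently adopted.  Identical centroids raise instead of
dividing by zero.

Nodes become labels by an explicit rule: the node with the lowest mean
agricultural-area fraction is NAT (natural landscapes); among the rest,
the highest centennial manure share of inputs is MAN, then the highest
fertilizer share is FERT, and the remainder is MOD.  Ties fall back to
surplus magnitude (highest → MAN) and raise if still unresolved.  NAT is
excluded from all downstream agricultural-surplus analysis.

## Yield response and technology

N output responds to N input through the saturating hyperbola
`Out = c·In/(c + In)`; the coefficient *c* (kgN ha⁻¹ yr⁻¹) is the
asymptotic maximum achievable output and parameterizes the prevailing
technological and management practices (TMPs).  Given window-mean input
and output the coefficient has the exact closed form
`c = In·Out/(In − Out)`, defined whenever 0 < Out < In.  The default fit
uses window means (baseline window 2015–2019); a least-squares fit to the
annual points inside the window is available behind `method="annual-lsq"`.
Fits are made on area-weighted typology/country/EU aggregates, not per
region.

Two 2030 technology modes:

* **same** — `c(2030) = c_baseline` (2015–2019 window);
* **improved** — *c* is estimated on the eight windows 1981–1985, …,
  2016–2019 (seven 5-year plus one 4-year), regressed by OLS on the
  window-midpoint year (arithmetic mean of the endpoints: 1983.0 …
  2017.5), and extrapolated to 2030.  `Δc_TMP = c(2030)/c_baseline − 1`,
  with the baseline *c* from 2015–2019 even though the last trend window
  is 2016–2019.  The 95% interval is the mean-response (confidence, not
  prediction) interval from the t distribution with 6 degrees of freedom;
  its low/high bounds propagate into scenario bounds.  A perfectly flat
  *c* history makes the improved mode identical to the same mode.

The implied surplus `S(In) = In²/(c + In)` is strictly increasing in In
and decreasing in c, so the input level hitting a surplus target inverts
in closed form: `In = (S + √(S² + 4cS))/2`.  `NUE = c/(c + In)` strictly
decreases with input — the familiar inefficiency of high-input systems.

## Scenarios

All intervention scenarios share one mechanism: fertilizer and manure
baseline means are scaled by `(1 − r_fert)` and `(1 − r_man)`; deposition
and fixation have no policy lever and stay at baseline; output follows
the response at the chosen technology mode; reductions are percent of
the baseline surplus/output.  Named story lines: GD-F (20% fertilizer),
FAO-F (43%), FAO-FM (43% + 4% manure), BAF (20% + 10%), LAP (20% + 20%).

BAU extrapolates the 1961–2019 surplus with a GLM — negative-binomial
family, log link — on a natural cubic spline basis of year.  Natural
splines are linear beyond the boundary knots, which gives a well-defined
log-linear extrapolation to 2030; a surplus increase shows up as a
negative reduction.  Continuous surpluses are rescaled by 10 into
count-like magnitudes for the over-dispersion-tolerant family and scaled
back for reporting; a Gaussian identity-link fallback covers series with
non-positive values, where the log link is undefined.  The default 5
knots (at year quantiles) is deliberately stiff: an unpenalized basis
with more knots tracks noise near the boundary and destabilizes the
11-year extrapolation, while 5 knots keep decade-scale curvature.

The bottom-up analysis evaluates the same arithmetic on the full
101 × 101 grid of reduction fractions (1% step; the axes are exact k/100
values so the five named scenarios are bitwise equal to their grid
cells).  Both surfaces are monotone non-decreasing in either cut, and the
improved-TMP surface dominates the same-TMP surface cellwise whenever
c(2030) > c_baseline.  The 50%-reduction frontier is interpolated
linearly between bracketing cells and cross-checked against the analytic
inversion.  The Green Deal target zone is `r_fert ≥ 0.20` with reduction
in [50%, 100%].

The EU-level bottom-up curve uses a single EU-aggregate *c*; running the
same functions at `scope="typology"` gives the per-typology alternative.

## Synthetic data

The generator emulates the structure the analysis assumes — 393 regions,
years 1850–2019, the 16-member ensemble, two sectors — with four
archetypes (MAN, FERT, MOD, NAT) mixed 25/30/30/15% by default.  Each
input component follows a logistic rise (midpoint mid-20th century)
multiplied by an exponential post-1985 relaxation, so the aggregate
surplus peaks near 1985 and declines afterwards.  Outputs are generated
from inputs through the hyperbolic response with a slowly rising *c*
(logistic plus a small positive linear term after 1980), so the response
fit and trend extrapolation operate on data satisfying their own model —
recovery tests are therefore informative about the estimator, not about
model misspecification.  Archetype levels are set so that MAN manure
shares exceed 60% in the 1940s, modern surpluses order MAN > FERT > MOD
≫ NAT, and agricultural NUE stays inside (20%, 80%) in every year, which
keeps every window's *c* fit well-posed.

Regional heterogeneity is a lognormal intensity multiplier (sd 0.10)
shared by inputs and *c* (leaving NUE untouched) plus milder
per-component tilts (sd 0.05); observation noise is multiplicative
lognormal (sd 0.05) per record and component.  The heterogeneity default
is chosen as the largest round value at which the four archetypes remain
recoverable from the z-scored decadal features (adjusted Rand index
≥ 0.9 for the SOM and for a k-means oracle alike, n ≥ 100 regions);
beyond that the FERT and MOD populations genuinely interpenetrate and no
classifier can separate them, which would make every downstream recovery
test vacuous.  Ensemble members multiply fertilizer by {0.95, 1.05},
manure by {0.88, 0.96, 1.04, 1.12} and pasture removal by {0.92, 1.08}.
All draws flow from a single seeded generator; a fixed seed gives
byte-identical tables.

What the generator does **not** emulate: spatial (gridded) structure and
neighborhood correlation, crop-mix and livestock detail, policy
discontinuities (e.g. 1990s reforms appear only as the smooth decline),
heavy-tailed or autocorrelated observation error, and real-data cases
where the hyperbolic response is misspecified.  Passing tests therefore
demonstrate correctness of the estimators and projections under the
model's own assumptions, not the validity of those assumptions for any
real record.

## Numerical choices and problem sizes

Ties in BMU assignment resolve to the lowest node index; feature columns
whose sd is below 1e-12 relative are treated as constant and dropped;
the DBI raises on identical centroids; `fit_c` refuses non-positive
surpluses rather than returning negative coefficients; grid axes are
exact decimal fractions.  The test suite runs the full pipeline on a
deterministic 12-region miniature (3 per archetype) and recovery checks
on 120 regions; `scripts/acceptance.py` runs the complete study at the
full 393-region scale, which completes in well under a minute.

## Known limitations

The technology trend is a straight line through eight points — adequate
for a decade of extrapolation, silent on saturation of technological
progress.  The BAU spline family applies a count-data likelihood to
continuous data (the rescaling is a documented convenience, and the
Gaussian fallback is exact in its own terms).  Country-level fits inherit
whatever regions a country happens to contain; countries whose baseline
output exceeds input are excluded with a warning rather than imputed.
N-loss pathway partitioning (leaching, volatilization, denitrification)
and economic/trade feedbacks are out of scope.
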