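# Methods

This package reconstructs how tree height and seasonal climate shape
conifer xylem anatomy, from raw inputs (per-tracheid measurements,
ring-width series, monthly climate, tree metadata) to fitted hierarchical
models and counterfactual predictions. This note documents the models, the
defaults, the numerical choices, and what the synthetic data can and
cannot show.

## Height and diameter reconstruction

Annual stem diameter is rebuilt backwards from the DBH measured at
sampling: `DBH_{t-1} = DBH_t - 2 * rw_t` (ring widths in mm, DBH in cm).
Missing rings are first filled with the mean of measured widths within 10
calendar years on each side of the gap; near series ends, all available
years on a side are used, and consecutive gaps are imputed jointly from
measured neighbours only, so the result does not depend on fill-in order.
The diameter remaining inside the innermost ring (distance-to-pith
allowance) is a per-tree parameter, default 0. Because imputed widths can
exceed the deleted ones, the implied pith diameter may undershoot zero
slightly; only a negative *end-of-year* DBH is treated as inconsistent
input.

Annual height is linear in reconstructed DBH, anchored at the coring
height for a hypothetical DBH of zero and the measured total height at the
sampling-year DBH:

    h_it = h_i0 + a_i * DBH_it,   a_i = (h_sampling - h_i0) / DBH_sampling.

This linear interpolation is adequate for trees still on the rising limb
of their height-diameter curve; it is *not* the site allometry below.

## Site allometry

The site height-diameter law is the saturating form

    h(D) = h_max * exp(a * exp(-b * D)),   h_max > 0, a < 0, b > 0,

rising from `h_max * e^a` at D = 0 toward the asymptote `h_max`. The
parameters are estimated by bounded nonlinear least squares with a
heuristic start (`h_max = 1.05 * max(h)`, rate `b` scaled to the mean DBH)
plus 20 jittered multistarts, keeping the best converged solution. The
form was chosen because it satisfies every behaviour required of the
height law here: monotone rise, a finite nonzero height at zero diameter,
an asymptote approached from below, and scale consistency (multiplying
heights by c multiplies `h_max` by c and leaves `a`, `b` unchanged).

The regional curve (expected ring width vs. cambial age) is the age-wise
mean smoothed by a discrete penalized (Whittaker-type) smoother with both
first- and second-difference penalties, weighted by ring counts:

    min_z  sum_a n_a (z_a - ybar_a)^2 + s^2 ||D1 z||^2 + s^4 ||D2 z||^2.

Span `s` defaults to 10% of the maximum age; `s = 0` returns the raw
age-wise means, and the stiff limit (`s` beyond 50x the maximum age,
handled in closed form) is the global mean ring width. The first-
difference term is what makes the stiff limit a *constant* rather than a
straight line. Twice the cumulative curve is the mean diameter-age
trajectory; composing it with the height law yields the age -> (diameter,
height) ontogeny per site.

## Per-cell traits and chronologies

A tracheid is latewood when Mork's criterion holds: `4 * CWT_rad / LD_rad
>= 1`, i.e. the doubled double wall fills the radial lumen. The boundary
case counts as latewood (the historical "wall >= lumen" rule), and the
radial lumen diameter is the default denominator; both are configuration
options because conventions differ between labs.

Per cell: conduit reinforcement `TB^2 = (2 * CWT_s / B_s)^2` on the side
`s` with the *thinner* single wall (ties resolve to radial), with `B_s`
the length of that same wall; anatomical density `DEN = CWA / (CWA + LA)`;
mean wall thickness `CWT = (CWT_rad + CWT_tan) / 2`. Annual chronologies
are unweighted means of the per-cell values within tree x year x ring
portion. Density is averaged per cell (mean of ratios) to match the other
traits; a ratio-of-sums variant is available for sensitivity checks. Cells
flagged non-tracheid are dropped before any computation.

## Seasonal climate

Each ring year y aggregates: previous fall (Sep-Nov of y-1), previous
winter (Dec of y-1 through Feb of y), spring (Mar-May) and summer
(Jun-Aug). Temperature by mean, precipitation by sum (the mean option
differs by a constant factor 3 that standardization absorbs). A ring year
is emitted only when all 12 contributing months exist; leading years are
dropped with a warning, or raise with the missing months named when years
were requested explicitly.

## The mixed model

Each trait x portion (8 models) is fitted separately. TB^2 and CWT are
log-transformed; all numeric responses and predictors are then z-scored
globally (height and squared height separately, so both carry their own
scale). Fixed effects: intercept, two site indicators (reference W-D),
h, h^2, eight seasonal predictors, and sixteen site x climate
interactions — 29 coefficients. Random effects: per-tree intercept and
slopes for h and h^2 with *diagonal* covariance. Errors are AR1 within
tree with per-tree relative SD multipliers (first tree fixed at 1 for
identifiability).

Estimation is REML. With `V_i = Z_i D Z_i' + sigma^2 w_i^2 R_i(phi)` and
`R_i[j,k] = phi^|year_j - year_k|` (continuous-lag AR1, so year gaps enter
directly and relabeling years changes nothing), the residual variance and
the fixed effects are profiled out analytically; the remaining parameters
are optimized unconstrained (log SDs relative to sigma, Fisher-z of phi,
log weight multipliers) by L-BFGS-B at tolerance 1e-8, with up to five
jittered multistarts when the first start fails. Random-effect variances
may collapse to the boundary; such fits are flagged, not errors. The
per-tree evaluation uses Cholesky factorizations (batched when all trees
share a year grid); a deliberately independent dense N x N assembly of the
same covariance lives in `xylemkit.validation` and is used only for
cross-checking.

Wald t tests use an inner-outer degrees-of-freedom convention: terms that
vary within trees are tested at `N - n_trees - p_within`, terms constant
within trees (the site indicators) at `n_trees - p_between`. This mirrors
the convention of the standard mixed-model software for grouped data; it
is a heuristic, and exact replication of any particular package's df is
not claimed. Stars: * p<0.05, ** p<0.01, *** p<0.001.

Marginal site means are evaluated at zero (the mean) of every standardized
covariate, where interactions vanish, so each site mean is intercept +
site effect. Pairwise differences use the studentized-range distribution
(Tukey) with the between-tree df, and the compact letter display comes
from maximal cliques of the not-significantly-different graph.

Counterfactual predictions zero the held variable in the standardized
design — for height, both h and h^2 and the corresponding random-slope
columns; for summer temperature, the main effect and its site
interactions — and push the dataset through the fixed effects plus the
tree-level random-effect predictions. Predictions are tree-conditional by
default (the models exist to separate individual growth trajectories from
climate), with a population-level flag.

## Synthetic data

The generator emulates a three-site boreal treeline study: W-D (warm,
dry, the reference site), C-D (cold, dry) and C-M (cold, moist), six
trees per site, monthly climate 1901-2015 drawn around site-specific
normals (temperature Gaussian, sd 1.5 degC; precipitation Gaussian with
CV 0.35, truncated at zero). Ring widths follow a negative-exponential
age trend (site-specific juvenile width 1.2-2.0 mm decaying with a
30-year time constant to 0.3-0.5 mm) with lognormal noise (CV 0.25);
missing rings are deleted with probability 0.02 (never the first or
sampling-year ring). Sampling DBH is exactly twice the cumulative ring
width plus the pith allowance (default 0), and sampling height is the
site height law at that DBH, so reconstruction is exactly invertible at
zero noise.

Ground truth lives on annual earlywood/latewood means — the level the
statistical model addresses. Per trait x portion, the mean follows the
same linear structure the model estimates (intercept, site offsets,
height terms, seasonal climate, optional site x climate interactions)
plus per-tree random effects (SDs expressed as multipliers — 0.8 / 0.4 /
0.2 — of each trait's own residual SD, so the random-effect scale tracks
the trait's units), AR1(0.4) errors, and per-tree residual scale
multipliers drawn lognormal (sd 0.25). The last 80 rings of each tree
with complete seasonal climate enter the cell stage. Default effect sizes
encode the headline qualitative structure (positive earlywood height
effect on lumen area, a -0.35 log-unit height effect on earlywood TB^2,
positive latewood summer-temperature effects on CWT and density at the
cold sites); they were chosen once, at design time, to be detectable at
the study's size under the h/h^2 collinearity that the design implies.

Cells (24 per ring, earlywood fraction 2/3) are drawn around the annual
portion means: additive Gaussian noise for LA and DEN, mean-one
multiplicative lognormal noise for the log-scale traits, then monotone
linear within-ring ramps (lumen shrinking, walls thickening; normalized
to mean 1 within each portion so annual means are preserved). Geometry is
assembled per cell: square lumen (`LD = sqrt(LA)`), a small random
radial/tangential wall asymmetry, wall lengths set so the cell's TB^2 is
reproduced exactly on either side, and wall area derived from the cell's
density. Because the four traits are drawn independently, wall area is
only statistically consistent with the perimeter-times-thickness
geometry: centred on it, with 95% of cells within a factor 2.5 at default
noise. Default intercepts (earlywood LA 900 um^2, CWT 2.5 um, latewood
LA 120 um^2, CWT 5 um, ...) were chosen so the geometric and
density-derived wall areas agree and latewood cells satisfy the Mork
criterion with a margin that survives default noise.

What passing tests on this generator do *not* show about real data: no
image-segmentation errors or missing cell walls, no dating error, no
within-ring climate signal (the truth is annual), no correlated trait
draws within a cell beyond the geometric links above, no stand dynamics,
fire or competition. The generator validates the *statistical machinery*,
not the biology.

## Validation studies and sizes

`xylemkit.studies` packages the validation experiments: the structured
REML likelihood is compared with the dense oracle on 20 random instances
(<= 5 trees x <= 8 years, gaps included) at 3 random parameter points
each (agreement to 1e-8 demanded; observed ~1e-12); degenerate
covariances reduce to OLS/GLS closed forms; every deterministic stage is
checked against brute-force oracles on random inputs; and the replicated
recovery study regenerates and refits the full design (18 trees, 3
sites, ~80 years, all 29 coefficients, weights and AR1 estimated) 50
times. From it we report the bias of the earlywood LA height coefficient
in Monte-Carlo SEs, its 95% Wald coverage, the type-I error pooled over
the ~22 truly-null coefficients of that model (pooling gives the rate a
usefully small Monte-Carlo error at 50 replicates), and the fraction of
replicates reproducing the injected sign/significance pattern. Fifty
replicates keeps the full study within a few minutes on one CPU while
leaving the Monte-Carlo bands meaningful.

## Known limitations

- The AR1 coefficient estimated from chronologies understates the
  generative phi slightly: within-ring sampling noise adds a white layer
  on top of the AR1 annual signal, attenuating lag-1 autocorrelation
  (e.g. truth 0.4 -> fitted ~0.30 at default cell counts). Fixed effects
  are unaffected; this is a property of the data, not an estimator bug.
- Denominator df are heuristic (above); p-values for weak effects should
  be read accordingly.
- The weight multipliers are only identified relative to tree 1; with 18
  trees and ~80 years each they are estimated with moderate precision.
- The Tucson writer emits one series per tree (no multi-radius support)
  and codes missing rings as 0.
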