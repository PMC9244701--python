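# Methods

This note documents the statistical machinery behind `standpattern`: the
estimators, their null models and defaults, the synthetic study the test
suite runs against, and the numerical and design choices that were
genuinely open.

## Stand structure

**DBH classes and age grades.** DBH (cm) is binned into 21 contiguous
4-cm classes, right-closed — class k covers (4(k−1), 4k], class 21 pools
everything above 80 cm — and into four right-closed age grades used as an
age proxy: young (1, 15], near-mature (15, 30], mature (30, 50], old
(50, ∞). Right closure is applied uniformly, so a 4.0-cm stem is class 1
and a 15.0-cm stem is young. DBH ≤ 1 cm is below the classification floor
and rejected rather than silently binned.

**Density and cover.** SDI is trees per hectare (reported rounded to the
nearest integer); CPA is the area of the union of crown discs (centre =
stem, diameter = CD), clipped at the plot boundary, as a percentage of
plot area. Crowns are modelled as circles because only a scalar crown
diameter is recorded. The union is evaluated on a 0.1-m raster with a
cell-centre inclusion test; against a seeded Monte-Carlo point-sampling
oracle this agrees within 0.5 percentage points on random plots (tested),
and overlapping crowns are never double-counted by construction. Biometric
mean ± sd use the population denominator n.

**Population-structure fits.** The per-class histogram (class index k =
1..21 vs count) is fitted by nonlinear least squares with two candidate
forms:

* decreasing logistic `count(k) = a / (1 + b e^{c k})`, a, b, c > 0 — a
  plateau-then-decline (reversed-J) shape typical of regenerating stands;
* Gaussian `count(k) = a exp(−(k−μ)² / (2σ²))` — a bell shape typical of
  stands dominated by intermediate classes.

Each form is fitted from a small set of fixed multistarts (five for the
logistic), tolerances 1e−8, at most 500 function evaluations per start;
the model with the higher R² = 1 − SS_res/SS_tot wins, ties going to the
Gaussian. Fewer than four non-empty classes is a fit error. The trend
label is *growing* when the logistic wins and young% > old%, otherwise
*stable* while young% ≥ 15, else *temporarily stable*. The 15% threshold
(configurable) separates the stable and temporarily-stable grade mixes of
the emulated study (18% vs 14% young) and is a judgement call, not an
estimate; note that a noisy Gaussian histogram can sit either side of it
when the true young share is near 15%.

## Point-pattern statistics

**Estimators.** For n stems in a window of area A,

    K(r) = (A / n²) Σ_{i≠j} 1{d_ij ≤ r} / w_ij
    g(r) = [Σ_{i≠j} 1{r−h/2 < d_ij ≤ r+h/2} / w_ij] / (λ n π((r+h/2)² − (r−h/2)²)),

with λ = n/A and ring width h. The ring estimator is the box-kernel
discretisation of g = (2πr)⁻¹ dK/dr; computing it directly from annulus
counts avoids differentiation noise. The default r-grid is 1..25 m in 1-m
steps with h = 1 m (r = 0 excluded; the first ring may not reach below
zero). Under CSR, K(r) = πr² and g ≡ 1; the estimates are exactly
calibrated up to the (n−1)/n conditioning factor (≤ 0.2% at n = 500).

**Edge correction.** Default is Ripley's isotropic weight: w_ij is the
fraction of the circle of radius d_ij centred on stem i lying inside the
rectangle, computed in closed form by inclusion-exclusion over the four
edge half-planes (per-edge arcs 2·acos(d/r), minus doubly-counted corner
arcs π/2 − asin(d₁/r) − asin(d₂/r) where d₁² + d₂² < r²; opposite-edge
arcs cannot intersect, so the expression is exact for any r and centre
inside the window). Translation correction and no correction are options.
Positions are treated as continuous coordinates; no grid discretisation
is applied.

**CSR envelopes.** The observed g(r) is compared against the pointwise
minimum/maximum of 199 seeded CSR simulations drawn with the same n in
the same window (a binomial process — conditioning on the observed count
is the convention for envelope tests). Min/max envelopes from s
simulations have nominal pointwise two-sided level 2/(s+1), i.e. 1% for
s = 199 (a "99% simulation interval"); the measured exceedance for CSR
data sits at that level (tested over 500 replicates). Per-r labels follow
the envelope comparison. The overall plot label is *aggregated* when g
exceeds the upper envelope on at least 10% of the r values; an excess is
checked first because clustering concentrated at small scales is
necessarily compensated by deficits at larger scales, so a clustered
pattern may lie below the envelope on more r values than above it.
Otherwise *regular* when g is below the lower envelope on ≥ 10% of r
values, else *random*. With 25 r values, the false-positive rate of the
10% rule (≥ 3 values outside one side) under CSR is of order 10⁻³.

**Aggregation indices.**

* ANN (Clark–Evans): mean nearest-neighbour distance over its CSR
  expectation ½√(A/n); < 1 aggregated. Significance by the analytic
  normal test with SE = 0.26136/√(n²/A). No boundary adjustment by
  default (the Donnelly perimeter correction is an option); at the
  emulated densities the uncorrected bias is ≈ +2%.
* Hopkins–Skellam: Σ P_i² / Σ I_i², with P_i the distances from
  min(n, 100) seeded uniform locations to the nearest stem and I_i the
  nearest-neighbour distances of an equal-sized seeded sample of stems
  drawn without replacement; > 1 aggregated.
* David–Moore: quadrat variance-to-mean ratio Σ(x_i − x̄)²/(x̄(q−1));
  Morisita: I_δ = q Σ x_i(x_i−1)/(N(N−1)). Both on square quadrats that
  must exactly tile the window (default side 10 m, 25 quadrats per plot —
  the quadrat size is a package choice, made configurable).
* Significance for HSI/DMI/Morisita uses a seeded 199-draw Monte-Carlo
  CSR null (for the quadrat indices the null reduces to a uniform
  multinomial, no geometry needed), reporting the standardised score
  (value − null mean)/null sd and a two-sided rank p; a closed-form t
  statistic was deliberately not invented for these indices. An index
  that is not significant at 0.05 is labelled random regardless of its
  direction.

**Kernel intensity.** Each stem spreads 1/(πR²) trees m⁻² uniformly over
the disc of radius R = 5 m (Epanechnikov optional), summed on a 1-m grid
evaluated at cell centres. No boundary renormalisation is applied, so the
surface integrates to n only when discs fit inside the window and fades
at the edges; the maps are descriptive, not density estimates for
inference.

**Index–environment correlations.** Pearson r with two-sided p from the t
transform on n − 2 df, pairwise-complete over plots (missing covariates
are explicit `None`s, never zeros). With 18 plots, |r| ≳ 0.468 is needed
for p < 0.05. No multiple-testing adjustment is applied across the five
factors; flags are raw per-pair significance at 0.05 and 0.01, so one
expects ~5% false positives per factor under independence.

## The synthetic study

The generator emulates an 18-plot design — three transects × six
50 m × 50 m plots at 20..1000 m from the river — with all randomness
derived from one master seed (one substream per plot, so any plot
regenerates independently and byte-identically).

* **Positions.** Upper: CSR with 113 trees/plot, except the 1000-m plot,
  which is mildly clustered (Thomas, σ = 4 m, μ = 10). Middle: CSR at 20
  and 200 m (95 trees), Thomas (σ = 2 m, μ = 25) beyond. Lower: Thomas
  everywhere (66 trees). Study plots use a count-conditioned Thomas
  variant (parents Poisson on a 4σ-padded window; each of exactly n
  offspring picks a parent and redraws its Gaussian offset until inside),
  so per-plot densities are design conditions rather than Poisson noise —
  the unconditional Thomas process, with its closed-form
  g(r) = 1 + exp(−r²/(4σ²))/(4πσ²κ), is kept separate for oracle tests.
  Unconditional cluster counts have CV ≈ 0.3 at these parameters, which
  would make the transect density ordering a coin flip across seeds.
* **Marks.** Grades are apportioned by largest-remainder quota from the
  per-transect mixes (29/43/23/5, 18/45/26/11, 14/48/29/9 percent) and
  shuffled over positions: the grade shares are treated as conditions of
  the emulated study, not as sampling noise (i.i.d. draws would flip the
  lower transect across the 15% trend threshold in roughly a third of
  seeds). DBH within a grade follows a linear "tilted" density on the
  grade interval — uniform in the middle and lower transects; decreasing
  tilts (1.0, 0.5, 1.0, 1.0) in the upper transect so its pooled
  histogram takes the reversed-J shape of a regenerating stand (with
  uniform draws the upper histogram is a plateau-plus-bump that the
  Gaussian fits better, contradicting the stand's growing structure).
  Old-tree DBH is capped at 100 cm. TH = 1.49·DBH^0.6 and
  CD = 0.9·DBH^0.5 with multiplicative lognormal noise (σ_log = 0.15)
  give ~10 m tall, ~4.5-m-crowned trees at DBH 25 cm.
* **Abiotic gradients.** Groundwater depth (offsets 8/6/4 m by transect,
  slope −0.002 m per m of DR) and soil moisture (22/16/10, −0.005)
  decrease downstream and away from the river; conductance (0.8/1.6/2.4,
  +0.0008) increases; pH is flat at 8.1. Gaussian noise has sd = 10% of
  each covariate's range — large enough that correlations are estimated,
  small enough that the built-in signs (ANN positive with GD and SM,
  negative with SC) are recoverable in ≥ 90% of seeds.

**What the generator does not emulate:** measurement error in stem
coordinates and biometrics, mortality (no dead-tree marks), inter-plot
spatial autocorrelation, non-circular crowns, and inhomogeneous intensity
within a plot (gradients exist only between plots). Tests passing on this
study therefore validate the estimators and the pipeline logic, not the
ecological claims one could draw from real stem maps.

## Problem sizes and numerical choices

The test suite exercises the estimators at the sizes a single desk run
supports: CSR calibration over 200 draws of n = 500; Thomas closed-form
recovery over 200 draws (pooled over replicates — summed pair counts
normalised by the squared pooled mean count — because per-pattern ratio
estimates condition on a count whose CV ≈ 0.3 here, biasing their plain
average ~10% low near r = 10); envelope calibration over 500 outer
replicates of n = 100 with 199 simulations each; Monte-Carlo CPA checks
with 2×10⁵ sample points per plot. The full 18-plot pipeline at 199
simulations per envelope and per null runs in well under a minute on one
CPU.

Degenerate inputs are errors, not warnings: fewer than 2 points for
distance statistics, zero-mean quadrat counts for DMI, zero variance for
Pearson, envelopes with fewer than 19 simulations, quadrat sides that do
not tile the window, inhibition packings that cannot be completed (the
error reports the achieved count). Trees exactly on the window boundary
are accepted (closed window); edge correction handles the boundary bias.

## Known limitations

* The isotropic correction assumes the rectangle; irregular windows are
  out of scope.
* K and g are homogeneous-process estimators; applying them to a plot
  with a strong internal density gradient conflates inhomogeneity with
  clustering (the classic confound, deliberately not addressed here).
* Per-pattern g estimates for strongly clustered, low-count patterns are
  noisy and conditionally biased (see above); plot-level labels remain
  reliable because the envelope is constructed under the same
  conditioning.
* The HSI standardised score is heavy-tailed under clustering; its rank p,
  not its magnitude, should be interpreted.
* CPA treats crowns as opaque discs; real canopies overlap in depth and
  the printed cover of a dense stand will differ from a photogrammetric
  estimate.
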