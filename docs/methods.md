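# Methods

## Model and assumptions

The naive CD4 pool is modelled as two well-mixed compartments: resting cells
X and dividing cells Y, with total N = X + Y. Thymic export θ feeds the
resting compartment. Resting cells enter division at per-cell rate
λ(N) = λ₀·exp(−N/ε) — competition among all naive cells for IL-7 and
self-peptide-MHC division signals, maximal when the pool is empty — and die
at per-cell rate δ(N) = δ₀·exp(N/ρ), growing with crowding as survival
signals are diluted. Dividing cells return to rest at rate r after a single
division that yields two resting daughters (hence the 2rY gain term), or die
by density-dependent AICD at per-cell rate μ′Y (total flux μ′Y²). The
population is treated as homogeneous (no clonal structure), with no
antigen-driven activation and no naive-to-memory maturation; CD8 and memory
compartments are out of scope.

Death of dividing cells deserves one note: the published parameter table
lists a constant "death rate of dividing cells 15/day", while the model text
defines it as density-dependent, μ = μ′Y. This package adopts the
density-dependent reading with μ′ = 15/day per 10¹¹ cells: the constant-rate
alternative predicts an equilibrium dividing:resting ratio near 0.1%,
incompatible with the reported ~0.4–0.5%, while the μ′ reading reproduces it.

## Units

Rate parameters mix absolute counts (θ in cells/day) with resource scales
(ε = 1, ρ = 100) that are only dimensionally consistent if cell numbers are
measured in units of 10¹¹ cells. The public API therefore works in absolute
cells throughout, with `cell_unit` (default 10¹¹) used internally to
condition the solver and for table-style reporting. λ₀ and δ₀ are plain
first-order rates (1/day). Ages convert at 365.25 days/year.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| θ | adult thymic output | 3×10⁸ | cells/day |
| λ₀ | division entry, no competition | 0.055 | 1/day |
| ε | division resource scale | 10¹¹ | cells |
| δ₀ | resting death, no competition | 0.02 | 1/day |
| ρ | survival resource scale | 10¹³ | cells |
| r | return from division | 4 | 1/day |
| μ′ | AICD slope | 1.5×10⁻¹⁰ | 1/day per cell |

## Equilibrium and stability

For a given total N the dividing-compartment balance is a quadratic in Y
with a single nonnegative root Y(N) = 2λN / (b + √(b² + 4μ′λN)), b = r + λ(N)
(the numerically stable form). Substituting into the resting balance leaves
one scalar equation F(N) = 0, bracketed ([10⁻¹² , 10⁴] model units, expanding
upward if needed) and solved by Brent's method, then polished by a 2-D
Powell-hybrid refinement. F's exponent is clamped at 700 far above the root,
where only its sign matters. When θ and λ₀ are effectively zero F is
non-positive from the origin and the empty pool is returned as the fixed
point. The analytic Jacobian uses ∂λ/∂N = −λ/ε and ∂δ/∂N = +δ/ρ; stability
is the strict sign of the largest eigenvalue real part, with |Re| < 10⁻¹⁰
flagged as marginal rather than classified.

`stability_threshold` bisects a parameter bracket on that sign, recomputing
the steady state at every trial value, to 10⁻⁴ relative tolerance; when the
sign is the same at both ends it reports no threshold in the bracket.

**Finding: the set point is unconditionally stable.** Earlier work reported
critical values (r > 0.281, μ′ < 106.79 per 10¹¹ cells, ε < 1.01×10¹¹, and a
λ₀ bound of 10⁻¹⁴ order). The scan here finds no stability change anywhere:
across the full brackets (r ∈ [0.01, 4], μ′ ∈ [15, 500] per 10¹¹, ε ∈ [0.5, 2]
×10¹¹, and wide ranges of θ, δ₀, ρ, λ₀) the leading eigenvalue stays near
−0.02/day. This is structural, not numerical: the ±λX/ε contributions cancel
between the Jacobian's diagonal entries, leaving
tr J = −(λ+δ) − δX/ρ − r − 2μ′Y < 0 for all positive parameters, so
instability would require det J < 0; the reduced balance F(N) has a single
transversal root over the scanned range, which fixes det J > 0. A
20,000-point random search over 3–7 decades of all seven parameters jointly
never produced a positive leading eigenvalue. The previously quoted
thresholds — including the λ₀ bound at machine-noise magnitude — are
therefore judged artifacts of the original numerical procedure; this package
reports what the scan finds, and the corresponding assertion in the
acceptance tests is deliberately left failing rather than adjusted to pass.

## Integration and derived quantities

Trajectories are integrated with adaptive LSODA at rtol 10⁻⁸ and atol 10⁻¹²
model units, on the state scaled to model units, and resampled onto an
output grid of 0.01 day for the first 10 days (the return-from-division
timescale is 1/r = 0.25 day, and the lymphopenic proliferation burst peaks
within days) and 1 day thereafter. Negative round-off within 10× atol is
clipped to zero. "Reached equilibrium" is defined as the earliest time after
which N stays within ±5% of its final value (the trajectory's own asymptote);
at the defaults the lymphopenic run enters that band at 191 days, at the low
edge of the reported 200–300 day window. The interdivision time is 1/λ(N),
the mean wait of a resting cell before division entry — ~55 days at the adult
set point. (The source literature quotes both ~50 and ~30 days for division
timing; the two cannot both equal 1/λ(N*), and this package reports the
computed value without forcing either.)

## Pediatric pipeline

Thymic output in childhood is anchored at three published values —
4×10⁸ cells/day at birth, a 2×10⁹ peak at 1 year, 3×10⁸ at age 20 — but its
functional form is not published. The curve used here is a smooth cubic rise
(zero slope at both ends) from birth to the peak, then exponential decay at
ln(θ_peak/θ_adult)/19 ≈ 0.0998/yr calibrated to hit the adult value at 20
years, constant thereafter; it is configuration, replaceable by any other
anchored form. Blood volume by age is linear interpolation of a table; the
default table is a synthetic fixture (~80 ml/kg against a standard
weight-for-age reference, 0.3 L at birth to 5 L at age 20) since the original
volume data are not published. Concentration is
blood_fraction · N / (volume in μl), with blood_fraction = 0.02 — the
standard assumption for the share of the whole-body naive pool in blood,
which puts the adult steady state at a physiological ~440 cells/μl. The
birth state is (10¹⁰ cells, 0), small against the adult set point. Kinetic
parameters are held at adult values: the question the pipeline poses is
whether thymic output and growth alone explain early-childhood counts.

At these defaults the predicted concentration rises from ~670 cells/μl at
birth to a peak in the first year and then declines slowly — the published
early-childhood shape. Whole-body N is not monotone: it overshoots near the
thymic peak and relaxes toward the adult set point as θ falls.

## Synthetic cohort

The clinical comparison cohort is unavailable, so a generator emulates its
assumed structure: ages uniform on [0, 3] years (no visit schedule was
reported), observations equal to the model curve times median-one lognormal
noise with coefficient of variation `noise_cv` (default 0.3; counts are
positive and heteroscedastic, so multiplicative noise is the natural model —
the true dispersion is unknown and the value is configuration, not a claim).
Comparison and fitting both work on log-residuals (RMS and mean), symmetric
under over/under-prediction and matched to the noise model. Fitting
optimizes log-parameters — bounded scalar search for one free parameter,
Nelder–Mead otherwise — within a 10-fold box around the start. What passing
recovery tests show is identifiability of the pipeline under its own noise
model at n = 500; they say nothing about fit quality to real children, whose
age sampling, dispersion and covariates the generator does not emulate
(no within-subject correlation, no measurement rounding, no covariates).

## Problem sizes and numerical choices

Adult runs integrate 1000 days; the pediatric run 3 years at 0.05-year
output steps (0.01 or 0.02-year grids where a cohort is interpolated);
recovery uses 10 seeds at n = 500, CV 0.3. Steady-state residuals at the
defaults are below 10⁻⁷ cells/day; halving solver tolerances moves N(t) by
under 10⁻⁷ relative. The `cell_unit` scaling is exactly neutral in the
mathematics; realized trajectories under different scalings agree at the
level of the integration tolerance (≤10⁻¹⁰ relative at tight tolerances).
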