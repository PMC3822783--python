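# tcellhom

A mechanistic two-compartment model of naive CD4 T cell homeostasis, for
immunologists and modellers studying how thymic export, IL-7/self-peptide-MHC
competition and cell death set the size of the naive T cell pool — in adults,
where the pool sits at a stable set point of ~10¹¹ cells, and in young
children, where thymic output and blood volume are both changing rapidly.

## The model

Resting naive CD4 cells *X* and dividing cells *Y* obey

    dX/dt = θ + 2rY − λ(N)X − δ(N)X
    dY/dt = λ(N)X − rY − μ′Y²

with total pool N = X + Y, thymic export θ (cells/day), division entry
λ(N) = λ₀·exp(−N/ε) (competition for division signals), resting death
δ(N) = δ₀·exp(N/ρ) (competition for survival signals), return to rest at
r = 4/day (one ~6 h division producing two resting daughters), and
density-dependent death of dividing cells at per-cell rate μ′Y
(Fas/FasL-mediated AICD). Adult defaults: θ = 3×10⁸ cells/day, λ₀ = 0.055/day,
ε = 10¹¹ cells, δ₀ = 0.02/day, ρ = 10¹³ cells, μ′ = 15/day per 10¹¹ cells.

The package computes the nontrivial steady state by a scalar reduction in N,
classifies its linear stability from the analytic Jacobian, searches for
critical parameter values by bisection, integrates trajectories (adaptive
LSODA), and runs a pediatric pipeline in which θ varies with age (peak
2×10⁹ cells/day at 1 year) and whole-body totals are converted to blood
concentrations (cells/μl) through an age-dependent blood volume. A synthetic
cross-sectional cohort generator (lognormal multiplicative noise) stands in
for clinical data, with comparison and parameter-fitting utilities.

## Worked example

```sh
python analysis/01_adult_homeostasis.py
```

prints

```
equilibrium total N* = 1.108e+11 cells, dividing:resting = 0.446%
leading eigenvalue -0.0222/day (stable: True)
interdivision time at the set point: 55.1 days
lymphopenic: N(1000 d) = 1.108e+11 cells, in ±5% band from 191 d, peak Y/X = 0.0129
excess: N(1000 d) = 1.108e+11 cells, in ±5% band from 117 d, peak Y/X = 0.0045
```

Starting from 100-fold below or 2-fold above the replete pool, both runs
converge to the same set point just above 10¹¹ cells within a few hundred
days. During recovery from lymphopenia the dividing fraction bursts to ~1.3%
of the resting pool before settling near 0.45%, and a resting cell waits
~55 days on average between divisions at the set point. The remaining
drivers scan stability (`02`), sweep the resource scales (`03` — halving ε
shrinks the pool by 43%, halving ρ by only 1%), predict pediatric
concentrations (`04` — rise to a peak in the first year, then slow decline),
and round-trip the synthetic cohort (`05` — λ₀ recovered to ~3% median error
across seeds). The same stages are available as a CLI:
`tcellhom adult|stability|child|cohort --config cfg.yaml --outdir results`.

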