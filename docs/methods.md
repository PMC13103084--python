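# Methods

## Atmospheric forcing

All pool models are driven by an annual atmospheric Δ¹⁴C series evaluated
by linear interpolation, constant before the first grid year. The packaged
parametric bomb curve has four segments controlled by `BombCurveParams`:

| parameter | default | meaning |
|---|---|---|
| `baseline` | 0 ‰ | pre-bomb level (Suess-effect depression ignored) |
| `rise_start` | 1955 | year Δ¹⁴C departs from the baseline |
| `peak_year` | 1964 | bomb peak |
| `peak_amp` | 700 ‰ | peak height above baseline |
| `decay_efold` | 16 y | e-folding time of the post-peak relaxation |
| `end_level`, `end_year` | 0 ‰ at 2020 | value the tail passes through |

The rise is linear; the tail is exponential with its asymptote solved from
the constraint curve(`end_year`) = `end_level`. Pinning the tail to a
recent-year value rather than decaying to the baseline reproduces the real
record's return to ≈0‰ around 2020 (ocean/biosphere uptake plus
fossil-fuel dilution push the atmosphere below a pure first-order decay
toward the pre-bomb level); the default curve gives +2.9‰ at 2018. The
curve is a single global series: no hemisphere or zone distinction is
attempted, since which zonal compilation applies to a given site is a
dataset-level decision — `load_curve` accepts any published record as a
`year,delta14c_permil` CSV.

Ignoring the pre-1950 Suess depression biases millennial ages slightly
young, well inside the cohort standard errors; the bias cancels entirely
in the background-corrected mixing calculations.

## Radiocarbon conventions

Δ¹⁴C_sample = (F¹⁴C·e^{λ(1950−t)} − 1)·1000 with λ = 1/8267 yr⁻¹; reported
site values are background-corrected, Δ¹⁴C = Δ¹⁴C_sample − Δ¹⁴C_atm(t).
Year arithmetic is continuous (fractional sampling dates are accepted).
The fitters take background-corrected observations and apply the same
correction to the model, so the convention is internally consistent
whichever forcing curve is used.

The TC/SOC/SIC δ¹³C mass balance does not close exactly in practice
because total C (dry combustion) and SIC (ignition) are measured by
different methods; misclosure up to 10% relative is accepted silently-ish
(a warning), a hard error is raised above 25%.

## Pool models

State variable: Z(t), the pool's ¹⁴C/C ratio relative to the
decay-corrected 1950 standard (Z = Δ¹⁴C_sample/1000 + 1). One pool at
steady state obeys dZ/dt = k(A(t) − Z) − λZ. Integration uses the exact
exponential (integrating-factor) update on annual steps with the forcing
averaged over each step:

    Z(t+Δt) = Z∞ + (Z − Z∞)·e^{−(k+λ)Δt},   Z∞ = k·Ā/(k+λ).

This update is exact for constant forcing — so the spin-up identity
Z(1900) = k·A₀/(k+λ) holds to machine precision — and unconditionally
stable, which matters because the fit grid spans k from 10⁻⁵ to 10 yr⁻¹
(an explicit Euler scheme would need sub-stepping above k ≈ 0.1 yr⁻¹).
Simulations start in 1900 from the analytic pre-bomb steady state; with a
0‰ baseline the 55 bomb-free years before 1955 make the start year
immaterial.

The one-pool fitter scans 2000 log-spaced rates, brackets every sign
change of (model − observation), and polishes each root by bisection in
log k to |residual| < 0.1‰ (below AMS measurement precision). Positive
background-corrected observations can be explained by two rates — a fast
pool still carrying bomb carbon or a slower pool that accumulated it — and
the fitter then returns the smaller k (longer transit time), keeping every
root in `all_ages` for audit. For a single well-mixed pool, mean age,
transit time and turnover time coincide at 1/k.

Two-pool structures (`parallel`: independent pools with input split γ /
1−γ; `series`: input through the fast pool, fraction a21 of its outflux
transferred onward) share the forcing; bulk Δ¹⁴C is stock-weighted,
respired Δ¹⁴C flux-weighted. Derived quantities per unit input: mean
transit time γ/k_f + (1−γ)/k_s (parallel) or 1/k_f + a21/k_s (series) —
equal to the total steady-state stock, an identity used as a conservation
check — and mean system age as the stock-weighted mean of pool ages
(1/k_i in parallel; 1/k_f and 1/k_f + 1/k_s in series).

Two observations cannot identify three parameters, so `fit_two_pool`
profiles k_fast over a log grid of fast-pool ages (default 1–200 y, 15
points), solves (k_slow, partition) by bounded least squares at each grid
point, and keeps every solution reproducing both observations within 1‰
as the reported family; the point estimate is the family member with the
shortest mean transit time (the most conservative claim about old-carbon
persistence). Degenerate parameters (γ ∈ {0,1}, a21 = 0) delegate to the
one-pool simulator so reductions are bitwise exact.

## Carbonate partition and screening

Equilibrium carbonate-CO₂ endmember: δ¹³C_SIC − 9.6‰ (calcite–CO₂
fractionation at the 20 °C incubation temperature; the temperature
dependence is out of scope). f_SIC comes from the δ¹³C two-endmember
balance, requiring endmember separation ≥ 2‰ (configurable) for
identifiability; estimates outside [0,1] are clamped and flagged rather
than rejected, since measurement noise routinely produces slightly
negative estimates at carbonate-poor sites. Screening: SIC content
< 0.1 mass-% ⇒ `assumed_zero_sic`; f_SIC > 0.15 ⇒ `excluded_high_fsic`;
region on the configured exclusion list ⇒ `excluded_region` (a
dataset-specific judgement, deliberately not hard-coded); otherwise
`included_original` — included sites keep their measured respired Δ¹⁴C,
the f_SIC-adjusted value being reported only for audit. The Δ¹⁴C carbonate
endmember defaults to −1000‰ (parent-material carbonate) and is overridden
by a site's measured SIC Δ¹⁴C when available.

## Mixing assumptions

The young endmember defaults to the atmospheric Δ¹⁴C of the sampling year
(consistent with the background-correction convention); a flag switches to
a fixed 0‰ for sensitivity runs. Recently fixed plant carbon in fact
carries slightly higher Δ¹⁴C than the contemporary atmosphere, so f_old is
a mild underestimate under either choice; this bias is acknowledged, not
modelled. Fractions are clamped to [0,1] with flags so cohort summaries
stay computable. Cohort summaries report both averaging orders — the mean
of site-level fractions and the fraction implied by cohort-mean Δ¹⁴C —
because they differ (ratio of means vs mean of ratios) and cohort-level
reporting conventions vary.

## Breakpoint detection

The broken-line model shares an intercept across segments (continuity at
ψ); ψ is profiled over all midpoints between sorted unique predictor
values inside an edge margin of 5% of the range, each candidate requiring
≥5 observations per side. OLS at each candidate is solved by batched 3×3
normal equations (the design is tiny and well-scaled; a `lstsq` fallback
guards singular candidates). AIC = n·ln(RSS/n) + 2p with p = 4 for the
broken line (counting ψ) and p = 2 for the linear reference; ties prefer
the simpler model. The ψ interval is a seeded nonparametric bootstrap
(default 499 resamples, percentile 95%); resamples where a candidate
loses per-side support fall back to the point estimate. The grid-profile
approach is deterministic and globally optimal on the candidate grid, at
the cost of resolving ψ only to the local data spacing — immaterial next
to sampling noise. At realistic noise (σ ≈ 25‰ against a slope change of
≈300‰ per aridity unit near the range edge) the estimator is essentially
unbiased (median ψ̂ within 0.01 of truth) while individual replicates
scatter with median absolute error ≈ 0.04 — a statistical floor shared by
any estimator at that signal-to-noise, not an implementation limit.

## Synthetic cohort

The generator emulates a 97-site global dryland survey: aridity uniform on
(0.46, 0.99); sampling years 2015–2020; covariates (MAT, MAP, NPP, plant
cover, richness, SOC, pH, texture, Fe+Al, respiration rate) drawn with
signs and ranges typical of dryland gradients — decreasing water, carbon
and productivity with aridity. Hidden truth per site: a bulk (slow) pool
age from ln(age) = 5.25 + 3.0·aridity + 3.5·(aridity − 0.87)₊ + ε,
ε ~ N(0, 0.35²), clipped to 40–6500 y, and a respired-substrate transit
time ln(tt) = −1.6 + ln(age) + ε′, ε′ ~ N(0, 0.35²), capped at the bulk
age. These coefficients were calibrated once so the generated cohort
reproduces the survey's published statistics — mean bulk Δ¹⁴C ≈ −190‰
(range ≈ −440 to −30‰), screened-cohort respired Δ¹⁴C ≈ −39‰, mean bulk
age ≈ 2100 y — and then frozen. About 46% of sites are carbonate-free
(SIC < 0.1%); carbonate sites draw a true f_SIC from Beta(0.7, 9) (mean
≈ 0.07, a tail past the 0.15 exclusion threshold), and 41 of 97 sites
carry POC/MAOC fractions.

Observables are forward-simulated through the same physics the pipeline
inverts — pool models under the packaged curve, δ¹³C mixing with the 9.6‰
offset, the −1000‰ carbonate Δ¹⁴C endmember — plus Gaussian noise (3‰ on
Δ¹⁴C, 0.3‰ on δ¹³C, AMS/IRMS-scale defaults). What the generator does
*not* emulate: spatial or temporal autocorrelation, multi-depth profiles,
non-steady-state stocks, C4-plant δ¹³C heterogeneity in SOC-derived CO₂,
and zonal differences in atmospheric forcing. Passing recovery tests
therefore demonstrate the *inferential machinery* is correct and
well-calibrated under the model's own assumptions, not that those
assumptions hold in any particular field dataset.

## Numerical and test-size choices

Fit tolerances: 0.1‰ (one-pool), 1‰ (two-pool) — both below measurement
precision; noiseless round-trip tests tighten the one-pool tolerance to
10⁻³‰ to isolate solver error from model error. The pipeline's per-site
fits use the default 2000-point grid (ages 0.1 y to 10⁵ y). Monte-Carlo
test sizes — 50 sites for one-pool parameter recovery, 200 replicates for
breakpoint recovery, 100 replicates at 199 bootstrap resamples for
CI-coverage — were chosen to keep each property's Monte-Carlo error well
below its assertion margin while the full suite runs in well under a
minute of compute per heavy test.

## Known limitations

- Steady-state assumption throughout: recently disturbed or accumulating
  soils violate it and bias ages in the direction of the disturbance.
- Bulk SOC treated as one (or two) well-mixed pools; true age
  distributions are continuous, and the reported means understate their
  spread. Full age/transit-time distributions are out of scope.
- The parametric bomb curve approximates the published atmospheric
  compilations to a few per mil in the tail; fits of very fast pools
  (< 20 y) are correspondingly more curve-sensitive than millennial ages,
  whose Δ¹⁴C is dominated by radioactive decay rather than the bomb
  transient. Substitute a published record via `load_curve` when absolute
  decadal turnover rates matter.
- Single breakpoint per relationship; multiple simultaneous thresholds are
  not modelled.
- Mixed-effects, random-forest and cross-validation analyses of the
  per-site table are deliberately left to stock statistical libraries
  operating on the pipeline's CSV output.
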