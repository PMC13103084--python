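# arid14c

Radiocarbon constraints on the persistence and turnover of soil organic
carbon (SOC) in drylands.

Drylands store a large share of global soil carbon, yet how long that
carbon persists — and how old the carbon leaving the soil as respired CO₂
is — has been poorly constrained. Paired Δ¹⁴C measurements of bulk SOC and
of CO₂ respired during laboratory incubations answer both questions at
once: the natural decay of ¹⁴C dates carbon fixed centuries to millennia
ago, while the pulse of "bomb" ¹⁴C injected by 1950s–60s atmospheric
weapons testing traces carbon cycling on annual-to-decadal timescales.
`arid14c` packages the full analysis chain for such data, for soil
biogeochemists working with site-level isotope surveys.

## What it computes

**Isotope corrections.** Fraction modern is converted to Δ¹⁴C with the
decay constant λ_C = 1/8267 yr⁻¹,

    Δ¹⁴C_sample = (F¹⁴C · e^{λ_C (1950 − t)} − 1) · 1000 ‰,

and background-corrected by the atmosphere of the sampling year,
Δ¹⁴C = Δ¹⁴C_sample − Δ¹⁴C_atm(t), so sites sampled in different years are
comparable. The δ¹³C of soil inorganic carbon (SIC) follows from the mass
balance δ¹³C_TC·w_TC = δ¹³C_SOC·w_SOC + δ¹³C_SIC·w_SIC, and incubation CO₂
slopes convert to respiration rates via the ideal gas law.

**Carbonate screening.** In carbonate-bearing soils, rewetting can release
CO₂ from carbonate dissolution. The SIC share of respired CO₂,

    f_SIC = (δ¹³C_CO₂ − δ¹³C_SOC) / (δ¹³C_SIC_eq − δ¹³C_SOC),
    δ¹³C_SIC_eq = δ¹³C_SIC − 9.6 ‰  (calcite–CO₂ equilibrium at 20 °C),

drives the site screening: SIC < 0.1% ⇒ all respired CO₂ treated as
SOC-derived; f_SIC > 15% ⇒ site excluded from respiration analyses;
otherwise the original respired Δ¹⁴C is used.

**Old-carbon share of respiration.** A two-endmember Δ¹⁴C mixing model,

    Δ¹⁴C_CO₂ = Δ¹⁴C_old·f_old + Δ¹⁴C_young·f_young,   f_old + f_young = 1,

with the young endmember at the sampling year's atmospheric Δ¹⁴C and the
old endmember set to the bulk-SOC value (high-end estimate), ¹⁴C-dead
petrogenic carbon at −1000‰ (low-end), or a mineral-associated-carbon
(MAOC) value inferred from bulk Δ¹⁴C assuming modern particulate organic
carbon.

**Mean age and transit time.** One-pool steady-state models forced by the
atmospheric bomb curve, dZ/dt = k(A(t) − Z) − λZ, run from 1900 and
inverted for k; for a single well-mixed pool, mean age = transit time =
turnover time = 1/k. Bomb-ambiguous observations (two rates fitting one
value) resolve to the longer transit time, with both roots retained.
Two-pool parallel and series structures fit paired bulk/respired values,
profiling the underdetermined fast rate and reporting pool stocks, flux
partitions, mean system age and mean transit time.

**Thresholds.** Continuous broken-line regression
y = β₀ + β₁x + β₂(x − ψ)₊ with the breakpoint ψ profiled over candidate
grid values, compared against a simple linear model by AIC, with a seeded
bootstrap interval for ψ — for detecting abrupt shifts of Δ¹⁴C along
aridity, productivity, or SOC gradients.

**Synthetic cohorts.** A generator reproducing the statistical structure of
a 97-site global dryland survey (aridity 0.46–0.99, bulk Δ¹⁴C ≈ −190‰,
respired Δ¹⁴C ≈ −39‰, ~46% carbonate-free sites, POC/MAOC data for a
subset), with a hidden-truth sidecar for parameter-recovery experiments.

## Worked example

```sh
arid14c simulate --seed 1 --out sites.csv        # 97 synthetic sites
arid14c run --sites sites.csv --out results/
arid14c fit-pool --delta14c -190 --year 2018
```

The last command inverts the one-pool model for a bulk Δ¹⁴C of −190‰
sampled in 2018 and prints

```json
{
  "k": 0.0005041982113183479,
  "age_years": 1983.3469805163702,
  "n_solutions": 1,
  "selection": "unique",
  "all_ages": [1983.3469805163702]
}
```

i.e. carbon this depleted implies a mean SOC age of roughly 2000 years.
`results/summary.json` from the pipeline run above reports, among other
quantities (mean ± standard error over the screened cohort):

| quantity | value |
|---|---|
| bulk Δ¹⁴C | −187.1 ± 10.4 ‰ (n = 97) |
| respired Δ¹⁴C | −42.0 ± 6.4 ‰ (n = 89 included) |
| bulk SOC mean age | 2132 ± 144 y |
| respired transit time | 619 ± 46 y |
| f_old (bulk-SOC endmember) | 0.24 |
| f_old (petrogenic endmember) | 0.05 |
| two-pool slow-pool mass fraction | 0.998 |

Respired CO₂ is consistently younger than bulk SOC (positive
respired-minus-bulk difference, here +147 ‰), yet still centuries old on
average — the signature of a small fast-cycling pool feeding most
respiration on top of a large, millennia-old stock. Per-site results,
including screening status and exclusion reasons, are written to
`results/per_site.csv`.

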