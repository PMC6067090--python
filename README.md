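# halleymort

Age trajectories of mortality decline in childhood, built from WHO-format
cause-of-death data and explained by a congenital-frailty hazard model.

In developed countries the all-cause mortality rate falls by three to four
orders of magnitude between the first day of life and its minimum around
ages 5–15 — far faster than it later rises in old age.  For congenital
anomalies of the central nervous system (CACNS, ICD-10 Q00–Q07) the decline
follows a strikingly simple law: on a log–log scale the age-specific rate
is linear with slope ≈ −1, i.e. an inverse proportion

  μ(x) = μ₁ / x.

`halleymort` implements the full analysis pipeline behind that observation:

- **who_io** — reads/writes the WHO Mortality Database ICD-10 flat-file
  dialect (26 age-group death columns plus the four infant columns
  [0,24) h, [1,7) d, [7,28) d, [28,365) d) and single-year population /
  live-birth tables; expands ICD-10 code ranges such as `Q00-Q07`.
- **halley_pool** — pools deaths Dᵢ and entering populations Lᵢ across
  countries and calendar years into one "large population" (the Halley
  method, so rare-cause old-age cells contain nonzero counts) and estimates
  the force of mortality per interval, μᵢ = Dᵢ/(Lᵢ·(Bᵢ−Aᵢ)) per 10⁷
  person-years.
- **loglog_models** — the nested model ladder on the log scale:
  quadratic `ln μ = c + γ ln x + δ (ln x)²` (curvature probe, Wald test of
  δ = 0), linear power law `ln μ = c + γ ln x` (95 % CI for γ, test of
  γ = −1), and the one-parameter inverse proportion with its closed-form
  scale `ln μ₁ = mean(ln μᵢ + ln xᵢ)` and goodness of fit
  R_b² = 1 − SS_resid/SS_total; nested F-tests, residual diagnostics, and
  the upper-age sensitivity sweep.
- **tcir_model** — the theory of congenital individual risk (TCIR): each
  individual carries a fixed risk r drawn from the reciprocal density
  f(r) ∝ 1/r on [r_min, r_max]; the population hazard is a
  Laplace-transform functional of r·f(r) and, while the cohort is nearly
  intact, reduces to the two-parameter "bent" curve
  μ(x) = μ₁ (1 − e^(−r_max·x))/x — a plateau below age ≈ 1/r_max bending
  into the inverse proportion.  Fitted by deterministic RSS minimization on
  the log scale.
- **cohort_sim** — a synthetic cohort generator under exactly those
  assumptions (log-uniform risks, exponential lifetimes, WHO-dialect
  tabulation, a large unaffected base population in the denominators),
  closing the loop with parameter-recovery experiments.
- **extremes** — per country-year extreme-age rates and the Ratio A
  (first-day / minimum) and Ratio B ([90,95) / minimum) analysis with
  normality checks and a paired comparison; the published 18-row
  country-year summary table is bundled.
- **cli_report** — a `halleymort` command line that drives the whole
  pipeline from a YAML config and writes reproducible tab-separated
  reports.

## Worked example

Simulate a bent-regime cohort (200 000 frail newborns with risks
log-uniform on [10⁻⁴, 2.9] per year, embedded in a 100× larger unaffected
population) and run the full pipeline:

```yaml
# sim.yaml
simulation:
  n: 200000
  r_min: 1.0e-4
  r_max: 2.9
  seed: 7
tcir_window: [0.0, 10.0]
upper_ages: [5, 10, 15]
out_dir: out
seed: 7
```

```sh
halleymort report -c sim.yaml
cat out/tcir_fit.tsv
```

```text
mu1	r_max	rss	r2	r2_adj	n
9934.35	2.75475	0.017447	0.998438	0.998215	9
```

The two-parameter bent curve recovers the generative upper risk limit
r_max = 2.9/yr to within 5 % (fitted 2.75/yr) with a log-scale R² of
0.998 over the nine age bins below age 10.  The accompanying
`recovery.tsv` reports the power-law slope fitted to the same data:

```text
gamma	gamma_ci_lo	gamma_ci_hi	ci_covers_minus1	rb2	tcir_mu1	tcir_r_max	true_r_max	r_max_rel_error	deaths_in_window
-0.35034	-0.500419	-0.200262	False	-1.98309	9934.35	2.75475	2.9	0.0500878	76889
```

With r_max ≈ 2.9/yr the plateau extends to ≈ 1/r_max ≈ 0.34 years, so the
trajectory is *not* an inverse proportion over [0,10): the straight-line
slope is only −0.35 and the one-parameter model fits badly (R_b² < 0) —
exactly the bent shape the TCIR predicts for disease categories with a
bounded congenital risk spectrum.  Raising r_max pushes the bend below the
first WHO age bin and the trajectory straightens toward slope −1.

On real inputs, point the config at the WHO mortality files and
single-year population tables instead of a `simulation` block
(`deaths`, `population`, `births` keys; `cause_set: "Q00-Q07"`), and the
same artifacts are produced for the pooled empirical trajectory.

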