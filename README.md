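# raygrowth

Age-and-growth inference for batoids (rays and skates) aged from vertebral
band pairs. The package covers the full analysis chain used in elasmobranch
life-history studies:

- **Reading precision** — average percentage error (APE), coefficient of
  variation (CV), percent agreement, and an age-bias table with
  per-reference-age one-sample t-tests.
- **Band-deposition periodicity** — maximum-likelihood fits of no-cycle /
  annual / biannual hypotheses to monthly opaque-edge frequencies (peak-
  normalized von Mises links), compared by AIC and Akaike weights.
- **Back-calculation** — OLS disc-width-on-vertebral-radius regression,
  ANCOVA-based sex pooling, and size-at-age under the body-proportional
  hypothesis, DW_t = DW_c·(a + b·VR_t)/(a + b·VR_c).
- **Growth modelling** — two- and three-parameter von Bertalanffy, Gompertz
  and logistic curves fitted per sex in a Bayesian framework (truncated
  weakly informative priors, ensemble MCMC, R-hat/ESS diagnostics), ranked
  by AIC with WAIC alongside, and sex contrasts from the posterior of
  θ_F − θ_M at a 90% credible level.
- **Life history** — Ricker theoretical longevity (age at 95% DW∞,
  5·ln2/k) and cross-species comparative statistics over a packaged
  compilation of published dasyatid growth parameters.
- **Synthetic populations** — a generator with known growth, band and
  reading truth (dimorphic logistic growth, seasonal edge deposition,
  ±1-year reading error, gillnet-like size selectivity), used throughout
  the test suite to validate each stage against its generative truth.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import raygrowth as rg

# a synthetic population with known logistic truth, plus a second reading
ds = rg.simulate_double_reads(
    rg.simulate_population(rg.SimulationConfig(n_fish=272, seed=1)))

print(rg.precision_report(ds.data[["read1", "read2"]]).to_dict())

# band periodicity
comp = rg.select_edge_model(rg.aggregate_edges(ds.data))
print(comp.best, comp.table[["hypothesis", "aic", "weight"]].round(2).head(1))

# regression -> back-calculation -> growth fit
fit = rg.fit_dw_vr(ds.data)
pairs = rg.back_calculate_all(ds.data.assign(age=ds.data["read1"]), fit)
t, dw = rg.build_growth_input(pairs, "M")
fr = rg.fit_growth_bayes(t, dw, "logistic", seed=1, sex="M")
print({p: round(fr.posterior.mean(p), 2) for p in ("dw_inf", "k", "t0")})
print("longevity:", round(rg.ricker_longevity(fr.posterior.mean("k")), 1), "y")
```

prints (seed 1):

```
{'ape_percent': 1.04, 'cv_percent': 1.47, 'pct_agree_exact': 90.81,
 'pct_agree_within_1': 100.0, 'n_fish': 272}
one_peak   hypothesis     aic  weight
         0   one_peak  196.77     0.8
{'dw_inf': 402.67, 'k': 0.44, 't0': -0.48}
longevity: 7.9 y
```

The precision numbers reflect the generator's 12.5% ±1-year reading-error
rate; the annual-cycle ("one_peak") hypothesis wins because edges were
deposited seasonally; and the male posterior means recover the generating
logistic parameters (DW∞ = 401.7 mm, k = 0.45 y⁻¹, t₀ = −0.36) within
posterior uncertainty, giving a theoretical longevity of 7.9 years against
the generating curve's 7.7.

A command-line interface mirrors the library
(`raygrowth simulate|precision|edges|backcalc|fit|compare|run`); `raygrowth
run` chains every stage and writes the report bundle with a seed-and-hash
manifest.

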