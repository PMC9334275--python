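# thermvar

Growth and cannibalism of damselfly larvae (*Enallagma cyathigerum*) under
fluctuating temperatures: a tested Python implementation of the thermal
performance curve (TPC) analysis, the Jensen's-inequality prediction, an
individual-based simulator of the rearing experiments, and the experiment
statistics.

Ectotherm performance is a nonlinear, left-skewed function of temperature.
The package models larval growth — the specific rate
`g = (ln HW_final − ln HW_initial)/days` from head widths in mm — with the
O'Neill (1972) curve

    rate(T) = R_max · ((CT_max − T)/(CT_max − T_opt))^x · exp(x (T − T_opt)/(CT_max − T_opt)),
    w = (Q10 − 1)(CT_max − T_opt),   x = (w²/400)(1 + √(1 + 40/w))²,

fits it by bounded multi-start nonlinear least squares, and evaluates the
Jensen's-inequality consequence: with the experimental bands (constant 23 °C
and fluctuations 22–24, 21–25, 20–26 °C sharing the 23 °C mean) lying on the
concave rising limb just below the ~27 °C optimum, time-averaged performance
under fluctuation falls slightly below performance at the constant mean.
Because no raw data ship with the package, an individual-based generator
simulates both experiments — singly reared larvae at five constant
temperatures (17–28 °C), and 10-larva containers with size-ratio-dependent
cannibalism, intrinsic mortality and weekly censuses — and the statistics
(one-way ANOVA, binomial GLM with deviance chi-square and Tjur's r², the
log/√-transformed size-variance regression) are run on the synthetic tables.
See `docs/methods.md` for the model and design details.

## Worked example

```python
import thermvar as tv

# the reference parameter set: Rmax 0.0681 day⁻¹, Topt 26.9, CTmax 44.7, Q10 2.56
obs = tv.simulate_single_growth(20, [17, 19, 22, 25, 28], tv.REFERENCE_TPC,
                                noise_sd=0.0, seed=1)
fit = tv.fit_oneill(obs, seed=1)
print(fit.params)

prof = tv.make_regime(tv.TREATMENT_REGIMES["high"])     # 20–26 °C, 2-week cycles
print(tv.regime_mean(prof), tv.jensen_gap(tv.REFERENCE_TPC, prof))
```

prints

```
TPCParams(rmax=0.06810000000000006, topt=26.89999999999999, ctmax=44.699999999999726, q10=2.5600000000000014)
23.0 -0.002633084951328253
```

— the noise-free generate-and-refit recovers all four generating parameters
to machine precision, the high-amplitude regime time-averages to exactly the
23 °C design mean, and the Jensen gap is negative: fluctuating 20–26 °C
costs about 0.0026 day⁻¹ (~5% of the rate at 23 °C), a small predicted
performance deficit.

The numbered drivers under `analysis/` run the full pipeline and write
tables to `results/`:

```sh
python analysis/01_fit_tpc.py            # generate-and-refit, with bootstrap CIs
python analysis/02_jensen_regimes.py     # four regimes, Jensen gaps, secant slopes
python analysis/03_simulate_interaction.py   # synthetic 4-treatment experiment
python analysis/04_interaction_stats.py  # GLM, ANOVAs, size-variance regression
python analysis/05_size_variance_mc.py   # 200-container size-variance Monte Carlo
```

For example, `03` reports `400 larvae started; 148 alive after eight weeks
(247 cannibalized, 5 intrinsic deaths)` and `05` finds mean per-container
cannibalism rising from 3.50 to 7.48 when initial size CV grows from 2% to
15% (slope 4.05, p ≈ 1e-64): more initial size spread, more cannibalism.
The same subcommands are available from a shell via the `thermvar` CLI
(`thermvar regime`, `thermvar simulate`, `thermvar fit-tpc`, …).

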