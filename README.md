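# rutsync

Stochastic-process analysis of reproductive synchrony in Serengeti
wildebeest (*Connochaetes taurinus mearnsi*), asking whether exposure to
male rutting vocalisations alone can account for the tight mating and
calving peaks observed in wild herds.

The analysis compares two experimental groups of five females each —
one exposed to continuous playback of recorded rutting calls, one
isolated from all male stimuli — followed for 26 weeks with their
ovarian cycles classified into pre- and post-ovulatory periods.  It is
aimed at quantitative ecologists and biostatisticians working on
phenology and birth-season timing.

## The model and statistics

**Time to ovulation.**  The pre-ovulatory period is a constant
follicular phase τ plus a memoryless waiting time with per-day hazard λ
(a homogeneous Poisson process), so its duration X follows a shifted
exponential law

    f(x; λ, τ) = λ e^{−λ(x−τ)},  x ≥ τ,

with mean τ + 1/λ and SD 1/λ.  Durations pooled within a treatment are
fitted with the classical minimum-variance-unbiased estimator pair for
this family: with m = min(x) and S = Σ(x − m), the scale estimate is
S/(n−1) (reported rate λ̂ = (n−1)/S) and the shift estimate
m − S/(n(n−1)).

**Synchrony.**  Synchrony of any time-to-event law is T80: the width of
its 80% highest density region, the shortest interval containing 80% of
the event-time mass.  For the shifted exponential,
T80 = ln(5)/λ in closed form; for general unimodal laws the package
minimises `quantile(u + 0.8) − quantile(u)` numerically.  A one-sided
permutation test (animal labels shuffled between groups, 50,000
permutations) tests the null of equal T80 against
T80(Control) > T80(Playback).

**Prediction.**  Assuming mating happens within a short periovulatory
window, time to mating equals time to ovulation, and calving time is
B = M + G with G a normal gestation of mean μ = 258 d and SD σ
predicted from a 41-species log2–log2 allometry of gestation SD on
gestation mean (primates and elephants excluded).  B then follows a
shifted ex-Gaussian with density

    f(b) = (λ/2) e^{λ(λσ²/2 + μ + τ − b)} erfc((λσ² + μ + τ − b)/(√2 σ)),

whose variance 1/λ² + σ² — and hence T80 — is free of the location
parameters.  Parametric bootstrap (simulate a dataset from the fitted
law, refit, recompute T80; 15,000 replicates per group) propagates
parameter uncertainty into predicted T80 mating and calving
distributions, which are compared with independent field windows
(mating 14–21 d; calving point estimates 19.56–28.99 d, outermost 95%
limits 15.67–31.70 d).

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data with the structure the analysis assumes (the generators
live in `rutsync.simulate`):

```sh
python analysis/01_simulate_experiment.py --seed 11
python analysis/02_fit_ovulation_models.py --seed 11
python analysis/03_permutation_test.py --seed 11
python analysis/04_predict_mating.py --seed 11
python analysis/05_predict_calving.py --seed 11
```

which prints (seed 11):

```
Control: n=16, rate=0.030/d (95% CI 0.019-0.052), shift=3.87 d, T80=54.11 d
Playback: n=34, rate=0.107/d (95% CI 0.077-0.155), shift=5.46 d, T80=15.11 d
T80 ratio Control/Playback: 3.58 (>1 means Playback is more synchronous)
D_obs = 39.00 d; one-sided p = 0.00404 (50000 permutations, unit=animal)
Control: median predicted T80 mating = 53.00 d; 0.09% of predictions inside 14-21 d
Playback: median predicted T80 mating = 15.00 d; 63.18% of predictions inside 14-21 d
gestation allometry: slope=0.906 on 37 species; predicted SD at 258 d mean: 5.84 d
Control: median predicted T80 calving = 61.75 d; 0.08% within 19.56-28.99 d, 0.23% within 15.67-31.7 d
Playback: median predicted T80 calving = 24.89 d; 85.23% within 19.56-28.99 d, 97.17% within 15.67-31.7 d
```

Reading this: females exposed to playback reach 80% ovulation in ~15 d
versus ~54 d for controls (a 3.6-fold synchrony difference the
permutation test calls significant), and only the playback-based
predictions are compatible with the field mating and calving windows.
`analysis/06_full_report.py` runs the same pipeline in one pass
(`rutsync.run_pipeline`) and writes `results/report.json` plus a text
summary; every stage seed and configuration constant is recorded in the
report with its provenance.

## Layout

- `src/rutsync/` — distributions, estimation, synchrony, inference,
  prediction, synthetic-data generators, CSV schemas, pipeline
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — unit, property and reproduction suites
- `docs/methods.md` — modelling assumptions, numerical choices and
  known limitations
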