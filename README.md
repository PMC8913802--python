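# koalasc

Bayesian density estimation for unmarked koala populations surveyed with
passive acoustic sensor arrays, plus the surrounding survey analyses:
BACIPS (Before–After-Control-Impact Paired Series) harvest-effect testing,
posterior density surfaces with forest-category overlays, and a synthetic
acoustic-survey generator.

The package is aimed at ecologists and biometricians analysing detector
arrays of nightly call counts — here, male koala bellows counted as the
number of 10-minute periods per night with at least one validated call —
where individuals cannot be identified and density must be inferred from
the spatial correlation of counts alone.

## The model

The core is the spatial count (SC) model, spatial capture–recapture for
unmarked populations, fitted by data augmentation: M hypothetical
individuals carry inclusion flags `z_i ~ Bern(ψ)` and latent activity
centres `s_i ~ Unif(S)`, where S is the detector envelope plus a buffer
(750 m default). Counts at detector j on night k follow

```
n_jk ~ Poisson(Λ_j),   Λ_j = λ0 Σ_i z_i exp(−d(s_i, x_j)² / 2σ²)
```

with λ0 the baseline encounter rate (expected nightly count at an
individual's activity centre) and σ the half-normal spatial decay scale,
linked to home-range area A by `σ = sqrt(A / (π·χ²₂(0.95)))`. Abundance is
`N = Σz`, density `D = N/|S|` in males ha⁻¹. Fitting is by
Metropolis-within-Gibbs (exact conditionals for z and ψ, log-scale
Metropolis for λ0 and σ, random-walk moves for activity centres) with
adaptive proposals, multiple seeded chains and Gelman–Rubin convergence
checks (R̂ < 1.1). Priors: λ0 ~ U(0, 100), ψ ~ Beta(1, 1), and σ either
uniform or gamma moment-matched to a home-range mean (e.g. 40 ha → mean
146 m) — see `docs/methods.md`.

## Worked example

```python
import koalasc as k

array = k.make_grid_array(5, 5, 400)            # 25 sensors, 400 m spacing
space = k.build_state_space(array, 750)         # 3100 m × 3100 m, 961 ha
pop = k.simulate_population(0.05, space, seed=1)      # true N = 48
counts = k.simulate_counts_model_exact(pop, array, 0.3, 150.0, 14, seed=2)

priors = k.make_priors("strong", homerange_mean=40.0)  # σ ≈ Gamma(mean 146 m)
draws = k.run_chains(counts, array, space, priors, k.MCMCConfig.desk(seed=11))
print(k.summarize(draws).round(4))
print(k.gelman_rubin(draws).round(3))
```

prints (posterior mean with 50% and 95% central intervals; R̂ per
parameter):

```
               mean       q25       q75     q2.5     q97.5
parameter
N           80.9641   55.0000  105.0000  29.0000  143.0000
D            0.0842    0.0572    0.1093   0.0302    0.1488
lambda0      0.2564    0.1715    0.3174   0.0955    0.5154
sigma      144.0878  126.5247  159.7228  98.7900  196.7330
psi          0.5392    0.3648    0.6992   0.1826    0.9537

N          1.010
D          1.010
lambda0    1.023
sigma      1.008
psi        1.010
```

The 95% interval for density (0.030–0.149 males ha⁻¹) comfortably covers
the generating 0.05, and all R̂ are below the 1.1 convergence threshold.
Note the posterior *mean* sits above truth: at ~0.2 expected counts per
detector-night the unmarked-count likelihood is weak and the flat ψ prior
pulls N upward — a model property at sparse data sizes, reproduced by an
independent JAGS implementation, and discussed in `docs/methods.md`.

The numbered drivers under `analysis/` run the full pipeline and write
their tables under `results/` (bulky draws go to `scratch/`):

```
python analysis/01_simulate_survey.py    # synthetic survey (both generators)
python analysis/02_fit_sc_model.py       # SC fit: summary, R̂
python analysis/03_density_surfaces.py   # 100 m raster + category table
python analysis/04_design_statistics.py  # harvest intensity, occupancy, BACIPS
python analysis/05_parameter_recovery.py # 10-replicate simulate-and-refit
```

There is also a thin CLI (`koalasc simulate|fit|surface|bacips|report`)
over the same functions.

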