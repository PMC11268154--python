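# fearcurve

How sharply does wildlife avoid people as disturbance intensity rises?
`fearcurve` is a Python library for answering that question from camera-trap
data.  It turns raw detection logs into **response curves** — the
probability of photographing a taxon on a camera-day as a function of the
number of humans recorded there the same day — fits competing decline
models to those curves by Bayesian MCMC, compares them with WAIC, and
quantifies resilience to short disturbance pulses with a negative-binomial
activity model.  A synthetic data generator emulating a multi-year,
multi-camera reserve network makes every stage testable end to end.

It is written for disturbance ecologists and quantitative conservation
scientists working with passive camera arrays.

## The models

Detection probability `y` at human count `x` is modelled by five families.
Two assume constant perceived risk per unit disturbance:

- exponential decay: `y = y0 · exp(−ς·x)`
- inverse polynomial (power law): `y = y0 / (1 + ς·x²)`

and two assume **discounting** — the behavioural-economics idea,
transplanted from time-to-reward to disturbance intensity, that animals
devalue each additional unit of risk as intensity grows:

- hyperbolic decay: `y = y0·ς / (ς + x)`
- harmonic (rational) decay: `y = y0 / (1 + ς·x)`

All of these nest inside the three-parameter **Arps decline equation**
from petroleum engineering,

```
y = y0 · (1 + d·ς·x)^(−1/d)
```

where `y0` is prevalence at zero disturbance, `ς` a taxon-specific
sensitivity, and `d` the discount exponent: `d → 0` recovers exponential
decay, `d = 1` the harmonic model, and `0 < d < 1` hyperbolic decline.
Fitting the Arps form therefore measures *how much* discounting the data
carry in a single parameter.

Curve fits use flat (uniform) priors and report posterior means with 95%
highest-density intervals; relative fit is judged by WAIC (deviance scale,
lower is better).  Pulse resilience is estimated per day offset `j` around
an event from per-camera counts `y_j ~ NegBinomial(π_j, r_j)` with
`π_j = r_j/(r_j + μ_j)` and activity `A_j = r_j(1−π_j)/π_j = μ_j`.

## Worked example

`python examples/fit_and_compare.py` simulates a response curve from the
combined-taxa Arps parameters (`y0=0.724, ς=5.00, d=0.784`; 2000
camera-days at each human count 0–15), fits all five forms, and prints:

```
      model        waic     p_waic  delta_waic  converged
       arps   99.205291   1.720229    0.000000       True
 hyperbolic  106.508312   1.897121    7.303021       True
   harmonic  106.614165   1.969691    7.408874       True
    invpoly  410.240623  43.798371  311.035332       True
exponential 2040.098453 356.890520 1940.893161       True

Arps posterior (truth: y0=0.724, sensitivity=5.00, discount=0.784):
           y0: 0.732  95% HDI [0.712, 0.750]
  sensitivity: 6.373  95% HDI [4.983, 7.968]
     discount: 0.864  95% HDI [0.776, 0.955]
```

The discounting family beats both non-discounting forms by hundreds of
WAIC units, the generating Arps form ranks first, and every 95% HDI covers
its generating value.  The other examples walk through log processing
(`response_curve_from_log.py`), curve shapes and the encounter-interval
arithmetic (`decay_model_shapes.py`), and pulse resilience
(`pulse_resilience_demo.py`).

A thin CLI mirrors the pipeline for shell use:

```
fearcurve simulate --config sim.yaml --out data/ --seed 1
fearcurve curves   --in data/events.csv --taxon coyote --out coyote.csv
fearcurve fit      --curve coyote.csv --model arps --seed 42 --out fit.json
fearcurve compare  --curve coyote.csv --models all --out table.csv
fearcurve pulse    --in data/events.csv --events data/pulse_dates.txt \
                   --cameras cams.txt --out pulse.json
```

## Layout

- `src/fearcurve/decay_models.py` — the five curve families and their limits
- `src/fearcurve/response_curves.py` — log deduplication, camera-days, curves
- `src/fearcurve/bayes_fit.py` — MCMC fitting, HDI, WAIC, model comparison
- `src/fearcurve/pulse_resilience.py` — negative-binomial activity model
- `src/fearcurve/synthetic_data.py` — the study-system generator
- `docs/methods.md` — modelling assumptions, priors, numerical choices
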