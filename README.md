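# preyspace

Space use of a wild prey population under spatially and temporally varying
predation risk — a reusable, tested implementation of the full analysis
chain used in before–after–control–impact (BACI) telemetry studies of
hunted game birds, validated end to end against synthetic data with known
ground truth.

## Who this is for

Movement and behavioral ecologists analyzing VHF-telemetry studies where
predation (or hunting) risk varies between sites and across a season, and
who need the entire chain in one place:

1. **Triangulation** — maximum-likelihood location estimates from azimuth
   bearing sets under a von Mises bearing-error model (Lenth-style Fisher
   scoring), with 95% error ellipses and the field-standard quality gates
   (fixes discarded above 2000 m² for daytime, 1000 m² for roost
   locations).
2. **Risk metric** — hunting pressure as mean hunters per camera photo,
   per site, per day, with a pre (1–25 Oct) / early (27 Oct–23 Nov) /
   late (24 Nov–15 Dec) season calendar.
3. **Home ranges** — fixed-kernel utilization distributions with the
   reference bandwidth h_ref = ½(sd_x + sd_y)·n^(−1/6); 95% and 50%
   isopleth areas and core centers, per individual × season (≥10 fixes)
   and as sliding 11-relocation moving windows advanced one fix at a time.
4. **Inference** — Gaussian linear mixed models (site and individual
   random intercepts) with flat-prior posterior simulation: 5000 draws of
   the fixed effects, 95% credible intervals, CI-exclusion significance,
   and posterior group-mean contrasts.
5. **Roost vegetation** — sequential (adonis-style) PERMANOVA on a
   distance matrix, bootstrapped 1000× over one-roost-per-individual-
   per-season subsamples; median pseudo-F with 2.5/97.5% bounds and the
   median-p significance rule.
6. **Survival** — product-limit surviving-proportion curves by sex × risk
   group and first-10-day mortality summaries.

A synthetic-data module generates complete studies (relocations, bearing
sets, camera counts, vegetation plots, fates) from an explicit
`SimulationTruth`, so every stage can be checked against known parameters.

## The model at the core

Movement is summarized by the utilization distribution
`f(z) = (1/(n·2πh²)) Σᵢ exp(−|z − xᵢ|²/2h²)`; the p% home range is the
smallest region holding p of its mass. Log area (and log center-shift
distance) are analyzed with LMMs such as

```
log(area95) ~ risk_group * season + year + (1|site) + (1|individual)
log(area95) ~ log(pressure) + sex + median_day + window_length + (1|site) + (1|individual)
```

with inference via draws β⁽ᵏ⁾ ~ N(β̂, V̂·σ²⁽ᵏ⁾/σ̂²), σ²⁽ᵏ⁾ ~ σ̂²·df/χ²_df —
the flat-prior approximate joint posterior of the REML fit.

## Worked example

```python
from preyspace import SimulationTruth, simulate_dataset, daily_pressure
from preyspace.risk import extend_pressure_preseason
from preyspace.homerange import seasonal_home_ranges, seasonal_shifts
from preyspace.windows import moving_window_table
from preyspace.inference import space_use_model_suite

truth = SimulationTruth(seed=1, risk_response_sexes=("F",),
                        n_individuals={"F": {"high": 12, "low": 12},
                                       "M": {"high": 12, "low": 12}})
ds = simulate_dataset(truth)
pressure = daily_pressure(ds.camera_days).merge(
    ds.sites[["site", "group"]], on="site")
full = extend_pressure_preseason(pressure, list(ds.sites["site"]), truth.year)
seasonal = seasonal_home_ranges(ds.relocations)
windows, steps = moving_window_table(ds.relocations, ds.sites, full)
models = space_use_model_suite(seasonal, seasonal_shifts(seasonal),
                               windows, steps, pressure=pressure, seed=1)
print(models["size_F"].summary())
```

On this dataset the female size model recovers the simulated risk×season
response: the `risk(high):season(early)` interaction posterior mean is
**0.93** (95% CI 0.61–1.25, excluding zero; the generator's truth is
+0.77 on the log-area scale), while the same term in the male model is
−0.29 with a CI spanning zero — masked by early-season harvest mortality.
The moving-window model's `log_pressure` slope is positive (0.25, CI
0.21–0.28): individuals expand their ranges when hunters are present.
The simulated high-risk males lose ≈25–30% of their cohort in the first
ten season days; females on low-risk sites ≈3%.

The same pipeline runs from the shell:

```sh
preyspace simulate --out run/ --seed 1     # synthetic data + full analysis
preyspace analyze  --data mydata/ --out results/
preyspace report   --out results/          # markdown summary + survival figure
```

`analyze` consumes `relocations.csv`, `bearings.csv`, `cameras.csv`,
`vegetation.csv`, `fates.csv` and `sites.geojson` (planar meters,
ISO-8601 dates) and emits pressure, home-range, window, model, PERMANOVA
and survival tables plus a run manifest.

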