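# spacetoevent

Space-to-event (STE) density and recruitment estimation for **unmarked
animals** from timelapse camera-trap data.

Many populations — white-tailed deer among them — have no natural marks, so
capture–recapture is off the table. The STE approach instead treats each
synchronized timelapse exposure (every 10 min, say) as an instantaneous
snapshot of a landscape sampled by a fleet of cameras with known viewshed
areas. At each snapshot the cameras are scanned in random order and the
cumulative viewshed area is accumulated until a camera with an animal in
view is reached. If animals redistribute between occasions and follow a
homogeneous spatial Poisson process with intensity λ (animals·m⁻²), the
area scanned to the first detection is exponentially distributed,

  S_j ~ Exp(λ),  right-censored at the total active area A_j,

so density is estimated by maximum likelihood from the censored sample.
The package implements both the exact interval-censored likelihood
(the event is only located to within the detecting camera's viewshed,
ℓ(λ) = Σ_events [−λ·pre_j + ln(1 − e^{−λ·a_j})] − λ·Σ_cens A_j; the
default) and the classical exponential approximation, whose MLE is the
closed form λ̂ = n/ΣS. Standard errors come from the censored-exponential
Fisher information (SE = λ̂/√n) with right-skewed lognormal Wald intervals.

Everything around the estimator is included:

- **Viewshed geometry** — per-camera sampled areas from six-sector maximum
  viewable distances, a_i = Σ_j π r_ij² (θ/k)/360, with deployment vs
  retrieval reconciliation and implausible-change flagging.
- **Diel windows** — NOAA sunrise/sunset (zenith 90.833°) and
  crepuscular / diurnal / nocturnal classification, because animals that
  bed at midday and go undetected at night violate the "all animals
  available" assumption and bias full-diel estimates low; fitting within
  the peak-activity window restores the estimate.
- **Demography** — abundance extrapolation N̂ = D̂ × area, fawns-per-adult-
  female recruitment with a delta-method SE, camera-quantity subset curves,
  and a camera-level bootstrap.
- **Synthetic data** — a generator realising exactly the model's
  assumptions (Poisson placement, independent redistribution, per-class
  diel availability) with known truth, so every stage is testable without
  field data.
- **CLI** — `ste simulate | viewshed-area | fit | recruit | subsets`.

## Worked example

Simulate a 50-camera, 61-day survey at the default study conditions
(3 deer km⁻² across stage/sex classes, crepuscular-peaking availability,
~300 m² mean measured viewshed), then fit density over the crepuscular
window and extrapolate to abundance:

```python
import spacetoevent as ste
from spacetoevent.diel import solar_days_for_range

cfg = ste.SimConfig(seed=7)
cameras, viewsheds, events, truth = ste.simulate_dataset(cfg)
areas = ste.fleet_areas(viewsheds)
table = ste.build_occasion_table(events, areas, (cfg.start, cfg.end, cfg.step))

solar = solar_days_for_range(cfg.latitude, cfg.longitude,
                             cfg.start.date(), cfg.end.date(), cfg.utc_offset)
peak = table.filter_by_period(["crepuscular"], solar)
result = ste.STEModel(peak).fit(seed=1)
print(result.summary())
abundance = result.abundance(cfg.study_area_km2)
print(f"Abundance over {cfg.study_area_km2} km^2: "
      f"{abundance.n_reported} ({abundance.lci:.0f}-{abundance.uci:.0f})")
```

which prints

```
Space-to-event density fit
==============================================
Likelihood variant:         interval_censored
Occasions used:             1464
Occasions dropped:          0
Detection events:           59
Total exposure (m2):        21351985.6
Permutation seed(s):        [1]
----------------------------------------------
Density (km^-2):            2.8268
SE (km^-2):                 0.3680
95% CI (km^-2):             [2.1901, 3.6485]
==============================================
Abundance over 86.41 km^2: 244 (189-315)
```

The crepuscular-window estimate (2.83 km⁻², CI 2.19–3.65) brackets the
3.0 km⁻² truth: restricting occasions to the peak-activity window is what
makes the availability assumption hold. Fitting the same table over the
full diel grid instead returns ~1 km⁻² — not an estimator failure but the
availability bias the diel filter exists to avoid. The 1464 occasions are
the ±1 h sunrise/sunset snapshots out of the 8784 on the 10-min grid; the
59 events drive the SE through λ̂/√n.

The same flows run from a shell against real CSV exports
(`ste fit --config run.yml`); see `spacetoevent/io.py` for the detections,
viewshed, camera, and outage CSV dialects.

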