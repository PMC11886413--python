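# Methods

## Model

A fleet of n cameras takes synchronized timelapse photographs every Δt
(default 10 min), producing instantaneous sampling occasions j = 1..J.
Camera i samples a fixed viewshed of area a_i (m²). Animals are assumed to
form a homogeneous spatial Poisson process with intensity λ (animals·m⁻²)
and to redistribute independently between occasions; Δt is the user's
responsibility and must be long enough for that independence to be
plausible (an animal feeding in front of one camera across consecutive
occasions violates it and biases density high).

At each occasion the active cameras are scanned in a fresh uniformly random
order and the cumulative area is accumulated until a camera containing at
least one animal of the target classes is reached. Under the Poisson
assumption the area scanned to the first detection is exponential with rate
λ, right-censored at the occasion's total active area A_j. The package fits
λ by maximum likelihood under either of two variants:

- **interval_censored** (default, exact). The event is only known to lie
  within the detecting camera's viewshed, i.e. in the area interval
  (pre_j, pre_j + a_det,j], giving
  ℓ(λ) = Σ_events [−λ·pre_j + ln(1 − e^{−λ·a_det,j})] − λ·Σ_censored A_j.
- **exponential_approx** (the classical form). The inclusive cumulative
  area s_j = pre_j + a_det,j is treated as an exact exponential
  observation; the MLE is the closed form λ̂ = n_events / (Σ s_j +
  Σ A_j,censored).

The event's space includes the detecting camera's full area (inclusive
convention). At camera-trap scale (λ·a_i ≈ 10⁻³) the two variants differ
negligibly — the suite checks their log-likelihood curvature agrees within
1% when max λ·a < 0.01 — but the interval-censored form is exact under the
model and is therefore the default. Whether an independently written STE
implementation includes the detecting camera's area in s, or uses the
interval-censored form, varies; both are provided and the convention is
stated rather than silently assumed.

### Uncertainty

SE(λ̂) = λ̂/√n_events, the inverse Fisher information of the censored
exponential (censored occasions carry no curvature). This analytic form is
more stable than a numerical Hessian at few events; the suite cross-checks
the two at 10⁻³ relative agreement. The 95% interval is the lognormal Wald
interval λ̂·exp(±1.96·SE/λ̂), chosen because the sampling distribution of
a rate MLE at modest n is right-skewed; its asymmetry (UCI − λ̂ > λ̂ − LCI)
is asserted as an invariant. Zero events raise an error rather than return
a boundary estimate; a single event returns a fit with a wide-CI warning.

### Numerics

Both variants are maximised by Brent root-finding on the score, which is
strictly decreasing in λ; the bracket spans [λ₀·10⁻⁶, λ₀·10⁶] around the
closed-form estimate λ₀, with relative tolerance 10⁻¹⁴. The suite verifies
the optimiser equals n/ΣS to 10⁻⁶ relative error on 200 random instances
and matches a 10⁴-point grid search for the interval-censored form.
ln(1 − e^{−x}) is evaluated as log(−expm1(−x)) for small-x stability.

## Viewshed areas

A camera's sampled area is the circular sector of its lens angle θ
partitioned into k equal wedges (k = 6 by default) with individually
measured maximum viewable distances: a_i = Σ_j π r_ij² (θ/k)/360. The
per-wedge angle is the exact division θ/k, never a rounded value. Areas are
carried in m² end to end; densities convert to km⁻² (×10⁶) only at
reporting, and all rounding (abundance to integer half-up, recruitment to
two significant figures) happens at report time with full precision kept in
machine-readable output. The "assumed viewshed" workflow — a single
manufacturer-spec sector area (e.g. 30 m PIR trigger distance at a 38.72°
lens ≈ 304.11 m², conventionally rounded to 300 m²) applied fleet-wide —
is expressed as a constant-area override on the occasion table. Because
λ̂ scales exactly as 1/c when all areas scale by c (an asserted identity),
a mis-assumed constant viewshed shifts density in direct proportion to the
area error, in the direction opposite the error's sign.

When viewsheds are measured at both deployment and retrieval, a policy
(deployment / retrieval / minimum / per-camera override) selects which to
use, and any camera whose area ratio between phases exceeds a flag
threshold (default 3) is flagged: vegetation growth or mismeasurement can
change a single camera's area by orders of magnitude and visibly move the
fleet-level estimate. Radii above an optional cap are flagged, not
rejected — implausible distances are a data-integrity signal, not
necessarily an error.

## Diel windows and availability

Sunrise and sunset come from the NOAA solar position algorithm (single
evaluation at local solar noon, zenith 90.833° = solar radius + standard
refraction), in local civil time under one fixed per-run UTC offset — the
study windows of interest sit inside a single DST regime, and a fixed
offset keeps timezone databases out of the core logic. Agreement with an
independently implemented almanac algorithm is asserted to ±3 min;
latitudes poleward of ±66.5° are rejected rather than mishandled.

Each occasion is classified crepuscular (within a buffer, default 1 h, of
sunrise or sunset; closed interval, so a timestamp exactly at the window
edge is crepuscular), diurnal (strictly inside the buffered daytime), or
nocturnal (otherwise); the three classes partition the diel cycle. The
peak-activity period for a class is the one maximising detections per
occasion — effort-normalised, because the three periods contain very
different numbers of occasions — with ties broken crepuscular > diurnal >
nocturnal. Peak selection is done per class (fawns often peak diurnally
while adult females peak crepuscularly), and recruitment may therefore
combine fits from different windows; the window labels travel with the
estimate.

Availability is the probability that an animal present in the study area
can be detected at an occasion (active, above ground, within viewable
space). Fitting over the full diel grid when availability varies by period
converges to (occasion-weighted mean availability) × truth — the estimate
is biased low by exactly the unavailable fraction — while fitting only
within the full-availability window recovers truth. The suite demonstrates
both limits mechanistically with the generator.

## Occasion table construction

Detections mark presence at the occasion within a match tolerance (default
60 s; timelapse stamps should land on the grid, the tolerance absorbs
clock drift). Duplicate detections at one camera-occasion merge; group
counts are retained on the detection records but the model consumes
presence only — the event is "≥1 animal in view". Cells outside a camera's
deployment interval or inside a declared outage window (theft, fire) are
inactive, excluded from exposure, and may not carry presence; outages are
explicit input rather than inferred from photo gaps, because gap inference
is unreliable when timelapse data loss is itself the failure mode.
Unknown-deer detections count toward the pooled all-deer fit but are
excluded from fawn-only and adult-female-only fits by default (a switch
exists): assigning unknowns to a stage class would manufacture information.

## Demography

Abundance is N̂ = D̂ × area with CI endpoints scaled identically (linearity
in area is asserted). Recruitment is fawn density ÷ adult-female density —
identical whether densities or abundances over the same area are used. Its
standard error, ratio·√(cv_fawn² + cv_AF²) by the delta method under
independence of the two fits, is an extension beyond the conventional
point-ratio report and is labelled as such; the suite checks it against a
1000-draw parametric bootstrap from the two lognormal sampling
distributions (15% agreement).

Camera-quantity curves refit nested subsets (the first k cameras in
deployment order, so size 40 means the last 10 deployed cameras removed),
each under the same seed policy. The camera bootstrap resamples cameras
with replacement; a subtlety matters here: copies of a duplicated camera
must not keep their occasion histories in lockstep, or replicate event
counts scale with the *unique* resampled area while exposure scales with
the full resampled area, biasing every replicate low by roughly 1/e.
Second and later copies therefore get an independent occasion permutation
of their (active, presence) history — valid because occasions are
exchangeable under the model, preserving each camera's marginal detection
frequency exactly while making copies behave as the exchangeable draws the
bootstrap intends. An identity resample reproduces the point fit exactly,
and every replicate is regenerable from its logged seed alone.

## Synthetic data

The generator realises the estimator's own model: per occasion and class,
the available population is Poisson with mean (density × study area ×
availability for the occasion's period), placed independently each
occasion (no animal identity, home ranges, or attraction/avoidance — the
generator deliberately tests the estimator under its assumptions, and
violation scenarios are out of scope). Two placement modes share this
model: an explicit point process with sector-wedge containment (plain
trigonometry: bearing → wedge index, radius test; exact for circular
wedges), and Bernoulli thinning drawing presence at camera i directly from
the marginal 1 − exp(−λ_avail·a_i) (exact and much faster; the suite
checks the two modes are statistically indistinguishable camera-by-camera).
Cameras sit at least the scenario's maximum radius from the region edge so
every wedge lies inside the region and the modes match exactly.

Defaults describe a late-summer deer survey in southeast Oklahoma: 50
cameras on an 86.41 km² area, 10-min occasions from 1 Aug to 30 Sep
(61 d × 144 = 8784), latitude 35.0°, longitude −95.5°, UTC−5, lens 38.72°.
Sector radii are lognormal by habitat scenario: open-forest μ=3.07,
σ=0.6, cap 75 m (mean camera area ≈ 300 m² — the cap truncation is
included in that calibration) and dense-understory μ=2.21, σ=0.7, cap
40 m (≈ 70 m²), spanning the order-of-magnitude spread that measured
forest viewsheds show. Class densities default to adult female 1.5, adult
male 0.8, fawn 0.4, unknown 0.3 km⁻² (total 3.0, a realistic managed-
forest deer density), with availability crepuscular 1.0 / diurnal 0.3 /
nocturnal 0.0 for adults and a diurnal fawn peak (0.3/1.0/0.0) so
per-class peak selection is exercised. Explicit blank rows (what a real
export contains for empty frames) are optional — they carry no information
beyond the occasion grid.

What passing tests show about real data, and what they do not: recovery
and coverage results certify the estimator under independent
redistribution, homogeneous density, perfectly measured areas, and exact
snapshot timing. Real surveys violate each to some degree (home ranges,
habitat selection, viewshed change over the season, clock drift), so field
performance claims require the diagnostics (viewshed flags, per-period
event logs), not just these suites.

## Validation problem sizes

Closed-form/optimiser agreement uses 200 random censored instances;
recovery/coverage uses 100 full-scale replicates (50 cameras × 8784
occasions, availability ≡ 1, truth 4 km⁻², Bernoulli-thinning mode),
asserting mean-estimate agreement within 5% and CI coverage in [90%, 99%];
the availability experiment uses 20 replicates with 7% tolerances (about
three Monte-Carlo standard errors of the replicate means); permutation
stability uses 50 orderings of one ≥300-event dataset (CV < 5%); the
bootstrap-consistency check uses 200 replicates.

## Known limitations

- Independence between occasions is assumed, never tested; choosing Δt is
  the user's job.
- Density is homogeneous in the likelihood; covariate models on λ are out
  of scope, as are TTE/REM/REST/spatial-count alternatives.
- The recruitment SE assumes the fawn and adult-female fits are
  independent, though they come from the same camera array; shared-camera
  correlation is not modelled.
- Nocturnal viewshed reduction (flash-limited range) is representable only
  through availability, not through time-varying areas.
- The solar computation targets mid-latitudes; polar day/night is rejected.
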