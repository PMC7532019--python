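# Methods

## Physical model

The perfusion circuit is a rotating liquid column driving flow through one
shallow rectangular channel and past a capillary burst valve.

**Centrifugal pressure.** Δp_c = ½ρω²(r₂²−r₁²) between the inner radius r₁
(taken at the middle of the inner reservoir compartment, a compromise
between its full and empty states) and the outer radius r₂ (the media
channel outlet). Steady rotation only; spin-up/spin-down transients are not
modelled.

**Hydrostatic pressure.** Δp_h = ρg₀H with g₀ = 9.80665 m/s². H is treated
as constant while spinning: the inlet compartment is kept full to the brim
and rotation pushes the effluent past the outlet port, so the level above
the outlet stays zero.

**Channel flow.** Q = [h³w/(12ηL)]·(1 − 0.630·h/w)·Δp, the first-order
shallow-channel (h ≪ w) approximation of rectangular-duct Poiseuille flow.
The default channel has h/w ≈ 0.054, far inside validity; geometry
validation emits a warning (not an error) above h/w = 0.5 where the
single-term correction degrades. Entrance effects, compliance and bubble
dynamics are neglected, and the dead-end tissue-chamber branch carries no
net flow, so it has no hydraulic representation.

**Burst valve.** p_v = −4σ·cos(θ_max)/d for a circular port of diameter d;
θ_max = 180° is the conservative ceiling (p_v = 4σ/d). Pinning is modelled
as a *permanent* constant backpressure: since the effluent is pushed
radially past the port, no liquid accumulates above it to quench the
meniscus. A one-shot valve (backpressure only until first burst) is
deliberately not implemented. Contact-angle hysteresis and
surface-roughness effects, which plausibly lower the effective p_v, have no
quantitative model here.

Combining the three gives the piecewise flow-vs-speed law
Q(ω) = B·max(0, ω² − ω₀²) with ω₀² = (p_v − Δp_h)/(½ρ(r₂²−r₁²)) and
B = C·½ρ(r₂²−r₁²), C the channel conductance. Four variants are kept for
model comparison: hydrostatic-only, centrifugal-only, combined (both, no
pinning), and the pinned law above.

## Units, geometry and provenance

All internal computation is in SI base units; rpm, μl/h, mm and g appear
only at interfaces. Fluid properties come from a small fixed table (water
at 4, 20, 25, 37 °C; handbook values) rather than live interpolation, so
every pressure the package prints is exactly reproducible; untabulated
temperatures are an error, never silently interpolated.

Every geometry value carries a provenance tag. Printed dimensions: channel
75 μm × 1.4 mm, port diameter 2 mm, head 8 mm, 10 cm disc, 4 systems × 5
chambers. Derived: the chamber radius 41.5 mm, back-computed from the
printed 1000 rpm ↔ 46.4 g anchor; this single radius reproduces the whole
printed speed↔g ladder to its printed precision (at 4000 rpm it gives
742.5 g against a printed 743 — consistent within the ±1 rounding of the
anchor itself, and the package always reports its own computed value). A
separate rotor preset (192.8 mm) covers the benchtop-centrifuge pairs
(1000 rpm ≈ 216 g, 1500 rpm ≈ 485 g) and is never mixed with disc geometry.
Assumed: r₁ = 10 mm, r₂ = 45 mm, L = 100 mm are free placeholders — the
device description never prints them — and every derived quantity inherits
the weakest provenance among its inputs (printed < derived < assumed), so a
burst pressure in pascal obtained through these radii is always flagged
`assumed`.

## Fitting the burst pressure

Input: per-speed mean flows with replicate standard deviations. Weights are
1/σ_i² with σ_i = sd_i/√n_i — the standard error of the mean, the natural
weight when the fitted points are replicate means ("error-weighted" without
a stated weight definition admits this as the standard reading). If every
σ_i is zero the fit degrades to unweighted with a warning; a mixture of
zero and nonzero σ_i is an error.

The objective is non-smooth in ω₀ wherever the threshold crosses a data
speed, so generic gradient optimizers stall. Instead the fit profiles a
*signed* threshold parameter a (equal to ω₀² in the pinned regime) on a
2000-point grid; at each candidate, B has a closed-form weighted
least-squares solution. The best grid point is polished twice: by a bounded
scalar search, and exactly — within one active set {i : ω_i² > a} the model
Q = Bω² − c is linear in (B, c), so the joint stationary point is available
in closed form and a = c/B. The distinguished point a = 0 (no pinning) is
always evaluated, so a threshold-free optimum is returned exactly.

The signed domain is the reason the model family nests its rivals: a < 0
corresponds to p_v below the hydrostatic head (the valve is open at rest
and the residual drive produces a constant flow), bounded below by the
p_v = 0 point when the column geometry is known. The unpinned combined
model is exactly the p_v = 0 member, so on data without pinning the fitted
threshold collapses to ω₀ = 0 and the pinned fit matches the combined
prediction instead of being structurally unable to.

p_v is reported only when the column radii are supplied (the conversion
needs them); otherwise the fit reports ω₀ and declines to convert. Both B
modes are implemented — B free ("fitted", the default, matching a fit with
a variable burst pressure) and B pinned to its geometry value
("fixed_from_geometry") — because the original analysis does not state
which was used.

**Uncertainty.** The threshold parameter is non-regular (the objective is
only piecewise smooth in it), so asymptotic covariance is unreliable; a
seeded parametric bootstrap is used instead. The default scheme redraws
each point's n_i replicates from Normal(mean_i, sd_i) and recomputes both
the mean and the sd before refitting, which propagates the sampling noise
of the scatter itself into the interval. The simpler scheme that resamples
only the means from Normal(mean_i, sd_i/√n_i) with sd fixed is kept as
`resample="means"` for comparison: a calibration study against the
synthetic generator (300 campaigns, 400 resamples each) measured 89.7%
coverage of the nominal 95% interval for the fixed-sd scheme — the classic
z-versus-t narrowing at n = 8 — against 92.0% for the replicate-level
scheme, which was therefore made the default. Reported: bootstrap sd of
p_v and the percentile 95% interval; a refit failure rate above 20% of
resamples aborts with diagnostics.

R² is computed unweighted, 1 − SSR/SST against the mean of the per-speed
means, so the statistic is comparable with values quoted for fits of mean
flow curves. Model comparison ranks the four variants by *weighted* SSR;
the three non-pinned variants enter as parameter-free predictions from the
geometry, the pinned one as the fitted model.

## Synthetic campaigns

The generator emulates the flow-measurement protocol: speeds 0, 50, 100,
150, 200 rpm; eight replicates per speed; 1 h collections; per-replicate
effluent mass = flow × duration × density, computed from the noisy flow so
mass bookkeeping is exactly consistent. Noise is Gaussian on the flow with
sd = max(relative_sd·Q_true, floor_sd), truncated at zero by resampling —
clipping would put a point mass at exactly zero and distort the sd. The
floor (default 3 μl/h) reflects the small apparent flow measured at rest;
the relative component (default 12%) is a generator choice, since
replicate-level scatter was never published. The default truth is the
pinned model calibrated exactly through the two reference measurements
(97 μl/h at 100 rpm, 445 μl/h at 200 rpm) via the closed-form two-point
solution.

Not emulated: evaporation, spin-down transient volume, speed-controller
error — the real campaign's systematics. Recovery results on synthetic
campaigns therefore demonstrate statistical identifiability of the model
under the stated design, not instrument accuracy, and the original fitted
value of 97 ± 17 Pa on the real (unpublished) replicates is *not* a
reproduction target of any test.

`perturb_geometry` supports sensitivity studies for the assumed radii and
channel length: each `assumed` length is jittered by an independent
lognormal factor while printed/derived fields stay bit-identical.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical campaigns
and bootstrap intervals. The recovery studies use 200–400 seeded campaigns
with 250–300 bootstrap resamples each — enough for the bias to be measured
to ~0.05 Pa and coverage to ~1.5 percentage points, while a full study runs
in about a minute on one CPU. Measured at the default design: bias
+0.04 Pa, estimator sd ≈ 1.0 Pa, 95%-CI coverage ≈ 92%.

## Known limitations

- Forward flow predictions (and any p_v in pascal) depend on the assumed
  r₁, r₂ and L; they are design aids, not ground truth, and are flagged so.
- The permanent-backpressure reading of pinning is the fitted assumption;
  if effluent accumulated above the port during a run, the effective
  threshold would decay in a way the model cannot express.
- The water-property table is fixed-point, not a general equation of state;
  media with serum or additives need explicit FluidProperties.
- Protocol planning records incubation gaps and gravity-driven flushing
  between loading steps as metadata only; no flow model is attached to
  those gaps.
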