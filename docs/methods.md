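# Methods

## Model overview

`fissureflux` estimates the annual soil CO₂ emission caused by earthquake
surface fissures. The causal chain is: an earthquake of magnitude M opens a
total fissure length L₀ and initial width W₀; the fissures heal over time
(length shrinks, width widens until infill); the exposed sidewall and
bottom areas, averaged over the time since the event, are multiplied by
chamber-measured emission rates. All physical parameters live in
`ModelConstants` and can be overridden from a flat YAML/JSON file.

## Scaling chain

The chain is anchored on the 2021 Maduo earthquake field survey: 653
fissures along five faults. The representative single-fissure length L′ is
the unweighted per-fault mean of the surveyed *maximum* fissure lengths
(942 m) — the maximum-emission reading of the survey; the per-fault mean of
the minima (76.6 m) is available through the same function for sensitivity
work. The Maduo total is L_M = L′ × N_M = 615,126 m, and any other event's
total scales linearly with its coseismic surface-rupture length,
L_k = (l_k / l_M) L_M.

Rupture length, where the catalog does not record one, inverts
M = 5.92 + 0.88 log₁₀ l (a continental-China magnitude–rupture-length
regression; l in **km**), and the initial width inverts
M = 6.81 + 0.78 log₁₀ W (a magnitude–average-displacement regression read
as the fissure aperture; W in **m**). Both logs are base-10, the standard in
seismological scaling laws, and both inversions round-trip to 1e-9 in
magnitude (tested). The source relations never state units explicitly;
km/m are the only choices that give plausible geometry at M ≈ 7. A recorded
rupture length always takes precedence over the inversion. The Maduo anchor
l_M defaults to the inversion at M 7.4 (≈ 48.06 km) and is overridable; the
anchoring magnitude itself defaults to 7.4 (the value used in the results
that the survey belongs to; 7.2 is also reported for the same event and can
be configured). Surface-wave and scaling-law magnitudes are treated as one
scale.

## Healing and exposed areas

Observed healing rates (from multi-year remote sensing of a large strike-
slip rupture) are per fissure: length shrinks at r_L = 0.49 m a⁻¹ and width
widens at r_W = 0.05 m a⁻¹ as sidewall material slumps into the crack.

**Central interpretive choice.** The rates are applied per *representative
fissure*: an event's total length behaves as L₀/L′ identical fissures of
length L′, so the total decays as L(t) = L₀ max(1 − r_L t / L′, 0) and
every event heals over the same recovery time t_rec = L′/r_L ≈ 1922.4 a.
Applying 0.49 m a⁻¹ to the event *total* would make healing time scale with
event size by orders of magnitude, contradicting the single-fissure
statistics behind the rates; that alternative reading remains available via
`mode="total_length"` on the healing/area functions, where
t_rec = L₀/r_L per event.

Width grows as W(t) = W₀ + r_W t while the fissure is open and is taken as
0 at and after t_rec: an infilled fissure has no exposed bottom. The
endpoint of widening is not constrained by the observations; truncation at
the length-driven recovery time is our choice. Depth is a constant D = 3 m
at all times (the soil carbon stock is concentrated in the top 3 m; no
depth-healing observations exist). Cross-sections are U-shaped: two
rectangular sidewalls and a flat bottom, so instantaneous areas are
S_w(t) = 2 D L(t) and S_b(t) = L(t) W(t).

Reported areas are multi-year averages over the time since the event,
integrated from the event date: with τ = min(T, t_rec),

    S̄_w = (2 D L₀ / T) (τ − τ²/(2 t_rec))
    S̄_b = (L₀ / T) (W₀ τ + r_W τ²/2 − (W₀ τ²/2 + r_W τ³/3)/t_rec),

the exact integrals of the linear/quadratic integrands (the 1/t_rec terms
vanish when healing is disabled, r_L = 0). The test suite checks the closed
forms against 10⁵-step trapezoid quadrature to 1e-6 relative on random
geometries. Note S̄_b is non-monotone in T: widening makes the bottom area
grow for centuries before length loss and averaging pull it down, so old
events can be bottom-dominated. Each event is averaged over its own elapsed
time T_k = reference_year − year_k (a single global T would be undefined
for a multi-century catalog); years use astronomical numbering (1 B.C. = 0)
so T_k is a plain subtraction, and a convenience `era` column (BC/AD) is
converted on read. An event dated in the reference year contributes its
initial areas (the T → 0⁺ limit). Catalog totals are plain sums over
events — additive and permutation-invariant by construction and by test.

## Emission budget

E = S̄_w E_w + S̄_b E_b in g CO₂ a⁻¹, with the sidewall/bottom components
reported separately, the plateau-wide rate increase E / A_plateau
(A = 2.57 × 10¹² m²), and percentage comparisons against user-supplied
reference fluxes or flux ranges (the literature denominators are cited, not
printed, in the source material, so they are config inputs). Reported
values are rounded half-up at the printed precision (3 significant figures
for E, 2 decimals for rates); full precision is kept internally. No
CO₂-to-C conversion and no CO₂-equivalent accounting.

## Chamber-flux processing

The field protocol measures hourly from 08:00 to 17:00, three replicates
per timepoint, on a control (uncracked, vegetation-removed) surface and
test surfaces (fissure sidewall, fissure bottom, and width×depth test
fissures carried as labels). Replicates are averaged per timepoint (more
than three at a timepoint is an error; fewer is a warning), timepoints pool
with equal weight into the group mean — no day/hour weighting — and each
group's annual rate is the mean instantaneous flux annualized as

    g CO₂ m⁻² a⁻¹ = µmol CO₂ m⁻² s⁻¹ × 44.01×10⁻⁶ g µmol⁻¹ × 31,536,000 s,

a 365-day year with the campaign mean standing in for the annual mean. The
aggregation of daytime spring/summer measurements into annual rates is not
otherwise constrained; this simplest defensible conversion is isolated in
`annualize_flux` so a season- or diel-weighted alternative can be swapped
in. The published rates themselves (968.53 / 514.79 / 1524.95 g CO₂ m⁻²
a⁻¹) enter the budget as constants, not re-derived. Ratios to control
(sidewall 63.51%, bottom 33.76%) fall out of the group summaries.

## Synthetic data

The generators are pure functions of their spec and seed (byte-identical
reruns) and emit data that pass every validator in the package.

- **Catalogs**: magnitudes from a doubly truncated Gutenberg–Richter law
  (density ∝ 10^(−bM)), default b = 1 — the canonical seismicity slope —
  over M 6.9–8.5 (the largest regional instrumental event is Ms 8.1);
  years uniform over the default −325…2022 window, matching the historical
  record's span; a configurable fraction of events (default 0.25) carries a
  recorded rupture length, scattered lognormally (σ = 0.2 in ln-space)
  around the scaling value, like field-mapped ruptures. A maximum-likelihood
  grid check in the tests recovers b within ±0.05 at n = 5000.
- **Campaigns**: hourly 08:00–17:00 timepoints, 3 replicates, fixed group
  multipliers (defaults: sidewall 0.6351, bottom 0.3376 of control — the
  field ratios), a control mean of 1.0987 µmol m⁻² s⁻¹ (annualizes to the
  measured control rate), a diurnal half-sinusoid peaking at 13:00 with
  amplitude 0.25 (soils warm with solar radiation; the shape is
  qualitative, not fitted), and multiplicative lognormal replicate noise
  with CV 0.2 by default, a typical chamber replicate spread. Default
  campaign length is 30 days, the scale of the field deployments.
- The bundled survey table (5 faults, 653 fissures) ships both as code
  (`table2_fixture`) and as a packaged CSV.

What the synthetic data do **not** emulate: spatial event placement and
fault geometry, magnitude-scale conversions, temperature/moisture
covariates of flux, seasonal flux cycles, and instrument-level file
formats. Passing parameter-recovery tests on these generators therefore
demonstrates that the pipeline arithmetic is correct under the stated
model, not that the model captures every feature of real campaigns.

## Numerical and interface choices

- Threshold filtering is inclusive (M ≥ 6.9). Duplicate catalog IDs warn
  but load; historical catalogs repeat names.
- Constants validate on construction: geometric and rate constants must be
  positive (healing rates may be 0, meaning no healing), the magnitude
  threshold must lie in [5, 9.5]; violating the measured rate ordering
  E_b < E_w < uncracked warns rather than fails, since users may probe
  other regimes.
- Closed-form areas clip sub-epsilon negative round-off from the cubic
  term to 0.
- CSV flux reads use round-trip float parsing so write→read is exact.
- The CLI logs stage summaries to stderr and writes results only to files;
  every run writes a manifest (input digests, config hash, package
  version) sufficient to reproduce it, and reruns on identical inputs are
  byte-identical apart from the manifest timestamp.

## Problem sizes in the test suite

Property checks run at sizes chosen to make the statistics sharp but the
suite quick: 100 random geometries against 10⁵-step quadrature, 5000-event
catalogs for slope recovery, and 200 seeded 30-day campaign replications
for ratio recovery (±3% tolerance ≈ 3 standard errors of the mean ratio at
CV 0.2 over 300 timepoints).

## Known limitations

- The healing model is deterministic and linear; no stochastic or
  asymptotic infill, and no depth evolution.
- The magnitude–width inversion treats an average-displacement regression
  as an aperture; widths at large M are accordingly generous.
- Annualization from daytime growing-season campaigns likely biases annual
  rates high; the conversion is isolated for replacement.
- Old events' bottom areas are sensitive to the width-truncation choice;
  see the non-monotonicity note above.
- No vegetation-type or regional stratification of emission rates.
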