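# Methods

## The simulated experiment

The generator reproduces a force-extension SMFS experiment on a 9×I27
homopolyprotein. At piezo displacement *Z* the chain extension *z* solves the
series force balance `k_c (Z − z) = F_wlc(z; p, Lc, T)`; the left side
decreases and the right side increases in *z*, so the root is unique. The
public scalar solver uses bracketed bisection (`brentq`, residual < 1e-4 pN);
inside the simulator the balance is solved for a whole piezo grid at once by
a vectorised bisection warm-started from the previous contour-length stage
(the old solution is a valid lower bracket because a longer chain extends
further at the same displacement).

Time is discretised on the acquisition grid `dt = 1/sampling_rate`. Within a
step the force is held at its step-start value (explicit scheme) and a
folded-domain rupture occurs with the exact per-step probability
`1 − exp(−n_folded · α(F) · dt)`, `α(F) = α0 exp(FΔx/kBT)`. Within a
constant-`Lc` stage this per-step Bernoulli cascade is sampled in one draw:
`E ~ Exp(1)` and the rupture lands on the first step where the cumulative
hazard reaches `E` — distributionally identical to stepping, but
vectorisable. A warning is logged when the realised per-step hazard exceeds
0.1; at the default acquisition rates this happens only on the final steps
before a rupture, where the force resolution per step (≈ r·dt ≈ 1–3 pN) is
still small against the Bell force scale kBT/Δx ≈ 25 pN. Halving `dt` moves
the mean rupture force by < 1 % (tested with ~6000 events per grid).

Default conditions mirror the experiment: speeds 400–12 800 nm/s, piezo
travel 400 nm, acquisition rate 2500 Hz at 400 nm/s scaling proportionally
with speed and capped at 80 kHz (so 80 kHz at 12 800 nm/s — both published
endpoints), cantilever 0.06 N/m (the value quoted for good signal-to-noise;
the cantilevers' nominal constant is 0.12 N/m and both are config-exposed),
ΔLc = 27.7 nm, p = 0.35 nm, T-dependent (Δx, α0) from the published I27
table, 5 pN Gaussian noise added to the *recorded* force only (instrument
noise does not feed back into the kinetics). The initial contour length
defaults to 9 × 4.4 nm (folded domains) + 5 nm linker = 44.6 nm; it is not
published and only shifts the first peak. Tether detachment is a
normally-distributed force threshold (400 ± 80 pN, truncated at 10 pN) —
detachment empirically needs a larger force than unfolding — rather than a
second Bell bond; this is sufficient to exercise the last-peak handling. An
optional adhesion artifact (decaying negative spike, −800 pN at contact,
confined to the first 20 nm) exercises the adhesion filter.

The clamped-force harness used for survival statistics samples the rupture
step from the same per-step law and then places the event within its step by
the conditional exponential density, so its output is exactly
Exponential(n·α(F)); the Kolmogorov–Smirnov test against the analytic CDF is
a check of the hazard bookkeeping, not of the discretisation.

## Curve correction and filtering

Correction: (1) linear baseline fitted over the final 20 % of the piezo range
(after detachment, force-free on any real retract trace; a `fit_baseline`
switch exists for synthetic never-detaching traces); (2) contact point = last
zero crossing of the median-smoothed force before the trace first exceeds
15 pN of tension; (3) tip–sample separation = piezo travel from contact minus
cantilever deflection F/k_c. With noise the detected contact sits where the
force leaves the noise floor (an offset of some nm toward positive
separation); this offset cancels in ΔLc, which is a difference of fits.

Detection: an event is a local maximum of the median-filtered force (window
5, chosen over Savitzky–Golay to preserve rupture edges) followed within 50
samples by a drop of ≥ 30 pN below the maximum; candidate maxima on the same
tooth (no intervening ≥ 30 pN drop) are merged, keeping the highest. The
30 pN drop threshold censors ruptures below ≈ 35–45 pN (peak force minus the
post-rupture relaxed force must exceed it).

Filtering, in order: < 3 events (first and last are unusable, leaving
nothing); > N+1 events (the +1 admits the detachment peak; more indicates
multiple tethers); force below −500 pN within the first 20 nm of separation
(surface adhesion); any peak-to-peak separation spacing deviating > 40 % from
the median spacing, the final (detachment) gap excluded. "Irregular pattern"
has no published numeric rule; spacing-vs-median is the simplest testable
proxy, and the ΔLc plausibility window downstream catches composite events
that pass it. Note that at the published 37 °C kinetic parameters the
simulated rupture-force distribution is broad (≈ 40–270 pN), so spacings
genuinely vary and the 40 % rule rejects the majority of curves; the rule is
deliberately left at its stated default rather than adapted to the generator.

## Event quantification

Each rising segment — from the end of the previous rupture's relaxation
(first sample back above 10 pN, or the relaxation minimum when the force
never drops that low) to the rupture maximum — is fitted with the WLC with
`p` fixed (single free parameter Lc, ordinary least squares on force,
standard error from the fit curvature; a config switch floats `p`).
FU is the raw (unsmoothed) force at the detected maximum (±2 samples): the
segment-wide maximum would bleed in the previous tooth when a sub-threshold
rupture was missed, and the median filter is edge-contaminated at the peak.
ΔLc_i = Lc_i − Lc_{i−1}. The first and last events of every curve are flagged
out of statistics, and events with ΔLc outside 27.7 ± 9 nm are excluded (the
window doubles as the composite/missed-event guard).

Loading rate: ordinary least-squares slope of the raw force against time over
the contiguous run of samples spanning the top 10 % of the segment's force
range (minimum 10 samples) before the maximum. It reduces exactly to k_c·v on
a Hookean ramp and tracks the WLC+cantilever series stiffness on model ramps.
On noisy data it is the pipeline's noisiest quantity: with 5 pN noise its
ln-r error has a standard deviation of ≈ 0.4, and at the slowest speeds the
10-sample window floor makes the slope estimate ≈ 30 % noisy per event.

## Bell–Evans estimation

The primary estimator pools all included events across speeds and regresses
FU (N) on ln r (N/s) by OLS — deliberately OLS, matching the field's "fitted
with a linear function" practice; the unit convention (r in N/s, v in m/s) is
recorded in every estimate because the intercept absorbs it. Δx = kBT/S;
α0 = 1/(S e^{c/S}) computed in log space; ΔG = ln(A/α0) in kBT with A = 1e7
s⁻¹ exposed (prefactors vary by orders of magnitude between studies, so ΔG is
always reported with the A used); D = 2ΔG/Δx². Standard errors propagate from
the slope/intercept covariance by the first-order delta method with analytic
Jacobians (verified against finite differences); an event-resampling
bootstrap is available as a cross-check.

The most-probable-force route (Fmp per speed from a Freedman–Diaconis
histogram with a Gaussian fitted to the modal bin ± 2 bins, falling back to
the modal bin centre; Fmp vs ln v) recovers Δx the same way but can only
yield α0 given an explicit effective stiffness k (its intercept absorbs
ln k); the implementation therefore requires a config-supplied k for that
route and reports α0 as unavailable otherwise.

A Monte Carlo grid search refines (Δx, α0) by simulating rupture-force
distributions per pulling speed at each grid point and minimising the summed
two-sample Kolmogorov–Smirnov statistic against the observed distributions
(KS chosen over chi-square to avoid a binning choice). It is deterministic
given a seed.

## Known biases and limitations

On synthetic data generated at the published 37 °C parameters the full
pipeline recovers the mean ΔLc to better than 0.1 nm, but Δx from the pooled
FU–ln r fit is overestimated by ≈ 20 % (typical recovery 0.20–0.22 nm against
a generating 0.17 nm). The decomposition, measured against the generator's
ground truth:

* an oracle fit on *all* true events with exact loading rates recovers Δx to
  ≈ 2 % — the estimator itself is sound;
* detection censoring (the 30 pN drop rule) removes the many sub-40 pN
  ruptures that the published kinetics produce at slow speeds, raising the
  low-speed force means and flattening the line (≈ +9 % on Δx);
* noise in the windowed per-event loading-rate estimate attenuates the
  regression slope (errors-in-variables; ≈ +7 %);
* acceptance filtering and the first/last exclusion add the remainder.

α0, the zero-force extrapolation of the line, is the least identifiable
parameter: with exact measurements the pooled fit converges to roughly the
*per-molecule* rate (⟨n_folded⟩·α0, a few-fold above the per-domain truth),
while the slope attenuation pushes it back down; recovered values typically
land within a factor ~2 of the generating rate but should be read as
order-of-magnitude estimates.

What passing tests show — and don't. The generator emulates the saw-tooth
mechanics, Bell kinetics, noise floor and acquisition of the experiment, but
not: refolding during retraction, the I27 unfolding intermediate, unspecific
multi-tether adhesion patterns beyond the single stereotyped spike,
cantilever dynamics (the cantilever is quasi-static), or drift. Parameter
recovery here therefore validates the analysis chain under the stated model,
not instrument-specific systematics.

Problem sizes: the in-silico study uses 50 curves per speed at six speeds
(≈ 600–650 included events at 37 °C, comparable to the published event
counts); distribution-level test statistics use 10⁴ draws (survival), 150–200
curves per condition (speed monotonicity), and ≈ 6000 events per grid
(time-step convergence).

Numerical choices: forces in pN and lengths in nm internally (kB T carried in
pN·nm; SI conversions only at the Bell–Evans interface, which works in N and
N/s); the WLC divergence guard is z/Lc ≤ 1 − 1e-6; fits are
`scipy.optimize.curve_fit`/`lstsq` with analytic initial values (the WLC Lc
start comes from inverting the dimensionless force at the segment end);
degenerate segments (no rising trend) and non-physical ramps (non-positive
slope) raise typed errors and the affected event is dropped with a logged
reason. Two amino-acid length constants coexist on purpose: 0.35 nm as the
fitting persistence length and 0.365 nm as the residue size for theoretical
ΔLc estimates; they are not reconciled.

All randomness flows from one top-level seed through
`numpy.random.SeedSequence.spawn` (speed-major, one child per curve), so any
dataset, test statistic or acceptance run is reproducible from its seed.
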