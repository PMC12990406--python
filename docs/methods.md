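# Methods

This note documents the models behind `dwatch`, the parameters that matter,
what the synthetic data generator does and does not emulate, and the
numerical choices that make runs reproducible bit for bit.

## Kinetic model

Every monitored compound is described by one species of a sequential
first-order chain with a dissolution front:

    M --k_d--> A --k1--> B --k2--> C

with `M` the undissolved pool in the herb tissue and A/B/C dissolved
species.  Units: amounts are arbitrary concentration units (the detector's
`response_factor` maps them to counts); all rates are per minute; time is
minutes from heating onset.  The 30-minute cold soak is collapsed into
`f0`, the fraction of the load dissolved at t = 0 (default 0.15 for
alkaloids and glycosides — the soak is described qualitatively in the
underlying protocol, never quantified, so one modest value is used
throughout and is configurable).

Class mapping: diester toxins are monitored as `A` (dissolution feeding a
hydrolysis loss), monoester actives as `B`, aminoalcohols as `C`, stable
compounds as `A` with `k1 = 0`, declining glycosides as `A` with a slow
first-order loss (the mechanism — complexation vs. transformation — is not
established, so a single phenomenological loss term is used), and thermal
conversion products (shogaols, zingerone) as `B` with `k2 = 0` plus a
pre-existing pool `B0`.  The biphasic polyphenol intermediate
(pentagalloylglucose) is the intermediate of a chain whose *source* is
itself released through a 12-stage Erlang delay: its observed rise is
convex late into the run (values near 0.2× peak at 100 min but a sharp
maximum near 180 min), a shape no two- or three-exponential chain can
produce; the staged delay stands for the stepwise hydrolysis of
higher-substituted galloylglucoses.  Aconine's transient co-decoction dip
over 50–100 min is reproduced with a time-windowed extra loss on `C`
(rate 0.05/min), again phenomenological.

Closed forms are used when everything is dissolved at t = 0 (the classical
sequential-decay solution, with the `k1 = k2` limit `k1·t·e^{−k1 t}`
handled explicitly to avoid 0/0); otherwise LSODA integration at
rtol 1e−10.  The two paths agree to <1e−6 relative and mass
`M+A+B+C` is conserved to the same tolerance (tested).

Co-decoction ("compatibility") effects are only multiplicative modifiers of
`(M0, k_d, k1, k2)` per compound, documented in the parameter file; the
`inhibition` field of `CascadeParams` divides `k2`, so larger values mean
stronger protection of the monoester — raising it can never lower `B(t)`.

## Scenario calibration

`src/dwatch/data/zwd_anchors.yaml` lists, per compound and system, the
reference intensity values (start/peak/end, plus the three-point trajectory
of the biphasic intermediate) that define the emulated conditions, and the
printed percent-change/ratio worked numbers with the reference convention
each uses (peak→end vs. post-dissolution(50 min)→end vs. start→end; the
fast-forming aminoalcohol uses its 30-min value).  Where a co-decoction
level is not part of the reference set (aminoalcohol co endpoints, the
stable-compound plateaus, shogaol's co start), a plausible design value is
recorded in the same file and marked by being absent from the printed
summary tables.

`scripts/calibrate_zwd.py` fits the chain parameters to those anchors once
(least squares in log-parameter space) and writes the versioned
`zwd_params.yaml`; the build never refits at run time.  Two calibration
targets beyond point values matter for the decision:

- the co-decoction toxin's fitted curve crosses half of its peak near
  105 min (its safe window must open in the 90–120 min band);
- the gating monoester's relative slope crosses +0.1 %/min near 105 min
  and −0.1 %/min at 150 min, so its plateau (see below) ends at 150 min.

With the toxin model class (dissolution + first-order loss) the peak value,
a ~105-min half-crossing and a ~47-min peak time cannot all be met at once;
the calibration prioritises the anchored peak value and the half-crossing,
which puts the toxin maximum near 36 min (inside the dissolution phase) —
peak *time* is not an anchored quantity.

## Acquisition model

5 Hz scan clock (⌊rate×duration×60⌋ scans: exactly 72,000 per ion mode at
240 min; the per-compound value count equals the scan count), positive and
negative modes as separate runs, unit-resolution channels: each compound
deposits `response_factor × concentration` at its nominal m/z.  Noise is
multiplicative lognormal with CV 0.05 (mean-one parameterisation) plus an
additive exponential baseline of mean 10 counts per channel; both are
modest defaults, configurable, and not fitted to any instrument.  No
isotope envelopes, charge states, chromatography, polarity switching,
MS/MS, drift, or cross-talk are modelled — passing tests say the pipeline
arithmetic is right, not that real matrix effects are survivable.

## Signal processing

EIC = per-scan sum of intensity within ±0.5 m/z of the nominal channel
(sum, not max: with unit-resolution deposition the window holds one peak).
Boxcar smoothing uses a centred window of 3 points whose half-width shrinks
symmetrically at the series ends (first/last points pass through
unchanged); this keeps the output inside the data's range and biases the
global mean by <0.5 % on series of ≥100 points.  The smoothed full-rate
series is block-averaged onto a 0.2-min grid (1,200 points) before fitting;
fitting the raw 72,000 points changes nothing statistically and costs two
orders of magnitude more time.

## Curve fitting

Gaussian sums (n ≤ 4) and Fourier series (n ≤ 3) are descriptive
smoothers.  Gaussian fits start from detected local maxima with five
deterministic restart perturbations; Fourier fits use variable projection
(linear coefficients exact given ω, ω initialised from the dominant FFT
frequency of the detrended signal, bounded scalar refinement, joint
polish).  Orders are tried from simple to complex with an early stop at
adjusted R² ≥ 0.9995; selection takes the highest adjusted R², ties within
1e−6 going to the fewer-parameter model.  Exact-family data are recovered
to ≤1e−4 relative with r² = 1−1e−9 (tested).

Summary conventions: trend is BIPHASIC if an interior maximum exceeds both
window ends by >15 %, else STABLE if |percent change| < 10 %, else the sign
of the change.  The plateau is the maximal interval around the curve
maximum where the curve stays within 10 % of that maximum *and* the
relative slope stays within ±0.1 %/min; with a slowly-declining fitted
curve the slope criterion is the binding edge, which is what pins the
gating monoester's plateau end at 150 min.

## SBTEF decision

Strictly lexicographic, because the five dimensions are described
ordinally (safety is "the top priority", bioactivity conditional on it,
then duration/energy/cost): no published numeric weights exist, so the
default is the hard-constraint ordering and a cardinal weighted mode is
provided but off by default.  Key parameters:

- `theta_safety = 0.5` of each toxin's own fitted peak.  This is a
  signal-relative proxy, not a pharmacological limit, and is the single
  most consequential free parameter: it is chosen so the toxin's safe
  window opens near the start of the 100–150 min band and is prominently
  configurable.
- `delta_bioactivity = 0.10` plateau band with 0.1 %/min slope cap.
- Bioactivity score: zero wherever any primary active
  (benzoylhypaconitine — the monoester whose retention the co-decoction
  effect protects) is outside its plateau; otherwise the mean over
  secondary actives (gallic acid, ellagic acid, 6-shogaol, zingerone,
  pentagalloylglucose) of curve(t)/max.  The declining monoesters are
  deliberately not in the gate: their plateaus sit before 100 min and an
  intersection gate would be empty.
- Endpoint grid 1 min; earliest maximiser within 1e−6 wins.  Energy =
  power × t/60 at constant 0.3 kW; cost = energy×rate + labour×t, both
  strictly increasing in t, so the earliest-time tie-break minimises all
  three trailing dimensions at once.

Because the secondary actives still rise through 105–150 min while the
gate closes at 150, the decision lands on the plateau's upper edge:
150 min (stable at 149–150 across noise seeds).

## Problem sizes and determinism

Default runs use the full 72,000-scan streams per mode and 1,200-point
fitting grids; the test suite exercises reduced scan rates (0.2–0.5 Hz)
where exactness, not scale, is under test.  All randomness flows from
explicit integer seeds (scenario seed → per-mode render seeds; fixed
sub-seeds for fit restarts), so identical inputs give byte-identical
outputs; ground-truth traces are deterministic and independent of the seed.

## Known limitations

- The kinetics are phenomenological: no temperature profile, pH,
  complexation equilibria or volume loss; co-decoction differences are
  rate/level modifiers, not mechanisms.
- Calibration anchors are treated as fitted-curve values; if they were raw
  or smoothed point readings the calibrated parameters would shift slightly
  (well within the 5 % anchor tolerance).
- The safety threshold is relative to the observed run's own peak, so it
  cannot flag a batch whose absolute toxin load is abnormal.
- Replicate support (`replicate_mean`: pointwise mean ± SD across
  independently processed replicates) exists but the default pipeline
  renders one replicate per ion mode.
- mzML output is a minimal uncompressed-float32 subset (with a matching
  reader); JSON-lines is the canonical, bit-exact format.
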