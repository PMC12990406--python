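# dwatch

Real-time mass-spectrometry monitoring of herbal decoctions: a simulation
and analysis pipeline for deciding *when to stop boiling*.

Classical multi-herb decoctions such as Zhenwu Decoction (ZWD: Fuzi,
Baishao, Fuling, Shengjiang, Baizhu) rely on heat-driven chemistry for
"toxicity attenuation and efficacy preservation": highly toxic diester
alkaloids from Fuzi (e.g. hypaconitine) hydrolyse into bioactive monoester
alkaloids (e.g. benzoylhypaconitine) and further into low-activity
aminoalcohols, while polyphenols, gingerol conversion products and
glycosides dissolve and transform on their own schedules.  Direct-infusion
online MS can watch all of this live — full scans over m/z 100–1500 at
~5 Hz give ≈72,000 intensity values per compound over a 240-minute run in
each ion mode — but turning that stream into a defensible decoction
endpoint needs a reproducible processing and decision chain.  `dwatch`
provides that chain, plus a calibrated synthetic scan-stream generator that
stands in for the instrument, for analysts developing or validating
endpoint rules.

## What it computes

1. **Kinetics** (`dwatch.kinetics`, `dwatch.scenario`) — every monitored
   compound class is one species of a sequential first-order chain with a
   dissolution front, `M →(k_d) A →(k₁) B →(k₂) C` (Bateman closed forms
   where available, tight-tolerance ODE integration otherwise).  The ZWD
   scenario ships with parameters calibrated so each curve passes within
   5 % of its reference intensity anchors, in both the single-herb and
   co-decoction systems.
2. **Acquisition** (`dwatch.stream`) — renders traces into full-scan
   streams (unit-resolution channels, multiplicative lognormal noise,
   exponential baseline), JSON-lines and mzML I/O.
3. **Signal processing** (`dwatch.processing`) — extracted-ion
   chromatograms (±0.5 m/z, sum aggregation), boxcar smoothing
   (points = 3, shrinking edges), block-averaging onto a 0.2-min grid.
4. **Curve fitting** (`dwatch.fitting`) — Gaussian sums
   y = Σ aᵢ·exp(−((x−bᵢ)/cᵢ)²) (n ≤ 4) and Fourier series
   y = a₀ + Σ aᵢcos(iωx)+bᵢsin(iωx) (n ≤ 3); model choice by adjusted R²
   with a parsimony tie-break; initial/peak/final values, percent changes,
   trends and plateaus are read off the fitted curve.
5. **SBTEF decision** (`dwatch.sbtef`) — lexicographic **S**afety >
   **B**ioactivity > **T**ime ≥ **E**nergy ≥ **F**inancial cost: toxins must
   fall below θ×their own fitted peak (θ = 0.5); inside that safe window the
   plateau-gated bioactivity score is maximised; among maximisers the
   earliest minute wins, which simultaneously minimises time, energy and
   cost.

## Worked example

```python
from dwatch import System, run_zwd_pipeline

result = run_zwd_pipeline(System.CO, seed=1)   # ~1 min on one CPU
print(result.decision.endpoint_min)
print(result.decision.safe_window)
print(result.decision.scores)
s = result.summaries["benzoylhypaconitine"]
print(s.trend.value, s.plateau)
```

prints

```
150.0
[(0.0, 3.4000000000000004), (107.2, 240.0)]
{'safety_toxic_fraction_of_peak': 0.25870108702255273, 'bioactivity': 0.7919707842934891,
 'time_min': 150.0, 'energy_kwh': 0.75, 'cost': 7.95}
biphasic (104.80000000000078, 150.00000000000142)
```

Reading: the toxin (hypaconitine) stays under half of its fitted peak from
107 min onward (the interval before 3.4 min is the trivial pre-dissolution
window); the gating monoester holds its high-efficacy plateau from ~105 to
150 min; the late-rising secondary actives (gallic acid, ellagic acid,
6-shogaol, zingerone, pentagalloylglucose) make the bioactivity score
increase through that plateau, so the endpoint lands on its upper edge —
**150 min**, at 0.75 kWh of heater energy.

The same chain is available from the shell:

```bash
dwatch simulate --system co --seed 7 --out run/
dwatch process  --stream run/stream.co.pos.jsonl --system co --out run/
dwatch process  --stream run/stream.co.neg.jsonl --system co --out run/
dwatch fit      --eics run/ --out run/
dwatch endpoint --fits run/ --out run/co.decision.json
dwatch report   --run-dir run/ --out run/report.md
```

## Layout

- `src/dwatch/` — library modules (kinetics, scenario, stream, processing,
  fitting, sbtef, pipeline, cli)
- `src/dwatch/data/` — compound library CSV, intensity anchors, calibrated
  kinetic parameters
- `docs/methods.md` — model assumptions, parameter choices, limitations
- `tests/` — unit, property and acceptance tests
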