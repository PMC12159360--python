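# uasswath

Analytics for the technical assessment of UAV (drone) sprayers, as
performed under the Swiss regulatory framework for aerial plant-protection
treatments. The package implements, as a tested and reusable library, the
computations an assessment engineer runs on homologation and survey data:

* **Patternator overlap analysis** — from a single-pass transversal spray
  distribution, simulate multiple back-and-forth passes at every candidate
  inter-lane spacing and determine the *effective swath width*: the
  greatest spacing *s* whose simulated deposition pattern has a coefficient
  of variation CV(*s*) = 100 · σ/μ below the 15 % uniformity criterion
  (σ the sample standard deviation, μ the mean deposit over one central
  swath-wide window). Includes the tank mass balance.
* **Lateral wind** — projection of 10 Hz three-component anemometer
  records onto the flight line's perpendicular, Tukey box summaries, and
  UAV-induced pulse statistics.
* **Fleet meta-analysis** — per-model effective-swath-width box
  statistics, OLS regressions of median swath width against UAV width and
  maximum take-off weight (MTOW), and MTOW vs total propeller working area
  (n · π d²/4).
* **Survey extrapolation** — plot-year deduplication, aggregation by crop
  / target / canton / slope band, and national estimates via the rounded
  inverse response rate.
* **Deposition & efficacy** — tracer deposits normalized by application
  rate, ground/UAV ratios per canopy region, and mildew severity
  summaries.
* **Compliance rules** — weather gate (go / advisory / no-go), composable
  safety distances ("the most stringent applies"), and the ±50 cm flight
  precision check.

No assessment dataset is publicly distributed, so the `synthetic` module
generates every input with the statistical structure the analyses assume
(Gaussian-plume spray profiles, AR(1) ambient wind plus a transient,
fleets with MTOW linear in propeller area, survey records with repeat
treatments, region-attenuated deposition).

## Worked example

```
python examples/patternator_swath.py
```

```
single pass: 61 grooves, 4.85 L collected over 6.1 m
mass balance: 4.85 kg (~5 kg tank weight difference)

CV by inter-lane spacing (threshold 15%):
   0.1 m  CV   0.74%  ok
   ...
   2.6 m  CV  16.35%  --
   3.1 m  CV   5.82%  ok
   4.1 m  CV  35.00%  --

effective swath width: 3.5 m (greatest spacing with CV below the criterion)
```

A 4.85 L collection means the aircraft landed about 5 kg lighter than it
took off (the patternator cross-check on tank weight). The CV stays low
while passes overlap heavily, peaks once adjacent plumes fall between each
other, dips again at an overlap resonance, and climbs steeply once lanes no
longer overlap; the greatest compliant spacing — here 3.5 m — is the
effective swath width a farmer may fly. Further scripts in `examples/`
cover wind summaries, fleet regressions, survey extrapolation (471 ha of
respondent vineyard area at a 28 % response rate → factor 3.57 → 1681 ha ≈
11.5 % of the 14 569 ha national vineyard surface), deposition ratios and
the compliance checks. A thin CLI exposes the same chains
(`uasswath simulate|swath|wind|fleet|survey|efficacy|check ...`).

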