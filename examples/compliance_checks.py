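"""Operational compliance checks: weather gate, distances, flight precision."""

from uasswath.compliance import (
    TreatmentScenario,
    WeatherConditions,
    flight_precision,
    required_safety_distance,
    weather_gate,
)

scenarios = [
    ("calm morning", WeatherConditions(20, 4.0, 2.0, 2.0)),
    ("gusty", WeatherConditions(20, 6.0, 2.0, 2.0)),
    ("steady breeze", WeatherConditions(20, 4.5, 4.0, 2.0)),
    ("heat + haze", WeatherConditions(27, 2.0, 1.0, 0.8)),
]
for name, cond in scenarios:
    verdict, reasons = weather_gate(cond)
    print(f"{name:14s} -> {verdict.value}")
    for r in reasons:
        print(f"                 {r}")

print()
cases = [
    ("field crops, heavy UAV",
     TreatmentScenario("field_crops", mtow_over_10kg=True)),
    ("vineyard, product says 50 m",
     TreatmentScenario("vineyard", product_drift_distance=50.0)),
    ("orchard by a stream, direct payments",
     TreatmentScenario("orchard", near_surface_water=True, direct_payments=True)),
]
for name, scenario in cases:
    d = required_safety_distance(scenario)
    print(f"{name}: drift {d.drift_m:g} m, water {d.water_m:g} m, "
          f"bystander {d.bystander_m:g} m -> governing {d.governing_m:g} m")

print()
for track in ([0.1, -0.3, 0.4], [0.2, 0.6, -0.1]):
    max_abs, ok = flight_precision(track)
    print(f"track deviations {track}: max |dev| {max_abs:.1f} m -> "
          f"{'pass' if ok else 'fail'} (+/- 50 cm rule)")
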