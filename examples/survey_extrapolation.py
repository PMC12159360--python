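"""Survey aggregation and national extrapolation.

Aggregates synthetic treatment records (repeat treatments of a plot within
a year count once), then reproduces the extrapolation arithmetic on the
reported respondent numbers: 471 ha of vineyard treatments at a 28%
response rate against the 14 569 ha national vineyard surface.
"""

from uasswath import synthetic
from uasswath.survey import aggregate, deduplicate, national_estimate

records = synthetic.gen_survey(
    synthetic.SurveyGenParams(n_plots=120, duplicate_rate=0.25, seed=4)
)
unique = deduplicate(records)
print(f"{len(records)} records -> {len(unique)} unique plot-years")
for key in ("crop", "target_class", "slope_band"):
    totals = aggregate(unique, key)
    pretty = ", ".join(f"{k}: {v:.1f} ha" for k, v in sorted(totals.items()))
    print(f"  by {key}: {pretty}")

est = national_estimate(471.0, 0.28, reference_total=14569.0)
print(f"\nrespondent vineyard area: {est.respondent_area_ha:.0f} ha")
print(f"extrapolation factor: {est.factor} (= round(1/{est.response_rate}, 2))")
print(f"national estimate: {est.estimate_ha} ha "
      f"= {est.share_percent}% of the {est.reference_total_ha:.0f} ha "
      "vineyard surface (an upper bound: non-respondents may have had "
      "nothing to report)")
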