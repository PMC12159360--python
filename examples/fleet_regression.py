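"""Fleet meta-analysis: what predicts the effective swath width?

Generates a synthetic fleet whose MTOW is linear in total propeller working
area, then (i) recovers that relation by OLS and (ii) compares how well
total UAV width vs MTOW predict the per-model median effective swath width.
"""

from uasswath import synthetic
from uasswath.fleet import (
    compare_correlations,
    linreg,
    model_summary,
    propeller_working_area,
)

models = synthetic.gen_fleet(11, seed=5)
print("model      rotors  d(m)  area(m2)  MTOW(kg)  median esw(m)")
for m in models[:5]:
    box = model_summary(m.esw_measurements)
    print(f"{m.model_name:9s}  {m.rotor_count:5d}  {m.propeller_diameter:4.2f}"
          f"  {propeller_working_area(m):7.2f}  {m.mtow:7.1f}  {box.median:6.2f}")
print("...")

areas = [propeller_working_area(m) for m in models]
fit = linreg(areas, [m.mtow for m in models])
print(f"\nMTOW vs propeller working area: "
      f"slope {fit.slope:.1f} +/- {fit.slope_se:.1f} kg/m2, R2 {fit.r_squared:.3f}")
print("(strong correlation: lift scales with total disc area)")

report = compare_correlations(models)
print(f"\nmedian esw ~ total width: R2 {report['r2_width']:.3f}")
print(f"median esw ~ MTOW:        R2 {report['r2_mtow']:.3f}")
print(f"stronger predictor: {report['stronger_predictor']}")
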