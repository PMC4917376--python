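"""Tolerance limits from the ±0.2 mm aperture reproducibility specification.

The manufacturer specifies the iris aperture reproducible to ±0.2 mm at the
nominal 800 mm distance.  Converting that to percentage limits on the QA
quotient gives the per-aperture action levels.  With an ideal step profile
and a flat output factor the limits are pure area ratios — ±0.67% at 60 mm,
+1.34/−1.33% at 30 mm — while the steep small-field OF gradient widens them
at small apertures.
"""

import irisqa as q

chamber = q.ChamberSpec()
step = q.BeamProfileModel(penumbra_mm=0.0)
flat_of = q.OutputFactorTable((5.0, 60.0), (1.0, 1.0))

print("ideal step profile, flat OF (pure area scaling):")
for d in (5.0, 30.0, 60.0):
    plus, minus = q.calculated_limits(step, flat_of, q.ApertureSpec.iris(d), chamber)
    print(f"  {d:5.1f} mm: {plus:+6.2f}% / {minus:+6.2f}%")

print("\nsigmoid profile, synthetic OF table (clamped extrapolation):")
model = q.BeamProfileModel()
table = q.default_output_factor_table()
limits = q.calculated_limits_table(model, table, chamber)
for d in (5.0, 30.0, 60.0):
    plus, minus = limits.at(d)
    print(f"  {d:5.1f} mm: {plus:+6.2f}% / {minus:+6.2f}%")

print("\nThe mm equivalent of a limit follows the area-scaling ruler:")
plus, _ = limits.at(5.0)
print(f"  +{plus:.2f}% at 5 mm = {q.delta_to_mm(plus, 5.0):+.3f} mm")
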