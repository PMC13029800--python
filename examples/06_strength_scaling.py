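"""Maximum-isometric-force scaling from anthropometry.

Total lower-limb muscle volume follows the linear regression
V [cm^3] = 47 * mass [kg] * height [m] + 1285, and each muscle's force
scales with its volume ratio divided by its optimal-fiber-length ratio
(force proportional to physiological cross-sectional area).
"""

from mskwarp.strength import (AnthropometrySpec, MuscleStrengthSpec,
                              apply_strength_scaling, handsfield_volume,
                              strength_scale_factor)
from mskwarp.synthetic import make_fixture_model

male = AnthropometrySpec(mass=76.43, body_height=1.84)
female = AnthropometrySpec(mass=59.53, body_height=1.64)
print(f"predicted volume, male mean anthropometry:   {handsfield_volume(male):8.1f} cm^3")
print(f"predicted volume, female mean anthropometry: {handsfield_volume(female):8.1f} cm^3")

spec = MuscleStrengthSpec("vastus_lateralis", V_generic=500.0, V_scaled=600.0,
                          l_optimal_generic=0.08, l_optimal_scaled=0.084,
                          F_max=2500.0)
k = strength_scale_factor(spec)
print(f"example factor (volume ratio 1.2, fiber-length ratio 1.05): {k:.4f}")
print(f"scaled maximum isometric force: {k * spec.F_max:.0f} N")

model = make_fixture_model()
generic_anthro = AnthropometrySpec(75.0, 1.80)
scaled = apply_strength_scaling(model, male, generic_anthro)
f0 = model.strength["psoas"].max_isometric_force
f1 = scaled.strength["psoas"].max_isometric_force
print(f"psoas F_max: {f0:.0f} N -> {f1:.0f} N "
      f"(volume ratio {handsfield_volume(male) / handsfield_volume(generic_anthro):.3f})")
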