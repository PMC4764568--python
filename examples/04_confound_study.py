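"""The stimulus-correlation confound under passive whisker deflection.

When angle and curvature change are correlated at ~0.96 (as they are when
an anaesthetised animal's whisker is driven by an actuator), a neuron
tuned *purely* to curvature can be predicted almost as well from whisker
angle — apparent angle tuning without any angle sensitivity.  This script
runs the simulation at the study conditions and at zero coupling, where
the confound disappears.
"""

from whiskerglm import confound_study, generate_session

res = confound_study(duration_s=60.0, seed=1)
print("emulated passive white noise (angle-curvature correlation ~0.96):")
print(res.report())

decoupled = generate_session("passive_whitenoise", 20, {"corr_target": 0.0}, seed=2)
res0 = confound_study(session=decoupled, seed=3)
print("\nsame simulation with the coupling removed (correlation 0):")
print(res0.report())

print("\nWith coupling, the angle GLM predicts a curvature-driven unit almost")
print("as well as the curvature GLM (~0.86 vs ~0.94); without coupling the")
print("angle GLM collapses to chance while the curvature GLM is unaffected.")
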