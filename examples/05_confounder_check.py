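"""Guard an interaction set against hidden common causes.

When physicians assign a therapy based on a variable that also drives
the outcome (here: disease burden), a naive treatment-outcome contrast
is confounded.  The check hill-climbs a BDeu-scored network with the
candidate set's edges forced, then tests every variable connected to
both treatment and outcome for conditional independence given the set.
"""

from dpac import confounder_check, generate, preset_confounded, preset_unconfounded

for name, preset in [("unconfounded", preset_unconfounded),
                     ("confounded", preset_confounded)]:
    data, _ = generate(preset(4000), seed=0)
    report = confounder_check(data, "therapy", ("modifier",), "metastasis")
    print(f"{name} cohort, S=(modifier,): passed={report.passed} "
          f"flagged={report.flagged_common_causes}")

data, _ = generate(preset_confounded(4000), seed=0)
report = confounder_check(
    data, "therapy", ("modifier", "burden"), "metastasis"
)
print(f"confounded cohort, S=(modifier, burden): passed={report.passed}")
print("(adding the common cause to the conditioning set restores validity)")
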