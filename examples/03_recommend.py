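"""Per-patient treatment recommendation by expected utility.

Learns a decision-support system from synthetic data (interaction
screening + noisy-OR fit), then recommends the therapy decision for two
patient profiles — first valuing only the outcome, then charging the
therapy a standard-gamble disutility.
"""

from dpac import (
    PipelineConfig,
    UtilitySpec,
    fit_pipeline,
    generate,
    preset_beneficial,
    standard_gamble_disutility,
    to_influence_diagram,
)

data, _ = generate(preset_beneficial(20_000), seed=0)
config = PipelineConfig(
    features=("marker", "node_status", "f3", "f4", "f5"),
    treatments=("therapy",),
    target="metastasis",
    adverse_state="yes",
)
diagram = fit_pipeline(data, config, seed=0)
print("selected interaction groups:",
      [g.parents for g in diagram.model.groups])

profiles = {
    "marker-positive": {"marker": "pos"},
    "marker-negative": {"marker": "neg"},
}
defaults = {"node_status": "neg", "f3": "a", "f4": "a", "f5": "a"}
for name, profile in profiles.items():
    features = {c: profile.get(c, defaults.get(c, "neg"))
                for c in diagram.chance_nodes}
    rec = diagram.recommend(features)
    print(f"\npatient {name}: recommend therapy={rec.decisions['therapy']}")
    print(f"  expected utility {rec.expected_utility:.3f}; adverse risk "
          f"{rec.p_adverse_chosen:.3f} (untreated: "
          f"{rec.p_adverse_status_quo:.3f})")

# a patient indifferent at p = 0.9 values therapy at a 0.1 utility cost
x = standard_gamble_disutility(0.9)
print(f"\nstandard-gamble disutility at indifference p=0.9: x = {x:.1f}")
costed = to_influence_diagram(
    diagram.model, ("therapy",),
    UtilitySpec(treatment_disutilities={"therapy": x}),
)
for name, profile in profiles.items():
    features = {c: profile.get(c, defaults.get(c, "neg"))
                for c in costed.chance_nodes}
    rec = costed.recommend(features)
    print(f"patient {name} with disutility {x:.1f}: "
          f"therapy={rec.decisions['therapy']} "
          f"(EU {rec.expected_utility:.3f})")
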