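"""Classify single patients with the Schroth decision rules.

Builds one postural observation per patient, runs the rule engine and
prints the assigned curve type together with the branch-by-branch
decision trace.
"""

from schroth_agree import PosturalObservation, classify

patients = {
    "displaced pelvis, lumbar follows it": PosturalObservation(
        pelvis_balanced=False,
        pelvis_lumbar_coupled=True,
        prominent_hip=True,
        thoracic_dominant=False,
    ),
    "displaced pelvis, lumbar opposes it": PosturalObservation(
        pelvis_balanced=False,
        pelvis_lumbar_coupled=False,
        prominent_hip=True,
        thoracic_dominant=True,
    ),
    "balanced pelvis, rib hump dominates": PosturalObservation(
        pelvis_balanced=True,
        pelvis_lumbar_coupled=False,
        prominent_hip=False,
        thoracic_dominant=True,
    ),
    "balanced pelvis, lumbar prominence dominates": PosturalObservation(
        pelvis_balanced=True,
        pelvis_lumbar_coupled=True,
        prominent_hip=False,
        thoracic_dominant=False,
    ),
}

for description, obs in patients.items():
    curve_type, trace = classify(obs)
    print(f"{description}: {curve_type}")
    print(f"  trace: {trace.serialize()}")

print(
    "\nThe label pairs 3cp/4cp occur only with a displaced pelvis "
    "(coupling decides between them); with a balanced pelvis the "
    "thoracic-vs-lumbar prominence comparison decides 3c vs 4c."
)
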