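"""Full reliability analysis of a simulated two-occasion rating study.

Simulates the default study conditions (44 subjects with prevalence
9/12/6/17 over 3c/3cp/4c/4cp, ten raters in three accuracy tiers, two
occasions, occasional missing ratings) and runs the complete pipeline:
per-rater test-retest coefficients, Fisher-pooled subgroup means and
multi-rater inter-rater coefficients, each unweighted and with the
clinical partial-credit weights.
"""

from schroth_agree import default_config, run_pipeline, simulate_study
from schroth_agree.simulate import default_groups

config = default_config(seed=7)
truth, occasion1, occasion2 = simulate_study(config)
report = run_pipeline(occasion1, occasion2, rater_groups=default_groups())

print(report.to_text())
print(
    "\nWeighted coefficients exceed their unweighted counterparts because "
    "most disagreements fall on clinically similar category pairs; the "
    "experienced tier (accuracy 0.90) outperforms the well-trained tier "
    "(0.75), which outperforms the full panel."
)
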