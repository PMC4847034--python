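"""Accuracy stratified by prediction confidence.

Pooled CV predictions are placed into 20 even bins of the confidence
score |p - 0.5| / 0.5.  A well-behaved consensus model is much more
accurate at high confidence, which is what makes the score usable as an
applicability guide for screening decisions.
"""

from qsarforest import (
    CVConfig,
    ForestFitConfig,
    SyntheticSpec,
    confidence_profile,
    cross_validate,
    generate,
)

dataset, _ = generate(SyntheticSpec(seed=7))
run = cross_validate(dataset, ForestFitConfig(), CVConfig(n_repeats=10, seed=3))

table = confidence_profile(run).table
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

populated = table.dropna(subset=["accuracy"])
low = populated[populated["bin"] <= 10]["accuracy"].mean()
high = populated[populated["bin"] > 10]["accuracy"].mean()
print(f"\nmean accuracy, lower confidence half: {low:.3f}; upper half: {high:.3f}")
# predictions in the top confidence bins approach perfect accuracy while
# the bins near the decision boundary are close to coin flips
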