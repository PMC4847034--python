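"""Fit a consensus forest and predict new chemicals.

Generates a synthetic descriptor table shaped like a real training set
(125 chemicals x 777 raw descriptors, 53 binders), preprocesses it
(constant-descriptor removal, min-max scaling), fits the five-tree
consensus and predicts a fresh 22-chemical external set drawn from the
same generative law.
"""

import numpy as np

from qsarforest import (
    Dataset,
    ForestFitConfig,
    SyntheticSpec,
    apply_minmax_scaling,
    fit_forest,
    fit_minmax_scaling,
    forest_predict,
    generate,
    make_external_set,
    remove_constant_descriptors,
)

spec = SyntheticSpec(seed=42)
train, _ = generate(spec)

reduced, removed = remove_constant_descriptors(train.descriptors)
params = fit_minmax_scaling(reduced)
scaled = Dataset(apply_minmax_scaling(reduced, params), train.labels)
print(f"{len(removed)} constant descriptors removed, {reduced.n_descriptors} kept")

forest = fit_forest(scaled, ForestFitConfig())
print(f"forest: {len(forest.trees)} trees, descriptors per tree:",
      [len(s) for s in forest.used_descriptors_per_tree])

external, truth = make_external_set(spec, 22, seed2=1)
ext_scaled = apply_minmax_scaling(
    external.descriptors.take_columns(reduced.descriptor_names), params
)
preds = forest_predict(forest, ext_scaled)

correct = sum(p.call == a for p, a in zip(preds, external.labels.labels))
print(f"external accuracy: {correct}/{len(preds)}")
print("first five predictions (p = consensus binder probability,")
print("confidence = |p - 0.5| / 0.5, the distance from the decision boundary):")
for p in preds[:5]:
    print(f"  {p.chemical_id}: p={p.p:.2f} call={p.call} confidence={p.confidence:.2f}")
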