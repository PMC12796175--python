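"""Explain a CNN prediction with additive pixel attributions.

Computes expected-gradients attributions against a training background
set, checks the additivity identity, and writes the three-panel
comparison figure (raw map / SPM clusters / attribution heatmap).
"""
import numpy as np

from plantarqc.cnn import PlantarCNN, TrainConfig, dataset_arrays, train
from plantarqc.explain import compute_attribution, render_triptych
from plantarqc.spm import SPMDecision
from plantarqc.synth import generate_dataset
from plantarqc.types import Side

ds = generate_dataset(n_subjects=30, valid_per_subject=4, target=40, seed=5)
grids, sides, labels = dataset_arrays(ds)
mean, sd = grids.mean(), grids.std()

model = PlantarCNN(seed=0)
train(model, ((grids - mean) / sd, sides, labels),
      ((grids - mean) / sd, sides, labels),
      TrainConfig(seed=0, max_epochs=6, samples_per_epoch=512))

i = int(np.flatnonzero(labels == 2)[0])        # a double-foot composite
sample = ds.sample(i)
attr = compute_attribution(model, grids[i], sample.side,
                           grids[labels == 0][:20], sides[labels == 0][:20],
                           fold_stats=(mean, sd), n_steps=32,
                           sample_id=sample.sample_id)
print(f"explained class {attr.target_class} "
      f"(model output {attr.model_output:.2f}, "
      f"background expectation {attr.baseline_expectation:.2f})")
print(f"additivity gap: {attr.additivity_gap * 100:.2f}% "
      "(attributions sum to the output difference)")

decision = SPMDecision(pmap=np.ones((64, 64)), clusters=[], fwe_threshold=0,
                       significant=[], is_outlier=False)
path = render_triptych(sample, decision, attr, "triptych.png")
print(f"wrote {path}: left=raw map, middle=SPM clusters (none here), "
      "right=blue/red attribution overlay")
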