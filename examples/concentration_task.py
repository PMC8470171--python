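"""At which dose was a culture exposed? The per-contaminant concentration task.

Each contaminant defines its own subtask: the classes are its dose levels
(30 replicates each, control included) and every sample is min-max
normalized so only curve shape carries information. Here: diclofenac,
doses 0 / 0.8 / 3 / 40 / 100 / 300 ug/L.
"""

import numpy as np

from ojiptox.evaluation import TaskDefinition, run_experiment, select_median_model
from ojiptox.models.base import ModelSpec
from ojiptox.simulate import generate_dataset, well_separated_config

dataset = generate_dataset(well_separated_config(master_seed=1))
task = TaskDefinition(kind="concentration", ec_filter="dcf")

runs = run_experiment(
    dataset, task,
    ModelSpec(family="rocket", hyperparameters={"n_kernels": 500}),
    n_runs=5, base_seed=1,
)

median = select_median_model(runs)
print("diclofenac concentration subtask (6 classes x 30 samples):")
for r in runs:
    print(f"  run {r.run_index}: train {r.train_accuracy:.3f}  test {r.test_accuracy:.3f}")
print(f"median-run test accuracy: {median.test_accuracy:.3f} (chance 1/6 = 0.167)")
print("per-dose accuracy of the median run:")
for dose, acc in sorted(median.per_class.items(), key=lambda kv: float(kv[0])):
    print(f"  {float(dose):>6.1f} ug/L: {acc:.2f}")
print("adjacent doses with similar Hill effects are the usual confusions")
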