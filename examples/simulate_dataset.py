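"""Generate the 13-contaminant synthetic exposure dataset and save it as CSV.

The design mirrors a real diatom exposure trial: 13 emerging contaminants,
each with its dose list (control included), 30 replicate transients per
dose, 458 fluorescence readings at 10 ms spacing per transient.
"""

from ojiptox.simulate import DatasetConfig, generate_dataset, table1_profiles
from ojiptox.io import write_curve_table

config = DatasetConfig(profiles=table1_profiles(), master_seed=1)
dataset = generate_dataset(config)
write_curve_table(dataset, "optox_synthetic.csv")

sizes = dataset.meta.groupby("ec_label").size().sort_index()
print(f"samples: {len(dataset)}  (expected 1950)")
print(f"points per curve: {dataset.values.shape[1]} at {dataset.time.dt * 1000:.0f} ms")
print("samples per contaminant:")
print(sizes.to_string())
# Each contaminant class pools all its doses: 4 doses -> 120 samples,
# 5 -> 150 (SDS), 6 -> 180, matching the emulated exposure-trial design.
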