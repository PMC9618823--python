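"""Generate a synthetic perturbation time course with planted modules.

The generator emulates a single-subject paired design: one treated and one
untreated expression series over hourly timepoints. Module genes share an
activation pulse only under treatment; everything else is background.
"""

from dnet import SimulationConfig, generate_dataset

config = SimulationConfig(
    n_genes=500,
    n_timepoints=24,
    n_modules=3,
    module_sizes=[20, 20, 20],
    activation_times=[4, 12, 20],
    seed=1,
)
treated, untreated, truth = generate_dataset(config)

print(f"treated matrix: {treated[0].shape[0]} genes x {treated[0].shape[1]} timepoints")
print(f"planted modules: {len(truth.module_genes())}, "
      f"activation times {truth.activation_time}")
print(f"rewired gene pairs expected in the differential network: "
      f"{len(truth.rewired_edges)}")
print(f"missing entries in treated replicate: {int(treated[0].isna().sum().sum())}")
# Each module contributes C(size, 2) treated-only co-expression pairs; the
# missing entries and constant genes exercise the QC stage downstream.
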