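"""Run the four-step preprocessing chain and show what each stage does.

Order: cosmic-ray removal -> asymmetric-least-squares baseline ->
Gaussian smoothing -> per-spectrum min-max scaling to [0, 1].
"""

import numpy as np

from sersdx import (NoiseModel, CohortPlan, binary_signatures,
                    simulate_cohort)
from sersdx.preprocess import PreprocessConfig, preprocess_pipeline

plan = CohortPlan(binary_signatures(), samples_per_class=3,
                  spectra_per_sample=10,
                  noise=NoiseModel(spike_rate=0.5), seed=42)
raw = simulate_cohort(plan)

clean = preprocess_pipeline(raw, PreprocessConfig())

n_spikes = int(raw.meta["spike_channels"].map(len).sum())
print(f"planted cosmic-ray spikes: {n_spikes}")
print(f"raw intensity range:       [{raw.intensities.min():.3f}, "
      f"{raw.intensities.max():.3f}] a.u.")
print(f"processed range:           [{clean.intensities.min():.3f}, "
      f"{clean.intensities.max():.3f}]  (min-max scaled per spectrum)")

k = raw.grid.index_of(1080.0)
cancer = (raw.meta["class_label"] == "cancer").to_numpy()
diff = (clean.intensities[cancer, k].mean()
        - clean.intensities[~cancer, k].mean())
print(f"1080 cm^-1 group contrast after preprocessing: {diff:+.4f}")
print("(positive: the planted dATP-band elevation in cancer survives "
      "the chain)")
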