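"""Simulate a labeled SERS serum-exosome cohort and write it to CSV.

Each sample contributes a bundle of spectra; cancer classes carry the
pan-cancer marker offsets (+ at 1080 cm^-1, - at 1380 cm^-1) on top of a
shared band set, under baseline drift, shot noise, amplitude jitter and
cosmic-ray spikes.
"""

from sersdx import default_binary_plan, simulate_cohort, write_cohort

plan = default_binary_plan(samples_per_class=6, spectra_per_sample=10,
                           seed=42)
cohort = simulate_cohort(plan)
write_cohort(cohort, "scratch_example_cohort.csv")

print(f"classes:            {cohort.classes}")
print(f"samples:            {cohort.n_samples}")
print(f"spectra:            {cohort.n_spectra}")
print(f"channels:           {len(cohort.grid)} "
      f"({cohort.grid.values[0]:.0f}-{cohort.grid.values[-1]:.0f} cm^-1)")
print(f"planted offsets:    {cohort.attrs['planted_deltas']['cancer']} "
      "(a.u. at 1080 / 1380 cm^-1)")
n_spikes = int(cohort.meta["spike_channels"].map(len).sum())
print(f"cosmic-ray spikes:  {n_spikes} across the cohort")
# The CSV (plus *_truth.csv ground-truth sidecar) round-trips through
# sersdx.read_spectra.
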