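"""Synthetic accuracy benchmark: pairing accuracy vs z-scaling deformation.

Reproduces one slice of the benchmark grid: 50 objects in a
200 x 150 x 100 um box, the second image z-scaled and randomly rotated,
registration from 3 or 9 landmarks, 4 replicates per condition.
"""

from lmreg3d import Scenario, run_benchmark

scenarios = [
    Scenario(z_scale=z, n_landmarks=k, n_replicates=4, seed=1000 + 10 * k + z)
    for z in (80, 100, 120)
    for k in (3, 9)
]
df = run_benchmark(scenarios)
print(df[["z_scale", "n_landmarks", "mean_accuracy"]].to_string(index=False))
print("\n(mean % of objects paired back to their true counterpart over 4"
      " replicates: 100% with no deformation, and more landmarks buffer"
      " the rigid fit against the non-rigid z-scaling)")
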