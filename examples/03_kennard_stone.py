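"""Kennard-Stone 70/30 partitioning and the split-size arithmetic.

Train sizes are round-half-up of 0.7*n, which reproduces 790/760/799 for
datasets of 1128/1085/1141 leaves; the selector itself is deterministic
max-min distance sampling, so extremes land in the training set.
"""
import numpy as np

import nirleaf as nl

for n in (1128, 1085, 1141):
    k = nl.train_size(n, 0.7)
    print(f"n={n}: train {k}, test {n - k}")

X = np.array([[0.0], [1.0], [2.0], [9.0]])
split = nl.split_dataset(X, 0.5)
print(f"collinear points {X.ravel().tolist()} at 50%: "
      f"train rows {sorted(split.train_indices.tolist())} (the two extremes)")

data = nl.easy_benchmark(seed=0, n_per_class=8)
Xp = nl.default_pipeline(step_nm=data.grid.step_nm).fit_transform(data.mean_spectra())
split = nl.split_dataset(Xp, 0.7)
print(f"benchmark ({len(data)} leaves): train {len(split.train_indices)}, "
      f"test {len(split.test_indices)}; split is identical on every rerun")
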