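"""The 1D CNN: symbolic shapes, then a short training run.

The two-stage architecture takes the 454-point derivative spectrum through
conv(128)+pool and conv(64)+pool stages into a 14144-wide flatten, a
100-unit dense layer and a 5-way softmax.
"""
import nirleaf as nl

arch = nl.default_architecture(kernel_size=5)
print("layer shapes (length x channels):")
for name, shape in nl.cnn_output_shapes(arch):
    print(f"  {name:8s} {shape}")

bench = nl.easy_benchmark(seed=1)
X = nl.default_pipeline(step_nm=bench.grid.step_nm).fit_transform(bench.mean_spectra())
y = bench.labels()
split = nl.split_dataset(X, 0.7)
model = nl.CNNClassifier(arch, nl.TrainConfig(epochs=8, batch_size=64, seed=0))
model.fit(X[split.train_indices], y[split.train_indices])
print(f"loss: {model.loss_history[0]:.3f} (epoch 1) -> "
      f"{model.loss_history[-1]:.3f} (epoch {len(model.loss_history)})")
print(f"training NER = {model.score_ner(X[split.train_indices], y[split.train_indices]):.2f} %")
print(f"testing NER  = {model.score_ner(X[split.test_indices], y[split.test_indices]):.2f} %")
# Eight epochs suffice on this separable benchmark; the production default
# is 300 epochs at batch 64.
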