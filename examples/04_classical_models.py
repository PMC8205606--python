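"""Train the four classical classifiers on the synthetic benchmark.

Pipeline: replicate mean -> SG first derivative (window 59, valid) ->
min-max -> Kennard-Stone 70/30 -> fit -> testing NER (percent correct).
"""
import nirleaf as nl

bench = nl.easy_benchmark(seed=1)
X = nl.default_pipeline(step_nm=bench.grid.step_nm).fit_transform(bench.mean_spectra())
y = bench.labels()
split = nl.split_dataset(X, 0.7)
Xtr, ytr = X[split.train_indices], y[split.train_indices]
Xte, yte = X[split.test_indices], y[split.test_indices]
print(f"{len(ytr)} training / {len(yte)} testing leaves, {X.shape[1]} features")

models = {
    "KNN (k=5, inverse-distance)": nl.KNNClassifier(nl.KNNConfig(k=5)),
    "SVM (RBF, C=32, gamma=2^-5)": nl.SVMClassifier(nl.SVMConfig()),
    "ELM (150 hidden)": nl.ELMClassifier(nl.ELMConfig(n_hidden=150, seed=0)),
    "BPNN (20 hidden)": nl.BPNNClassifier(
        nl.BPNNConfig(n_hidden=20, learning_rate=0.5, epochs=2000, seed=0)),
}
for name, model in models.items():
    model.fit(Xtr, ytr)
    print(f"{name:30s} testing NER = {model.score_ner(Xte, yte):6.2f} %")
# NER is the percentage of held-out leaves whose maturity level is predicted
# exactly; the benchmark is designed to be separable, so values near 100
# confirm each implementation rather than estimate field performance.
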