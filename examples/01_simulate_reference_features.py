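"""Draw a balanced simulated feature set from the published class statistics.

Real arrhythmia corpora are heavily unbalanced (normal rhythm dominates), so
a balanced training set is synthesized by drawing each of the six centroid
features from its published per-class normal distribution.  The printed table
compares the sample means of the draw with the generating means: agreement to
the second decimal shows the generator is faithful; the remaining gap is pure
sampling noise.
"""

import numpy as np

import hhtecg as hg

model = hg.reference_feature_model()
records = hg.simulate_features(model, n_per_symptom=1000, seed=7)
X, y = hg.feature_matrix(records)

print(f"simulated {len(records)} records ({len(records) // 5} per class)\n")
print("class  IMF1 freq (sim / model)   IMF1 power (sim / model)")
for symptom in hg.SYMPTOM_IDS:
    sub = X[y == symptom]
    mu_f = model.params[symptom]["f1_freq"][0]
    mu_p = model.params[symptom]["f1_pow"][0]
    print(
        f"{hg.SYMPTOM_NAMES[symptom]:>5}  "
        f"{sub[:, 0].mean():.3f} / {mu_f:.3f} Hz          "
        f"{sub[:, 1].mean():.3f} / {mu_p:.3f}"
    )

print("\nNormal rhythm shows the highest IMF1 frequency and the lowest power;")
print("ventricular tachycardia the opposite — the separation the bank exploits.")
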