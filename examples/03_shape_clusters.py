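"""Select the number of body-shape clusters with Calinski-Harabasz.

Trunk curves are clustered with K-means for k = 2..10 and the k with the
highest Calinski-Harabasz score wins; subjects are then one-hot encoded
by nearest centroid (the BS_PHOTO feature).
"""

import numpy as np

from photobf.shape import ShapeCurves, encode_shape, fit_shape_clusters

rng = np.random.default_rng(0)
k_true = 3
centers = 30.0 + np.arange(k_true)[:, None] * 8.0  # three trunk-width archetypes
X = np.vstack([rng.normal(c, 0.8, size=(25, 12)) for c in centers])
curves = [ShapeCurves(fc=x, sc=x - 25.0, trunk_span=(0, 100)) for x in X]

model = fit_shape_clusters(curves, seed=0)
print(f"planted k = {k_true}, selected k_fc = {model.k_fc}, k_sc = {model.k_sc}")
print("Calinski-Harabasz trace (FC):")
for k, score in model.fc.criterion_scores.items():
    marker = " <- chosen" if k == model.k_fc else ""
    print(f"  k={k}: {score:10.1f}{marker}")
enc = encode_shape(curves[0], model)
print("subject 0 one-hot FC encoding:", enc.fc_onehot.astype(int))
print("A single 1 marks the shape cluster this trunk belongs to.")
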