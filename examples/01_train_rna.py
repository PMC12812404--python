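"""Train the dual-pathway VAE on synthetic scRNA-seq counts and check how
well the latent space recovers the simulated cell types.

Builds a hierarchically clustered negative-binomial count matrix, runs the
RNA preprocessing (HVG selection, log1p/z-score/clip), fits the model with
default hyperparameters, and scores the posterior-mean latent with k-means
against the ground-truth labels.
"""

import lorentzvae as lv
from lorentzvae.metrics import clustering_metrics
from lorentzvae.synthetic import SyntheticSpec, generate_rna, zero_fraction

X, truth = generate_rna(SyntheticSpec(n_cells=1000, n_features=300,
                                      n_clusters=6, hierarchy_depth=3,
                                      de_strength=1.2, seed=0))
print(f"counts: {X.n_cells} cells x {X.n_features} genes, "
      f"{zero_fraction(X):.0%} zeros")

ds = lv.preprocess(X)
model, trace = lv.fit(ds, config=lv.ModelConfig(seed=0, epochs=100,
                                                early_stopping=False))
print(f"total loss: {trace['total'].iloc[0]:.1f} -> "
      f"{trace['total'].iloc[-1]:.1f} over {len(trace)} epochs")

Z = model.embed(ds)            # posterior means, cells x 10
scores = clustering_metrics(Z, truth.labels, seed=0)
print(f"ARI {scores['ari']:.3f}  NMI {scores['nmi']:.3f}  "
      f"ASW {scores['asw']:.3f}")
# ARI/NMI near 1 mean k-means on the latent reproduces the simulated
# cluster labels; ASW > 0 means the types are geometrically separated.
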