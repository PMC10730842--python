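"""Connectivity gradients of one preprocessed run.

Runs the chain Pearson connectivity -> Fisher z -> top-10%-per-row
sparsification -> normalized-angle affinity -> diffusion-map embedding
(alpha = 0.5, automated diffusion time), aligns to the study template, and
summarizes the principal gradient per network.  The network means are
ordered along the unimodal -> transmodal hierarchy.
"""
import numpy as np

from gradcap import ConnectivityMatrix, EffectConfig, NETWORKS, make_parcellation, simulate_run
from gradcap.gradients import (
    gradients_from_connectivity, gradients_from_run, network_summary,
    procrustes_align,
)
from gradcap.preprocess import preprocess_run
from gradcap.synth import make_ground_truth, model_covariance

parc = make_parcellation(350, seed=0)
truth = make_ground_truth(parc, EffectConfig(), seed=1)
run, motion, _ = simulate_run(parc, truth, n_frames=180, seed=3)
clean, _ = preprocess_run(run, motion)

g = gradients_from_run(clean)
print(f"{g.n_components} components; leading eigenvalues "
      f"{np.round(g.eigenvalues[:3], 4)}")

# align to the noise-free model template (the study's external reference)
cov = model_covariance(parc, truth)
d = np.sqrt(np.diag(cov))
template = gradients_from_connectivity(
    ConnectivityMatrix(values=cov / np.outer(d, d), n_frames_used=0))
if np.corrcoef(template.loadings[:, 0], parc.hierarchy_position)[0, 1] < 0:
    template.loadings[:] = -template.loadings
aligned = procrustes_align(g, template)

summary = network_summary(aligned, parc, component=0)
print("\nprincipal-gradient network means (unimodal -> transmodal):")
for net in NETWORKS:
    print(f"  {net}: {summary[net]:+.4f}")
print(f"overall range (max - min over nodes): {summary['range']:.4f}")
print("\nthe means increase from VIS to DMN: the planted hierarchy is the "
      "principal axis of connectivity similarity")
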