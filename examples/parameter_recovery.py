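"""Recovering known generative parameters with truncated EM.

Builds a bars dictionary (10 non-negative fields on a 5x5 grid), samples
2000 observations from the max-superposition generative model with
Bernoulli(0.2) activations and Gaussian noise sigma=0.05, then fits MCA with
Expectation Truncation (H'=8 candidates, at most gamma=4 simultaneously
active) and 40 EM iterations.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from maxcause import em, mca, synth

gt = synth.make_ground_truth_fields("bars", (5, 5), 10, seed=0, pi=0.2, sigma=0.05)
Y, _ = synth.sample_mca_dataset(gt, 2000, seed=1)
cfg = em.ETConfig(H_prime=8, gamma=4, n_iterations=40, seed=0)
params, monitor = mca.fit_mca(Y, 10, cfg)

A = gt.fields / np.linalg.norm(gt.fields, axis=0, keepdims=True)
B = params.W / np.linalg.norm(params.W, axis=0, keepdims=True)
C = A.T @ B
r, c = linear_sum_assignment(-C)

print(f"mean cosine similarity (best matching): {C[r, c].mean():.4f}")
print(f"recovered pi    = {params.pi:.4f}   (true 0.2)")
print(f"recovered sigma = {params.sigma:.4f}   (true 0.05)")
print(f"free energy: first {monitor['free_energy'][0]:.1f} -> last {monitor['free_energy'][-1]:.1f}")
print(
    "\nCosine near 1 means each learned field matches a ground-truth bar up to\n"
    "column permutation; pi and sigma recover the sparsity and noise level."
)
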