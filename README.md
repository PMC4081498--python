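# fastfc

Fast voxel-level functional-connectivity graphs from fMRI-like time
series, built on the closed-form **tetrachoric correlation** of
median-dichotomized signals.

## The problem

Voxel-level connectivity graphs treat every gray-matter voxel as a node,
which preserves the data's native spatial resolution but requires
V(V−1)/2 pairwise correlations — billions of pairs at typical V. This
package implements the estimator that makes this cheap, alongside the
conventional Pearson baseline, and the downstream graph pipeline
(density thresholding, degree maps, group averaging) plus the simulation
study that validates the estimator. It is aimed at researchers analyzing
resting-state fMRI connectivity at high resolution and at anyone needing
fast, exact binary-similarity correlation at scale.

## The core idea

Dichotomize each time series at its own median: d_v,k = 1 iff
s_v,k ≥ median(s_v). With both marginals of the resulting 2×2 table fixed
at 1/2, the tetrachoric correlation — normally found by numerical
integration — has the closed form

    r_t = −cos(2π · n11 / T)

where n11 counts time points at which both series are 1. Binary series
are bit-packed into machine words, so each pair costs ⌈T/64⌉ AND +
popcount operations and one table lookup; the cosine is never evaluated
per pair. Graphs are built by keeping the top round(κ·V(V−1)/2)
correlations (density κ fixed across subjects), and node degree
k_i = Σ_j b_ij, z-scored per subject, maps hub structure.

## Worked example

```python
import numpy as np
import fastfc as f

# synthetic dataset: 200 voxels, T=275, one planted 20-voxel cluster (rho=0.7)
spec = f.PlantedStructureSpec(V=200, T=275, clusters=((20, 0.7),), seed=0)
ts, labels = f.make_timeseries(spec)

# tetrachoric pipeline: dichotomize -> pack -> AND/popcount/lookup
bits, flags = f.dichotomize_matrix(ts.data)
C_t = f.tetrachoric_matrix(f.pack(bits, word_width=64, degenerate=flags))

# Pearson baseline on the same data
C_r = f.pearson_matrix(ts.data)

# density-thresholded graphs and degrees
theta_t, G_t = f.density_threshold(C_t, kappa=0.01)
theta_r, G_r = f.density_threshold(C_r, kappa=0.01)
k_t, k_r = f.degree(G_t).k, f.degree(G_r).k
print(f"theta_rt={theta_t:.3f}  theta_r={theta_r:.3f}  edges={G_t.n_edges}")
print(f"degree corr(k_r, k_rt) = {np.corrcoef(k_r, k_t)[0,1]:.3f}")
print(f"top-degree nodes in cluster: "
      f"{np.isin(np.argsort(-k_t)[:20], np.where(labels == 0)[0]).mean():.0%}")
```

prints

```
theta_rt=0.320  theta_r=0.200  edges=199
degree corr(k_r, k_rt) = 0.997
top-degree nodes in cluster: 100%
```

The 199-edge budget slightly exceeds the cluster's 190 internal pairs, so
both graphs absorb the whole planted cluster and the realized thresholds
drop to the strongest background correlations. The cluster's 20 voxels
are exactly the top-degree nodes in both graphs, and the two degree
profiles agree to r=0.997 — the tetrachoric graph recovers the same hub
structure as the Pearson graph.

The estimator-validation study runs the same comparison on pure
bivariate-normal samples over a grid of 199 population correlations:

```python
res = f.run_study(T=100, n_reps=10000, seed=1)
print(res.grid_correlations())  # corr(r, rho), corr(r_t, rho), corr(r_t, r)
print(res.bin_stats(0.0, "r")["sd"], res.bin_stats(0.0, "r_t")["sd"])
```

At T=100 the estimates correlate ≈0.99 with the truth and with each
other; at ρ=0 the sampling SDs are ≈0.101 (r) and ≈0.157 (r_t) — the
dichotomized estimator is noisier by roughly a factor π/2 but tracks r
faithfully.

The same workflow is available from the shell:

```bash
fastfc synth -V 200 -T 275 --cluster 20:0.7 --grid 8,8,8 --seed 0 --out-dir data/
fastfc corr --functional data/functional.nii.gz --gm-map data/gm_map.nii.gz \
            --method tetrachoric --out data/tri
fastfc graph --triangle data/tri --density 0.01 --out data/edges.tsv
fastfc degree --edges data/edges.tsv --nodes 200 --out data/degrees.tsv
fastfc sim -T 100 --reps 10000 --seed 1 --out-dir data/sim/
```

See `docs/methods.md` for the model, parameter meanings and limitations.

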