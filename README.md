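# connvar

Multi-scale resting-state fMRI metrics and their longitudinal variance
decomposition on surface meshes.

## What this package is for

Test–retest studies of the functional connectome ask two questions about any
rfMRI-derived metric: how much does it fluctuate within a person from session
to session (intra-individual variability, σ²w), and how much does it differ
between people (inter-individual variability, σ²b)?  Their ratio

    ICC = σ²b / (σ²b + σ²w)

is the intraclass correlation — the test–retest reliability that bounds a
metric's usefulness as a biomarker.  `connvar` implements, for a balanced
longitudinal design (by default 30 subjects × 10 sessions, 300 volumes at
Δt = 2 s), the full chain from vertex-wise BOLD time series to vertex-wise
variance components for eight standard metrics at three spatial scales:

- **local** — ALFF (summed Fourier amplitude over Ω = [0.01, 0.1] Hz divided
  by T/2), fALFF (its fraction of the full-spectrum amplitude), and ReHo1 /
  ReHo2 (Kendall's coefficient of concordance W over one-ring / two-ring mesh
  neighborhoods);
- **meso** — seed-based Fisher-z connectivity (SFC) and dual-regression (DR)
  network maps from group templates, plus the between-network interplay
  matrix;
- **global** — weighted degree (DCw) and eigenvector (ECw) centrality of the
  vertex-level connectome, A = arctanh(ρ(vi, vj)), thresholded at 5% edge
  density.

Variance components are estimated per vertex (and for each metric's global
mean) with a covariate-adjusted random-intercept linear mixed model fitted by
restricted maximum likelihood:

    gM_ij   = μ00 + γ0j + age_j + sex_j + motion_ij + ε_ij                 (global)
    M_ij(v) = μ00(v) + gM_ij + γ0j(v) + age_j + sex_j + motion_ij
              + mcBBR_ij + Jacobian_j(v) + ε_ij(v)                         (vertex)

with γ0j ~ N(0, σ²b), ε ~ N(0, σ²w) (compound-symmetric within-subject
covariance).  ICC values are banded slight / fair / moderate / substantial /
almost-perfect and summarized per network label (mean and percentage ≥ 0.4).

Because the real repeated-measures dataset is not required, a synthetic
cohort generator produces surface meshes (icospheres standing in for the
fsaverage5 grid), contiguous network atlases, and band-limited BOLD cohorts
with *known* per-vertex σ²b, σ²w — so the entire pipeline is testable against
ground truth.

## Worked example

```python
import numpy as np
import connvar as cv

mesh = cv.build_icosphere(2)                       # 162 vertices
sigma_b, sigma_w = cv.icc_gradient(mesh, 0.1, 0.9) # true ICC gradient
config = cv.PipelineConfig(
    cohort=cv.CohortConfig(n_subjects=30, n_sessions=10,
                           sigma_b=sigma_b, sigma_w=sigma_w, seed=0),
    metrics=("ALFF",), model_levels=("vertex",))
result = cv.run_pipeline(config, stages=("simulate", "preprocess",
                                         "metrics", "model"))

icc_hat = np.array([result.vertex_fits["ALFF"][v].icc
                    for v in range(mesh.vertex_count)])
truth = result.cohort.truth.icc
print(f"MAE  = {np.abs(icc_hat - truth).mean():.4f}")
print(f"r    = {np.corrcoef(icc_hat, truth)[0, 1]:.4f}")
```

Output (seed 0):

```
MAE  = 0.0572
r    = 0.9584
```

The estimated vertex-wise ICC tracks the simulated truth with r ≈ 0.96; the
mean absolute error of ≈ 0.057 is dominated by the sampling variance of a
variance-ratio estimated from 30 subjects (see `docs/methods.md` for the
error budget).  A full eight-metric run is one call:

```bash
connvar run-all --seed 0 --out results/run0
```

which writes per-metric value matrices (`metric_*.tsv`), per-vertex and
global decomposition tables (`model_*_vertex.tsv`, `model_*_global.tsv` with
σ²b, σ²w, ICC, band, normalized strengths and the intercept Wald z),
per-network ICC summaries, the mean interplay matrix, ground truth, and a
checksummed run manifest.

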