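# modvelo

Modular Bayesian RNA velocity for spliced/unspliced single-cell count data.

RNA velocity infers the direction of cellular differentiation from the
imbalance between unspliced (nascent) and spliced (mature) mRNA counts,
via the kinetics

    du/dt = alpha_g(t) - beta_g u
    ds/dt = beta_g u - gamma_g s

where `alpha`, `beta`, `gamma` are transcription, splicing and degradation
rates and `v = ds/dt` is the velocity.  The difficulty is `alpha_g(t)`:
real transcription rates change in complex, coordinated ways along a
trajectory.  modvelo expands the *derivative* of the transcription rate
into `M` independently switching **modules**,

    d alpha_g / dt = sum_m lam_mi (alphahat_mgi - alpha_mg),

each with its own switch-on/off times on a shared latent timescale, a
relaxation rate `lam`, and gene loadings `alphahat_mg` (zero in the OFF
state).  Every module's ODEs solve in closed form, so the model combines
biophysically flexible dynamics with exact likelihood evaluation, and the
modules double as an interpretable, mechanistically grounded analog of the
factors in matrix decomposition: they can be ranked for marker genes,
classified into OFF/induction/ON/repression states per cell, and their
steady-state expression can serve as reference signatures for spatial
deconvolution.

The model is fully Bayesian: raw counts enter a negative-binomial
observation model with per-cell and per-modality detection efficiencies,
per-batch ambient RNA and gene-wise overdispersion; all parameters carry
hierarchical priors and are inferred by stochastic variational inference
(implemented in numpy/numba with reparameterized gradients — see
`docs/methods.md`).  The posterior is returned as joint samples, so every
downstream quantity — velocities, the velocity graph, module activations,
per-cell time uncertainty — is posterior-aware.

The package also ships a forward simulator with known ground truth, and
the CBDir (cross-boundary directional correctness) benchmark metric with a
time-concordance companion.

## Worked example

```python
import numpy as np
from scipy import stats
from modvelo import (SimulationConfig, simulate, recovery_score,
                     PriorConfig, fit, posterior_time_cv)
from modvelo import downstream as ds

# simulate a 2-module trajectory and re-fit it
data, truth = simulate(SimulationConfig(n_cells=200, n_genes=60,
                                        n_modules=2, seed=11))
bundle = fit(data, PriorConfig(n_modules=2, epochs=600), seed=0)

scores = recovery_score(truth, bundle)
print("beta  Spearman rho = %.3f" % scores["beta_spearman"])
print("gamma Spearman rho = %.3f" % scores["gamma_spearman"])
rho_t = stats.spearmanr(truth.times, bundle.posterior_mean("t")).statistic
print("latent-time Spearman rho = %.3f" % rho_t)
print("median posterior-time CV = %.3f" % np.nanmedian(posterior_time_cv(bundle)))
print(ds.module_markers(bundle, module=0, k=3).to_string(index=False))
```

prints

```
beta  Spearman rho = 0.925
gamma Spearman rho = 0.831
latent-time Spearman rho = 0.988
median posterior-time CV = 0.080
   gene  fraction  target_rate
gene_18  0.934341     0.886604
gene_20  0.910524     0.560091
gene_49  0.901085     0.777579
```

The rank correlations say the fitted per-gene splicing/degradation rates
and per-cell latent times track the simulation's ground truth; the small
posterior-time CV says the data carry real dynamics (on data without
dynamics it grows — see the limitations section of `docs/methods.md`).
The marker table ranks genes by the fraction of their transcription rate
explained by module 0.

A command-line interface covers the same pipeline for files on disk:

```
modvelo simulate --seed 1 --out sim.h5ad
modvelo fit sim.h5ad --n-modules 2 --out fit.h5
modvelo analyze sim.h5ad fit.h5 --outdir results/
modvelo benchmark sim.h5ad fit.h5 --transitions transitions.csv --out cbdir.csv
```

`analyze` writes module activation/state tables, marker lists, the
steady-state reference signatures (genes x modules) and the sparse
transition-probability graph; `benchmark` scores CBDir and time
concordance against ground-truth cluster transitions.

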