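# genembed

Generative embedding for model-based classification and clustering of
regional brain time series.

Instead of feeding raw fMRI signals or descriptive statistics to a
classifier, each subject's data are first explained by a *generative network
model*: a bilinear dynamic causal model (DCM) of coupled neuronal
populations observed through balloon-model haemodynamics. The posterior
means of the neuronal coupling parameters — directed connection strengths,
their modulation by task demands, and driving-input gains — form a
low-dimensional, mechanistically interpretable feature space (a *generative
score space*). In that space the package supports:

* **supervised analysis** — cross-validated linear max-margin classification
  reported as balanced accuracy with a Bayesian significance measure (the
  posterior *infraliminal probability*, the probability that the classifier
  operates at or below chance);
* **unsupervised analysis** — variational Bayesian Gaussian mixture
  modelling with the number of clusters selected by the free-energy
  approximation to the log model evidence; and
* **external validation** — purity and chance-corrected *balanced purity*
  against categorical variables, one-way ANOVA and multiple regression
  against continuous clinical scores.

The intended users are computational-psychiatry and neuroimaging
methodologists who want to stratify patient cohorts by circuit-level
mechanism rather than by symptom checklists.

## The model

Neuronal dynamics of the R regions follow the bilinear state equation

    dx/dt = (A + Σ_j u_j(t) B^(j)) x(t) + C u(t)

with endogenous coupling `A` (Hz), modulatory changes `B^(j)` induced by
input `u_j`, and driving-input gains `C`. Each region's activity drives the
classical balloon model (vasodilatory signal, inflow, venous volume,
deoxyhaemoglobin) whose nonlinear observation equation yields percent BOLD
signal change. Subject-wise inversion maximises a variational-Laplace free
energy, returning a Gaussian posterior N(μ̂, Σ̂) over parameters and an
approximation to ln p(y|m); in the linear-Gaussian limit both the posterior
and the free energy are exact (verified against closed forms in the test
suite).

Clustering uses a Dirichlet + Gaussian–Wishart mixture inverted by
mean-field variational Bayes. The default prior learns per-feature Wishart
scales through conjugate Gamma hyperpriors shared across all candidate K, so
the evidence comparison across cluster numbers remains fair while the model
can discover that clusters are much tighter than the overall spread in some
coupling parameters and not in others. A fixed conjugate prior is available
and reproduces textbook closed forms exactly.

The bundled synthetic-cohort generator reproduces the working-memory study
conditions the package targets: a three-region visual–parietal–prefrontal
network under an n-back block design (six 22-trial blocks per condition,
500 ms stimuli, 900 ms ISI, TR 2.6 s), three patient subgroups with printed
coupling profiles (sizes 9/24/7), confound covariates, and cluster-dependent
negative-symptom scores (means 15.6/19.6/27.9).

## Worked example

```python
import numpy as np
from genembed import (table1_cohort, generate_feature_cohort, standardize,
                      select_model_order, LabelledPartition, purity,
                      balanced_purity, anova_external,
                      posterior_model_probability)

space, labels, covariates = generate_feature_cohort(table1_cohort(), seed=7)
z = standardize(space)
solution = select_model_order(z.X, K_max=5, n_restarts=5, seed=7)
print({k: round(v, 1) for k, v in solution.free_energies.items()})
print(solution.selected_K, round(solution.log_bayes_factor, 1))
part = LabelledPartition(solution.assignments, labels)
print(round(purity(part), 3), round(balanced_purity(part), 3))
F, dof, p = anova_external(solution.assignments, covariates["score"].to_numpy())
print(f"F={F:.2f} on {dof} dof, p={p:.2e}")
```

Output:

```
{1: -774.6, 2: -713.0, 3: -703.7, 4: -712.7, 5: -732.7}
3 9.0
0.975 0.958
F=46.19 on (2, 37) dof, p=8.76e-11
```

The free-energy profile peaks at K = 3 (log Bayes factor 9.0 over the
runner-up, i.e. posterior model probability > 99.9%), the recovered
subgroups match the generating ones almost perfectly (balanced purity
0.958), and — although the clustering never saw them — the subgroups differ
strongly in their simulated symptom scores.

The same stages are scriptable from the shell:

```bash
genembed simulate-cohort --cohort table1 --seed 7 --out cohort/
genembed embed   --space cohort/score_space.tsv --covariates cohort/covariates.tsv --out cohort/z.tsv
genembed cluster --space cohort/z.tsv --k-max 5 --seed 7 --out solution.json
genembed validate --solution solution.json --covariates cohort/covariates.tsv --out metrics.json
genembed run --seed 7 --out runs/        # full pipeline, one config-hashed directory
```

## Layout

| Module | Contents |
| --- | --- |
| `genembed.network` / `genembed.design` | network specs, coupling/haemodynamic parameters, n-back micro-time designs |
| `genembed.forward` | bilinear + balloon forward simulation (batched RK4) |
| `genembed.invert` | variational-Laplace inversion, `DCMInverter` estimator |
| `genembed.embedding` | score spaces, eigenvariates, confound residualization, comparator features |
| `genembed.vbgmm` | variational mixture, free-energy model-order selection |
| `genembed.validation` | purity, balanced purity, balanced accuracy, infraliminal probability, ANOVA/regression, Wald |
| `genembed.supervised` | cross-validated linear SVM baseline |
| `genembed.synthetic` | seeded cohort generators |
| `genembed.pipeline` / `genembed.cli` | reproducible runs and the `genembed` command |

See `docs/methods.md` for the modelling assumptions, default parameters and
their rationale, and known limitations.
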