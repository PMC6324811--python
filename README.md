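# nbgmifs

Penalized **Poisson and negative binomial (NB) regression for
high-dimensional count outcomes** (P > N), fit by the generalized monotone
incremental forward stagewise (GMIFS) algorithm, with offset handling,
dispersion estimation, AIC/BIC/cross-validation model selection,
over-dispersion diagnostics and a simulation harness for method evaluation.

## The problem

Count biomarkers such as micronucleus (MN) frequency — the number of
binucleated cells carrying at least one micronucleus in a cytokinesis-block
assay — are routinely over-dispersed: their variance exceeds their mean, so
a Poisson model understates uncertainty. When such an outcome is paired
with a high-throughput feature set (e.g. microarray gene expression with
thousands of probes measured on tens of subjects), classical Poisson/NB
maximum likelihood is undefined because there are more predictors than
observations. `nbgmifs` fits sparse rate models in exactly this regime.

## The model and algorithm

For counts `y_i` scored over exposures `c_i` (cells scored), with a small
set of forced-in covariates `x_ij` (e.g. gender) and a large penalized set
`x_ik` (e.g. gene expression), the mean model is

    mu_i = c_i * exp(gamma0 + x_ij' gamma + x_ik' beta)

so `log(c_i)` is an offset and the model describes a rate. The NB family
adds a heterogeneity parameter `alpha` with `Var(Y) = mu + alpha*mu^2`
(`alpha -> 0` recovers the Poisson).

GMIFS builds an L1-style solution path without a penalty grid: the
penalized predictors are standardized and duplicated with their negations
into the expanded design `[X : -X]`; at every step the single expanded
coefficient with the steepest log-likelihood gradient
`x' (y - mu) / (1 + alpha*mu)` is incremented by `epsilon` (default 0.001),
the intercept and forced-in coefficients are refit by maximum likelihood,
and `alpha` is re-estimated by a moment equation. The path stops when
successive log-likelihoods differ by less than `tau` (default 1e-5) or the
number of nonzero coefficients exceeds N - 1. A final model is the path
step minimising AIC, BIC or cross-validated prediction error.

## Worked example

Sixty to eighty subjects, MN counts scored over 500–2000 cells, gender
forced in, 100 expression features of which three (indices 4, 17, 62)
truly drive the rate:

```python
import numpy as np
from nbgmifs import CountGMIFS, CountDataset, diagnose, nb_sample

rng = np.random.default_rng(8)
n, k = 80, 100
expr = rng.standard_normal((n, k))
gender = rng.integers(0, 2, n).astype(float)
cells = rng.choice([500.0, 1000.0, 2000.0], n)
beta = np.zeros(k); beta[[4, 17, 62]] = [0.5, -0.5, 0.4]
mu = cells * np.exp(np.log(4 / 1000) + 0.3 * gender + expr @ beta)
y = nb_sample(mu, 0.4, rng)

data = CountDataset(y=y, exposure=cells, X_unpenalized=gender[:, None],
                    X_penalized=expr)
print(diagnose(data).to_string(index=False))
res = CountGMIFS.from_dataset(data, family="negbin").fit()
print(res.summary())
sel = res.select("bic")
print(np.flatnonzero(sel.params.beta), round(sel.params.alpha, 3))
```

prints

```
                test   statistic               df      p_value                          null
         boundary_lr  247.117433 boundary-mixture 5.518863e-56           alpha = 0 (Poisson)
score_overdispersion    3.073457               79 1.451889e-03 no over-dispersion (Var = mu)
 lagrange_multiplier 3672.597561                1 0.000000e+00 no over-dispersion (Var = mu)
  pearson_dispersion    7.555306                           NaN                dispersion = 1
```

— every diagnostic rejects equi-dispersion (Pearson dispersion 7.6 instead
of 1), so the NB family is appropriate — and then

```
GMIFS count regression path
===========================
family:            negbin
observations:      80
penalized K:       100
unpenalized J:     1
epsilon / tau:     0.001 / 1e-05
steps run:         6342 (stop: tol)
final loglik:      -188.1958
final alpha:       1.0733
AIC minimum:       369.027 at step 3123 (40 nonzero)
BIC minimum:       412.134 at step 916 (7 nonzero)
[ 4 13 17 51 62 65 89] 0.222
```

The BIC model keeps 7 of 100 features and recovers all three true drivers
(4, 17, 62); its heterogeneity estimate is 0.222. The AIC model is denser,
as expected. `res.predict(...)` gives fitted rates for new subjects, and
`res.plot_paths()` draws the monotone coefficient trajectories.

The same fit is available from the shell:

```bash
nbgmifs fixture --kind negbin_offset --seed 7 --out-dir fx
nbgmifs diagnose --response fx/response.csv --exposure-col cells_scored --unpenalized gender
nbgmifs fit --response fx/response.csv --matrix fx/features.csv \
    --exposure-col cells_scored --unpenalized gender --criterion bic --out-dir fit_out
nbgmifs simulate --design small-independent --alpha 0.3 --delta 1.75 --reps 5 --seed 7
```

For a real cohort reproduction one would export the processed expression
matrix of GEO accession GSE31836 as a features-by-samples CSV plus a sample
table with MN counts, binucleated-cell denominators and neonate gender, and
run `diagnose` followed by `fit --family negbin` with
`--orientation features_by_samples`. The package never downloads data.

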