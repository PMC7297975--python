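# robitsel

Sparse Bayesian feature selection and classification for high-dimensional
data whose features come in correlated groups — the typical situation in
gene-expression studies, where co-regulated genes move together and an
analyst wants a *short, interpretable* gene signature, not a 500-gene
coefficient vector.

## The model

`robitsel` fits a **robit** (t-link) binary regression with a small-scale
**Cauchy ("hyper-LASSO") prior** on the coefficients:

    y_i = 1{z_i > 0},   z_i = x_i β + ε_i,   ε_i ~ T(α₀=1, ω₀=0.5)
    β_j ~ Cauchy(0, e⁻⁵)                                 for j = 1, …, p

The heavy-tailed link absorbs the extreme outliers that are routine in
expression data; the heavy-tailed, tiny-scale prior shrinks noise
coefficients far harder than the LASSO while leaving genuinely large
effects nearly untouched.  Within a group of correlated features this
non-convex prior makes the posterior *multimodal*: each mode keeps roughly
one representative per group.  Rather than fighting that multimodality with
optimization, the package samples it:

* a **restricted Gibbs sampler with HMC** — latent prior variances λ_j get
  closed-form Inverse-Gamma updates; only the coefficients with the largest
  freshly drawn variances (plus the intercept) are moved per sweep by a
  Hamiltonian Monte Carlo trajectory, with the frozen contribution `X_F β_F`
  cached so the per-sweep cost scales with the number of signals, not p;
* a **two-stage fit** — a full-dimension screening chain ranks features by
  |posterior mean| and the top p* = 100 get a longer, definitive chain;
* **subset subdivision** — each stage-2 draw is reduced to the features
  above 10% of that draw's largest |coefficient|; features active in <5% of
  draws are dropped as jitter; unique patterns become candidate signatures
  with posterior frequencies, each scored by leave-one-out cross-validation
  with a Cauchy-penalized logistic refit (error rate, AMLP, AUROC, AUPRC);
* **posterior-averaged prediction** — new cases are classified by averaging
  the robit predictive probability over all retained draws, an ensemble
  across posterior modes that typically beats any single sparse subset.

See `docs/methods.md` for assumptions, tuning parameters and limitations.

## Worked example

`examples/extract_subsets.py` simulates the desk-scale grouped design
(p = 200 features, three signal groups of 10 sharing one latent factor
each, 170 noise features, n = 200 training cases), runs the two-stage fit
and prints the subset report:

```
58 distinct subsets over 2500 draws (0% of draws had no feature above threshold)
top 5 by posterior frequency, with LOOCV metrics:
freq   members (true group)                ER    AMLP  AUROC AUPRC
0.407  f2(g1), f16(g2), f23(g3)             0.09  0.23  0.97  0.97
0.095  f2(g1), f16(g2), f23(g3), f126(g0)   0.07  0.21  0.97  0.97
0.059  f2(g1), f16(g2), f23(g3), f172(g0)   0.09  0.22  0.97  0.97
0.043  f2(g1), f16(g2), f23(g3), f117(g0)   0.09  0.22  0.97  0.97
0.041  f2(g1), f16(g2), f23(g3), f90(g0)    0.09  0.22  0.97  0.97
top (highest frequency): ['f2', 'f16', 'f23']
optimal (lowest AMLP):   ['f2', 'f16', 'f23', 'f126']
```

Reading: 41% of the posterior draws select exactly features f2, f16, f23 —
one representative from each true signal group and nothing else.  That
three-feature signature misclassifies 9% of training cases under LOOCV and
ranks them with AUROC 0.97; lower-frequency variants add one feature each.
The other examples cover simulation (`simulate_grouped_data.py`), fitting
and posterior-averaged prediction (`fit_two_stage.py`), the prior's
sparsity quantiles (`prior_tail_quantiles.py`) and expression pre-filtering
(`filter_expression_matrix.py`).

A thin CLI wraps the same library calls:

```bash
robitsel simulate --scenario a-small --seed 1 --outdir run/
robitsel fit --matrix run/train_matrix.csv --labels run/train_labels.csv --seed 1 --outdir run/
robitsel subsets --chain run/chain.npz --matrix run/train_matrix.csv \
    --labels run/train_labels.csv --outdir run/
robitsel predict --chain run/chain.npz --matrix run/test_matrix.csv --out run/probs.csv
robitsel filter-genes --matrix expr.csv --out kept.csv
```

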