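# kernelsurv

Instance-based survival prediction for right-censored time-to-event
data, aimed at clinical and epidemiological cohorts of small to medium
size where *interpretable* individual predictions matter: every
predicted survival curve can be traced back to the most similar
training patients and their similarity weights.

## The method

Given training data $(x_i, t_i, \delta_i)_{i=1..n}$ with covariates
$x_i \in \mathbb{R}^m$, observed times $t_i > 0$ and event indicators
$\delta_i \in \{0,1\}$, a prediction for a query $x$ proceeds in two
steps:

1. **Kernel weights under a learned metric.** Each training instance
   gets a Gaussian radial-basis weight
   $w_i(U, x) = \exp(-\lVert Ux - Ux_i \rVert^2)$, where $U$ is an
   upper-triangular matrix and $A = U^\top U$ induces the
   Mahalanobis-type distance $d^2(x, x') = (x-x')^\top A (x-x')$.
2. **Weighted piecewise-exponential hazard.** Time (after a monotone
   transformation, below) is split into $k$ intervals
   $(\tau_{j-1}, \tau_j]$ at event-time quantiles, and the weighted
   maximum-likelihood hazard in interval $j$ is the closed-form
   occurrence/exposure ratio
   $\lambda_j(x) = \sum_i w_i \delta_{ij} \big/ \sum_i w_i r_j(t_i)$,
   with $r_j(t)$ the time at risk spent in interval $j$.  The predicted
   curve is $S(t\mid x) = \exp(-\sum_j \lambda_j(x)\, r_j(t))$.
   Because the rates are interval-specific, hazard ratios may change
   over time: the model is not restricted to proportional hazards.

$U$ is learned by minimizing the regularized leave-one-out negative
log-likelihood
$\eta \lVert U \rVert_F^2 - \tfrac1n \sum_l [\delta_l \log
\hat\lambda^{(-l)}_{j(t_l)} - \sum_j \hat\lambda^{(-l)}_j r_j(t_l)]$
with L-BFGS from the identity, where the hazard for instance $l$ is
computed with $w_l := 0$ (no instance predicts its own outcome).
Observed times are first mapped through the monotone transform
$\varphi$ that sends event times to their Nelson–Aalen cumulative
hazard values (censored times interpolate linearly), so that a single
interval already reproduces the nonparametric marginal survival curve
and few intervals ($k = 4$ by default) suffice.

The package also provides the evaluation toolkit (Antolini's
time-dependent concordance, the IPCW Brier score, its numerical
integral, and $R^2 = 1 - \mathrm{BI}(M)/\mathrm{BI}(\mathrm{KM})$) and
a four-series simulation benchmark with a variance-controlled
interaction signal, calibrated non-proportional Weibull arms, monotone
covariate distortion, and tie stress — see `docs/methods.md`.

## Worked example

```python
from kernelsurv import FitConfig, ScenarioConfig, evaluate_model, fit, simulate

cfg = ScenarioConfig(series="A", n_train=200, n_test=500,
                     interaction_fraction=0.5, censoring=0.25, seed=1)
train, test = simulate(cfg)
model = fit(train, FitConfig(k=4, eta=0.01, seed=0))
print(evaluate_model(model, test))
for idx, w, t, d in model.explain(test.covariates[0], top_k=3):
    print(idx, round(w, 3), t, d)
```

Running `python examples/01_fit_predict_explain.py` (this exact
pipeline) prints:

```
train: n=200, events=146 (27% censored)
fitted in 54 L-BFGS iterations, loss 0.8715 -> 0.6064
test concordance 0.630 (0.5 = uninformative), R^2 vs Kaplan-Meier 0.066

most influential training patients (weight = kernel similarity):
  train[ 97]  weight 0.573  time   0.59  event
  train[ 86]  weight 0.464  time   0.35  event
  ...
```

A concordance of 0.63 means 63% of time-orderable test pairs are
ranked correctly by the model at the earlier subject's event time; the
positive $R^2$ means the integrated Brier score improves on the
covariate-free Kaplan–Meier baseline; the neighbor table is the
explanation of the prediction — the closest training patients under
the learned metric, with their outcomes.

The other scripts in `examples/` demonstrate the Nelson–Aalen time
transform (exact coincidence on uncensored data), crossing survival
curves versus the single-interval proportional restriction, and
cross-validated selection of the regularization weight η.

A thin CLI mirrors the library:
`kernelsurv simulate|fit|predict|evaluate|explain --help`.

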