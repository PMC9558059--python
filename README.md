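# mwedist

Bayesian and maximum-likelihood estimation for the **Modified Weibull
Extension distribution (MWED)** under right censoring — a three-parameter
bathtub-hazard lifetime model for censored survival data such as cancer
patients' remission and survival times.

The MWED has cumulative hazard

$$H(x) = \mu\theta\left(e^{(x/\theta)^\sigma} - 1\right),$$

so its survival, density and hazard functions are
$R(x) = e^{-H(x)}$, $f(x) = h(x)R(x)$ and
$h(x) = \sigma\mu (x/\theta)^{\sigma-1} e^{(x/\theta)^\sigma}$, with scale
$\theta > 0$ and shapes $\sigma, \mu > 0$.  The hazard increases when
$\sigma \ge 1$ and is bathtub-shaped when $\sigma < 1$ — the pattern patient
survival times often show.  As $\theta \to \infty$ the model collapses to a
two-parameter Weibull, which makes the likelihood boundary-degenerate; this
package treats that honestly (see `docs/methods.md`).

The package provides:

- closed-form `pdf`/`cdf`/`reliability`/`hazard`/`quantile` and a seeded
  inverse-transform sampler;
- censored log-likelihoods (type-II and general right censoring), analytic
  gradients, finite-difference Hessian/third-derivative tensors, and an MLE
  with an explicit existence test against the Weibull boundary;
- gamma priors via prior-mean elicitation, the three-parameter **Lindley
  approximation** for posterior expectations, a 3-D **quadrature oracle**,
  and Bayes estimators with posterior risks under four loss functions
  (SELF, PLF, QLF, ELF);
- the Monte-Carlo evaluation protocol (type-II censored samples, mean and
  MSE per estimator) and two embedded censored cancer datasets (`D1`:
  30 leukemia remission times, `D2`: 22 bile-duct-cancer survival times)
  with Kaplan-Meier comparison curves;
- a thin CLI: `mwed simulate`, `mwed fit`, `mwed oracle`.

## Worked example

Fit the leukemia remission dataset (30 patients, 5 right-censored, weeks)
by maximum likelihood and by the four Bayes rules:

```python
import mwedist as mw

ds = mw.load_dataset("D1")
res = mw.fit_dataset(ds)
for method, p in res.params.items():
    print(method, round(p.theta, 1), round(p.sigma, 4), round(p.mu, 5),
          "fit-MSE", round(res.fit_mse[method], 5))
```

prints

```
MLE  91.0   0.6925 0.01803 fit-MSE 0.00583
SELF 91.2   0.5955 0.01777 fit-MSE 0.00198
PLF  128.0  0.6141 0.01836 fit-MSE 0.00184
QLF  45.8   0.5646 0.0159  fit-MSE 0.00872
ELF  46.2   0.5739 0.01671 fit-MSE 0.00697
```

Each row is a fitted parameter triple; $\sigma < 1$ says the estimated
hazard is bathtub-shaped.  `fit-MSE` is the mean squared vertical distance
between that method's fitted CDF and the Kaplan-Meier empirical CDF at the
uncensored times — the Bayes fits under SELF/PLF track the data more
closely than the MLE.  (For this dataset no finite unconstrained MLE
exists, so $\theta$ is restricted to the observation window and sits at its
cap of 91 weeks; see the methods note.)

The same from the shell: `mwed fit --dataset D1 --out report.json`.

More narrative scripts live in `examples/` — distribution basics, this
dataset fit, a small Monte-Carlo study, and a Lindley-vs-quadrature
validation.

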