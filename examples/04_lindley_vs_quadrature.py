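"""Validate Lindley's approximation against direct numerical integration.

For a seeded censored sample the five posterior moments of each parameter
are computed twice: by the Lindley expansion around the MLE (fast,
asymptotic) and by 3-D Gauss-Legendre quadrature over the posterior (slow,
near-exact).  The relative gap is the approximation error; it scales with
the squared relative standard error of each parameter, so the weakly
identified scale theta carries most of it.
"""

import numpy as np

import mwedist as mw

truth = mw.Params(1.0, 1.0, 1.0)
prior = mw.elicit_prior(truth.as_array())  # prior means at the truth, rate 1

s = mw.generate_censored_sample(1000, 800, truth, seed=6)
fit = mw.fit_mle(s)
bundle = mw.derivative_bundle(
    s, fit.params, prior_gradient=mw.log_prior_gradient(fit.params, prior)
)
print("MLE:", np.round(fit.params.as_array(), 3),
      " relative SE:", np.round(bundle.se / fit.params.as_array(), 3))

lin = mw.lindley_moments(bundle)
quad = mw.quadrature_moments(s, prior, bundle=bundle)

print(f"\n{'parameter':>9} {'moment':>6} {'Lindley':>9} {'quadrature':>10} {'rel gap':>8}")
for p in ("theta", "sigma", "mu"):
    for kind in ("m1", "m2", "inv1", "inv2", "ln"):
        lv, qv = getattr(lin[p], kind), getattr(quad[p], kind)
        print(f"{p:>9} {kind:>6} {lv:9.4f} {qv:10.4f} "
              f"{abs(lv - qv) / max(abs(qv), 1e-12):8.1%}")
# sigma (relative SE ~0.07) sits in the asymptotic regime: gaps ~1-2%.
# theta (relative SE ~0.34) does not: gaps of several percent remain even at
# n=1000 — Lindley's error is second order in the relative SE.
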