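"""Fit the MWED to the leukemia remission dataset (D1) by five methods.

D1 holds remission times (weeks) of 30 leukemia patients, 5 right-censored.
The fit reports the constrained MLE (the upturn scale theta is restricted to
the observation window — beyond it the data cannot tell the MWED from its
Weibull limit), the four Bayes estimates under different loss functions with
empirical-Bayes gamma priors, and a goodness-of-fit summary per method: the
mean squared distance between each fitted CDF and the Kaplan-Meier empirical
CDF at the uncensored times (smaller is better).
"""

import numpy as np

import mwedist as mw

ds = mw.load_dataset("D1")
print(f"{ds.name}: {ds.note} ({ds.records.n_censored} censored), times in {ds.time_unit}")

res = mw.fit_dataset(ds)
print(f"\n{'method':>6} {'theta':>10} {'sigma':>8} {'mu':>9} {'fit MSE':>9}")
for method, p in res.params.items():
    print(f"{method:>6} {p.theta:10.3f} {p.sigma:8.4f} {p.mu:9.5f} "
          f"{res.fit_mse[method]:9.5f}")
# sigma < 1: the fitted hazard is bathtub-shaped, typical of remission data.
# The Bayes estimates under SELF/PLF track the empirical curve more closely
# than the MLE (lower fit MSE), the study's qualitative headline.

t = np.array([10.0, 30.0, 60.0])
print("\nestimated P(remission > t) under the entropy-loss (ELF) fit:")
for ti in t:
    print(f"  t = {ti:4.0f} weeks: R = {mw.reliability(ti, res.params['ELF']):.3f} "
          f"(Kaplan-Meier: {res.km(ti):.3f})")
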