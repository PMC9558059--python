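"""A small Monte-Carlo comparison of MLE and Bayes estimators.

Generates type-II censored samples (n=50, 20% censored) from a known truth,
estimates the three parameters by MLE and by four Bayes rules (gamma priors
centered at the truth), and reports the mean estimate and the Monte-Carlo
MSE per method.  300 replicates keep this fast; the published protocol uses
10,000.
"""

import mwedist as mw
from mwedist.simulation import StudyConfig, run_study

cfg = StudyConfig(
    truth=mw.Params(1.0, 1.0, 1.0),
    n=50,
    censoring_fraction=0.20,
    replicates=300,
    seed=7,
)
print(f"truth (1, 1, 1); n={cfg.n}, r={cfg.r}; {cfg.replicates} replicates\n")
res = run_study(cfg)
print(res.table.to_string(index=False))
print(f"\nreplicates dropped (MLE nonexistent / information not PD): "
      f"{res.dropped_replicates}")
# 'mean' near the truth and small 'mse' mark a good estimator. The MLE of
# theta is heavy-tailed (the likelihood is boundary-degenerate), so its MSE
# is much larger than the shrinkage-stabilized Bayes columns; the entropy
# loss (ELF) is typically among the best for theta, matching the published
# study's conclusion. n_used counts replicates with a coherent estimate.
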