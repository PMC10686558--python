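"""Lagged history regression and decay-curve fits to the mean weights.

The history GLM measures how strongly each past rewarded/unrewarded choice
pulls the next choice; fitting exponential and hyperbolic curves to the
rewarded-choice weights (compared by AIC) previews which decay family
describes the behavior.
"""

import numpy as np

import foragefit as ff

env = ff.make_environment(ff.TaskConfig(n_trials=2000, seed=5))
table = ff.simulate_agent(ff.hyp_agent(beta=2.0, tau=2.0), env, 2000, seed=6)

w = ff.fit_history_glm(table, n_lags=10)
print("lag   beta_rewc  beta_unrc")
for i in range(10):
    print(f"{i + 1:3d}   {w.beta_rewc[i]:9.3f}  {w.beta_unrc[i]:9.3f}")

fe = ff.fit_weight_curve(w.beta_rewc, "exp")
fh = ff.fit_weight_curve(w.beta_rewc, "hyp")
print(f"\nexp curve: tau={fe.tau:.2f}  AIC={fe.aic:.2f}")
print(f"hyp curve: tau={fh.tau:.2f}  AIC={fh.aic:.2f}")
best = "hyperbolic" if fh.aic < fe.aic else "exponential"
print(f"lower AIC -> {best} decay describes the mean weights better")
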