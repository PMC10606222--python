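"""Crossing survival curves: where interval-specific hazards pay off.

Generates a two-arm cohort whose arm-wise survival curves cross (equal
time-averaged hazards but different Weibull shapes), then compares the
4-interval kernel model with its single-interval (proportional-hazards)
restriction.
"""

import numpy as np

from kernelsurv import (
    FitConfig,
    ScenarioConfig,
    calibrate_series_b,
    evaluate_model,
    fit,
    simulate,
)

alpha1, theta0, theta1 = calibrate_series_b(target_isd=0.3)
print(f"calibrated arm parameters: alpha1={alpha1:.3f}, "
      f"shapes theta0={theta0:.3f}, theta1={theta1:.3f}")
print("(integrated squared difference between arm curves = 0.3, "
      "time-averaged hazard ratio = 1)")

cfg = ScenarioConfig(series="B", n_train=200, n_test=1000, censoring=0.0,
                     alpha1=alpha1, theta0=theta0, theta1=theta1, seed=8003)
train, test = simulate(cfg)

m4 = fit(train, FitConfig(k=4, eta=0.01, seed=0))
m1 = fit(train, FitConfig(k=1, eta=0.01, seed=0))
r4 = evaluate_model(m4, test)
r1 = evaluate_model(m1, test)
print(f"\nR^2 with k=4 intervals: {r4['r_squared']:.3f}")
print(f"R^2 with k=1 interval : {r1['r_squared']:.3f}  (proportional restriction)")

arm = test.covariates[:, -1]
grid = np.linspace(0.01, float(np.quantile(test.times, 0.95)), 40)
S = m4.predict_survival(test.covariates, grid)
diff = S[arm == 0].mean(axis=0) - S[arm == 1].mean(axis=0)
sign_change = np.where(np.diff(np.sign(diff)) != 0)[0]
if sign_change.size:
    print(f"\nfitted mean curves of the two arms cross near "
          f"t = {grid[sign_change[0]]:.2f} - the k=4 model reproduces "
          "the non-proportionality")
else:
    print("\nno crossing detected in the fitted mean curves")
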