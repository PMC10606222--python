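"""The Nelson-Aalen time transform in action.

On uncensored data, a single-interval unweighted exponential model on
the transformed time axis reproduces the Nelson-Aalen survival estimate
exactly - so the hazard intervals are freed up to model
non-proportionality instead of curve shape.
"""

import numpy as np

from kernelsurv import SurvivalDataset, build_model, fit_time_transform, nelson_aalen

rng = np.random.default_rng(0)
n = 50
X = rng.normal(size=(n, 2))
t = np.exp(rng.normal(size=n))  # lognormal: far from exponential
ds = SurvivalDataset(X, t, np.ones(n))

tt = fit_time_transform(ds.times, ds.events)
print(f"transform knots: {tt.knot_times.size} event times -> "
      f"cumulative-hazard values in [{tt.knot_values[0]:.3f}, "
      f"{tt.knot_values[-1]:.3f}]")

model = build_model(ds, U=np.zeros((2, 2)), k=1)  # pooled, one interval
na = nelson_aalen(ds.times, ds.events)
S_model = model.predict_survival(X[0], np.sort(t))
S_na = np.exp(-na.at(np.sort(t)))
print(f"max |S_model - exp(-H_NA)| over all observed times: "
      f"{np.max(np.abs(S_model - S_na)):.2e}")
print("the pooled single-interval fit on transformed time IS the "
      "Nelson-Aalen curve (up to float rounding)")
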