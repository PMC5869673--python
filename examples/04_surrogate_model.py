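"""Fit the heteroscedastic surrogate that stands in for
"spectrometer + pipeline" in population simulations.

The surrogate maps true age -> distribution of predicted age:
predicted ~ Normal(alpha + beta*age, (sigma0 + sigma1*age)^2).
An unbiased pipeline gives alpha ~= 0, beta ~= 1; sigma1 > 0 means
predictions spread out for older mosquitoes.
"""

import numpy as np

from mozzage import (
    SplitSpec,
    SyntheticSpec,
    WavelengthGrid,
    fit_pipeline,
    fit_surrogate,
    generate_study,
    simulate_predictions,
    split_train_val_test,
)

grid = WavelengthGrid(350, 2500, 10.0)
ds = generate_study(SyntheticSpec(grid=grid, seed=3))
split = SplitSpec(seed=5)
parts = split_train_val_test(ds, split)
pipe = fit_pipeline(ds, split=split, precomputed_split=parts)

truth = parts.test.ages
pred = pipe.predict(parts.test)
model = fit_surrogate(truth, pred, method="laplace")

print("surrogate fitted to held-out (true, predicted) age pairs:")
print(f"  alpha  = {model.alpha:+.3f} d   (0 for an unbiased pipeline)")
print(f"  beta   = {model.beta:+.3f}     (1 for an unbiased pipeline)")
print(f"  sigma0 = {model.sigma0:.3f} d   noise SD at age 0")
print(f"  sigma1 = {model.sigma1:.3f} d/d noise growth per day of age")
for name, (lo, hi) in model.credible_intervals().items():
    print(f"  95% CI {name}: [{lo:.3f}, {hi:.3f}]")

sim = simulate_predictions(model, np.full(10_000, 8.0), seed=0)
print(
    f"\n10,000 simulated readings of an 8-day-old mosquito: "
    f"mean {sim.mean():.2f} d, SD {sim.std():.2f} d"
)
print("The surrogate lets population studies skip spectrum generation entirely.")
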