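"""How individual-age accuracy improves with calibration-set size.

Runs a small learning-curve experiment (subsample -> fit -> score on a
fixed test set) and fits the square-root law RMSE(n) = a + b/sqrt(n):
`a` is the accuracy floor and b/sqrt(n) the finite-calibration penalty.
"""

import numpy as np

from mozzage import (
    CVConfig,
    SplineConfig,
    SyntheticSpec,
    WavelengthGrid,
    fit_pipeline,
    generate_study,
    learning_curve,
    predicted_rmse,
)
from mozzage.spectra_io import split_train_val

grid = WavelengthGrid(350, 2500, 10.0)
ds = generate_study(SyntheticSpec(grid=grid, seed=2))


def scaled_fit(train_ds, test_ds, fit_seed):
    # smaller spline basis and CV so tiny subsamples stay fittable
    pipe = fit_pipeline(
        train_ds,
        cv=CVConfig(n_bootstrap=8, component_cap=10, seed=int(fit_seed)),
        precomputed_split=split_train_val(train_ds, 0.3, int(fit_seed)),
        spline_config=SplineConfig(df=3, min_rows=10),
    )
    return pipe.predict(test_ds)


sizes = [50, 100, 200, 400]
lc = learning_curve(ds, sizes, replicates=10, seed=4, fit_predict=scaled_fit)
fit = lc.fit_power_law()

print("size   median RMSE   IQR (days)")
for s, med, lo, hi in zip(sizes, lc.medians, lc.q25, lc.q75):
    print(f"{s:4d}   {med:11.2f}   [{lo:.2f}, {hi:.2f}]")
print(f"\nfitted law: RMSE(n) = {fit.a:.2f} + {fit.b:.1f}/sqrt(n) days")
print(f"predicted RMSE at n=800: {predicted_rmse(fit, 800):.2f} days")
print("\nDiminishing returns: each doubling of n buys less accuracy than the last.")
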