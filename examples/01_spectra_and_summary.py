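"""Generate a synthetic spectral study, round-trip it through the wide-CSV
dialect, and print the per-study age-group summary table.

The counts are the standard way mosquito ageing datasets are described:
mosquitoes per study in the age bins <=5, (5,10], (10,15], (15,20], >20 days.
"""

import tempfile
from pathlib import Path

from mozzage import (
    SyntheticSpec,
    WavelengthGrid,
    age_group_counts,
    generate_study,
    load_spectra_table,
    write_spectra_table,
)

# coarse 10 nm grid keeps the file small; the canonical instrument grid is
# 350-2500 nm at 1 nm
grid = WavelengthGrid(350, 2500, 10.0)
ds = generate_study(SyntheticSpec(grid=grid, seed=0))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "study_a.csv"
    write_spectra_table(ds, path)
    loaded = load_spectra_table(path)

print(f"{loaded.n_samples} mosquitoes on a {len(loaded.grid)}-point grid")
table = age_group_counts(loaded)
table["total"] = table.sum(axis=1)
print(table.to_string())
print("\nEach row is one study; columns count mosquitoes per age group in days.")
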