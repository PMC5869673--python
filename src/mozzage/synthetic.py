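"""Synthetic spectral datasets with known ground truth.

The generator emulates the structure of real mosquito NIR absorbance
data: smooth baseline curvature, a monotone age-dependent signal
confined to specific wavelength bands, additive per-study offsets and
multiplicative gains (inter-study variability), smooth per-mosquito
artifacts (probe positioning, scattering), and white instrument noise
that grows toward the long-wavelength detector edge.  Every draw is
deterministic given the spec and seed, and true ages are recorded in the
metadata, so every downstream module can be tested without laboratory
data.

Two scales of biological realism matter for what tests can show:

* ``age_jitter_sd`` makes same-age mosquitoes biochemically different,
  setting the irreducible individual-age error floor (default 0.44 days,
  the asymptote of the published RMSE-vs-training-size relation).
* The artifact and noise scales control how much calibration data a
  model needs before approaching that floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridError
from .spectra_io import CANONICAL_GRID, SpectraDataset, WavelengthGrid

#: Default smooth baseline: three broad Gaussian bumps (centre nm, width nm,
#: amplitude in absorbance units).
DEFAULT_BASELINE = ((500.0, 180.0, 0.9), (1200.0, 320.0, 0.6), (1900.0, 260.0, 0.45))

#: Default age-signal bands (low nm, high nm, slope in absorbance/day),
#: confined to the windows known to be age-predictive in Anopheles.
DEFAULT_SIGNAL_BANDS = (
    (350.0, 708.0, 0.0010),
    (709.0, 1066.0, 0.0022),
    (1067.0, 1424.0, 0.0016),
)

#: Study-A-like age-group counts (bins <=5, (5,10], (10,15], (15,20], >20).
STUDY_A_BIN_COUNTS = (196, 302, 100, 101, 172)
AGE_BIN_EDGES = (5, 10, 15, 20)


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to generate one synthetic study deterministically."""

    n_mosquitoes: int = 871
    grid: WavelengthGrid = CANONICAL_GRID
    #: One of: explicit ages, an exponential mean, or age-group bin counts.
    ages: tuple | None = None
    age_mean: float | None = None
    age_bin_counts: tuple | None = STUDY_A_BIN_COUNTS
    signal_bands: tuple = DEFAULT_SIGNAL_BANDS
    age_jitter_sd: float = 0.44
    baseline_bumps: tuple = DEFAULT_BASELINE
    study_offset: float = 0.0
    study_gain: float = 1.0
    n_artifacts: int = 60
    artifact_sd: float = 0.025
    noise_sd: float = 0.012
    edge_noise_factor: float = 4.0
    edge_start_nm: float = 1850.0
    study: str = "A"
    species: str = "An. arabiensis"
    sex: str = "female"
    preservation: str = "fresh"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mosquitoes < 1:
            raise ConfigurationError("n_mosquitoes must be >= 1")
        if self.noise_sd < 0 or self.artifact_sd < 0 or self.age_jitter_sd < 0:
            raise ConfigurationError("noise scales must be >= 0")
        for lo, hi, _ in self.signal_bands:
            if lo > hi:
                raise GridError(f"signal band [{lo}, {hi}] is inverted")
            if hi < self.grid.start_nm or lo > self.grid.stop_nm:
                raise GridError(
                    f"signal band [{lo}, {hi}] lies outside the grid "
                    f"[{self.grid.start_nm}, {self.grid.stop_nm}]"
                )


def scaled_bin_counts(n: int, proportions: tuple = STUDY_A_BIN_COUNTS) -> tuple:
    """Age-group counts summing to ``n`` with Study-A-like proportions.

    Largest-remainder apportionment, so any n reproduces the published
    young-heavy age imbalance.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    props = np.asarray(proportions, dtype=float)
    quotas = n * props / props.sum()
    counts = np.floor(quotas).astype(int)
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(n - counts.sum()):
        counts[order[i % counts.size]] += 1
    return tuple(int(c) for c in counts)


def _band_profile(w: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Raised-cosine window on [lo, hi]: smooth, 1 in the core, 0 outside."""
    width = hi - lo
    ramp = max(0.1 * width, 1e-9)
    prof = np.zeros_like(w)
    inside = (w >= lo) & (w <= hi)
    prof[inside] = 1.0
    left = inside & (w < lo + ramp)
    right = inside & (w > hi - ramp)
    prof[left] = 0.5 * (1 - np.cos(np.pi * (w[left] - lo) / ramp))
    prof[right] = 0.5 * (1 - np.cos(np.pi * (hi - w[right]) / ramp))
    return prof


def _draw_ages(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.ages is not None:
        ages = np.asarray(spec.ages, dtype=float)
        if ages.size != spec.n_mosquitoes:
            raise ConfigurationError("len(ages) must equal n_mosquitoes")
        return ages
    if spec.age_mean is not None:
        return rng.exponential(spec.age_mean, spec.n_mosquitoes)
    counts = np.asarray(spec.age_bin_counts, dtype=int)
    if counts.sum() != spec.n_mosquitoes:
        raise ConfigurationError(
            f"age_bin_counts sum to {counts.sum()} but n_mosquitoes is "
            f"{spec.n_mosquitoes}"
        )
    # Integer ages drawn uniformly inside each left-open bin; the last bin
    # extends five days past its lower edge (laboratory cohorts rarely
    # exceed ~25 days).
    lows = (0,) + AGE_BIN_EDGES
    highs = AGE_BIN_EDGES + (AGE_BIN_EDGES[-1] + 5,)
    ages = np.concatenate(
        [
            rng.integers(lo + 1, hi + 1, size=c)
            for lo, hi, c in zip(lows, highs, counts)
        ]
    ).astype(float)
    return ages[rng.permutation(ages.size)]


def generate_study(spec: SyntheticSpec) -> SpectraDataset:
    """Generate one synthetic study as a validated :class:`SpectraDataset`.

    Absorbance is baseline + sum of band-profiles times (age + biological
    jitter) + study offset/gain + smooth per-mosquito artifacts + white
    noise, all deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.grid.wavelengths
    ages = _draw_ages(spec, rng)
    n = spec.n_mosquitoes

    baseline = np.zeros_like(w)
    for c, width, amp in spec.baseline_bumps:
        baseline += amp * np.exp(-0.5 * ((w - c) / width) ** 2)

    signal = np.zeros_like(w)
    for lo, hi, slope in spec.signal_bands:
        signal += slope * _band_profile(w, lo, hi)

    eff_age = ages + rng.normal(0.0, spec.age_jitter_sd, n)
    A = baseline[None, :] + eff_age[:, None] * signal[None, :]

    # Smooth per-mosquito artifacts: random Gaussian bumps with per-row
    # coefficients.  Bump shapes are drawn per study, so they also act as
    # a source of inter-study structure.
    for _ in range(spec.n_artifacts):
        center = rng.uniform(spec.grid.start_nm, spec.grid.stop_nm)
        width = rng.uniform(150.0, 450.0)
        shape = np.exp(-0.5 * ((w - center) / width) ** 2)
        A += rng.normal(0.0, spec.artifact_sd, n)[:, None] * shape[None, :]

    A = spec.study_gain * A + spec.study_offset

    if spec.noise_sd > 0:
        noise_scale = np.where(
            w > spec.edge_start_nm,
            spec.noise_sd * spec.edge_noise_factor,
            spec.noise_sd,
        )
        A += rng.normal(0.0, 1.0, A.shape) * noise_scale[None, :]

    meta = pd.DataFrame(
        {
            "study": spec.study,
            "species": spec.species,
            "sex": spec.sex,
            "preservation": spec.preservation,
            "age_days": ages,
        }
    )
    return SpectraDataset(spec.grid, A, meta)


def generate_multistudy(specs) -> SpectraDataset:
    """Concatenate several synthetic studies sharing one grid."""
    specs = list(specs)
    if len(specs) < 2:
        raise ConfigurationError("need >= 2 study specs")
    grid = specs[0].grid
    for s in specs[1:]:
        if s.grid != grid:
            raise GridError("all studies must share one wavelength grid")
    parts = [generate_study(s) for s in specs]
    return SpectraDataset(
        grid,
        np.vstack([p.absorbance for p in parts]),
        pd.concat([p.meta for p in parts], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Reference multi-study composition
# ---------------------------------------------------------------------------

#: Study composition of the published multi-study mosquito NIRS database:
#: per-study species, country, sex, preservation method and age-group
#: counts (bins <=5, (5,10], (10,15], (15,20], >20 days).  Grand total 4549.
REFERENCE_STUDY_TABLE = pd.DataFrame(
    [
        ("A", "An. arabiensis", "Tanzania", "female", "fresh", 196, 302, 100, 101, 172),
        ("B", "An. arabiensis", "Tanzania", "female", "silica gel", 103, 168, 103, 51, 0),
        ("C", "An. arabiensis", "Tanzania", "female", "fresh", 99, 50, 95, 69, 0),
        ("D", "An. arabiensis", "Tanzania", "male", "fresh", 100, 50, 72, 67, 0),
        ("E", "An. gambiae s.s.", "Tanzania", "female", "fresh", 208, 305, 0, 102, 93),
        ("F", "An. gambiae s.s.", "Tanzania", "female", "fresh", 100, 50, 93, 90, 0),
        ("G", "An. gambiae s.s.", "Tanzania", "female", "fresh", 100, 50, 86, 94, 0),
        ("H", "An. gambiae s.s.", "Tanzania", "male", "fresh", 100, 50, 67, 77, 0),
        ("I", "An. gambiae s.s.", "Tanzania", "male", "fresh", 100, 50, 76, 13, 0),
        ("J", "An. gambiae s.l.", "Tanzania", "female", "RNAlater", 91, 162, 42, 0, 0),
        ("K", "Ae. aegypti", "Australia", "male", "RNAlater", 46, 43, 46, 50, 42),
        ("L", "Ae. aegypti", "Australia", "female", "RNAlater", 41, 45, 46, 43, 50),
    ],
    columns=[
        "study", "species", "country", "sex", "preservation",
        "n_le5", "n_5_10", "n_10_15", "n_15_20", "n_gt20",
    ],
)

_AEDES_SIGNAL_BANDS = (
    (709.0, 1066.0, 0.0022),
    (1067.0, 1424.0, 0.0016),
)


def generate_reference_dataset(
    seed: int = 0,
    grid: WavelengthGrid = CANONICAL_GRID,
    **overrides,
) -> SpectraDataset:
    """Synthetic stand-in for the published multi-study database.

    Reproduces the per-study sizes, species, sexes, preservation methods
    and age-group composition of :data:`REFERENCE_STUDY_TABLE` exactly;
    spectra are synthetic, with per-study offsets, gains and artifact
    structure drawn deterministically from ``seed``.  Aedes studies use
    the two-band Aedes signal layout.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for row in REFERENCE_STUDY_TABLE.itertuples():
        counts = (row.n_le5, row.n_5_10, row.n_10_15, row.n_15_20, row.n_gt20)
        is_aedes = row.species.startswith("Ae.")
        specs.append(
            SyntheticSpec(
                n_mosquitoes=int(sum(counts)),
                grid=grid,
                age_bin_counts=counts,
                signal_bands=_AEDES_SIGNAL_BANDS if is_aedes else DEFAULT_SIGNAL_BANDS,
                study_offset=float(rng.normal(0.0, 0.15)),
                study_gain=float(rng.uniform(0.85, 1.15)),
                study=row.study,
                species=row.species,
                sex=row.sex,
                preservation=row.preservation,
                seed=int(rng.integers(0, 2**31 - 1)),
                **overrides,
            )
        )
    return generate_multistudy(specs)
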