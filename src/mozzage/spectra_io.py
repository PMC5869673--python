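"""Reading, validating, summarising and splitting spectral datasets.

A dataset is a matrix of absorbance spectra on a shared wavelength grid with
one row of metadata per mosquito (study label, species, sex, preservation
method, true age in days).  The on-disk dialect is a wide CSV: metadata
columns first, then one numeric column per wavelength, labelled in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    GridError,
    MetadataError,
    MissingDataError,
    SizeError,
)

#: Metadata columns expected in the wide-CSV dialect, in canonical order.
METADATA_COLUMNS = ("study", "species", "sex", "preservation", "age_days")

#: Default age-group boundaries (days) used for summary count tables:
#: bins are <=5, (5, 10], (10, 15], (15, 20], >20.
DEFAULT_AGE_BIN_EDGES = (5.0, 10.0, 15.0, 20.0)

_GRID_TOL = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid, inclusive of both endpoints, in nm."""

    start_nm: float
    stop_nm: float
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise GridError(
                f"start_nm ({self.start_nm}) must be below stop_nm ({self.stop_nm})"
            )
        if self.step_nm <= 0:
            raise GridError(f"step_nm must be positive, got {self.step_nm}")
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > _GRID_TOL:
            raise GridError(
                "grid length (stop_nm - start_nm) / step_nm must be an integer; "
                f"got {n}"
            )

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """Wavelengths in nm, strictly increasing, length ``len(self)``."""
        return self.start_nm + self.step_nm * np.arange(len(self))

    @classmethod
    def from_wavelengths(cls, wavelengths: Sequence[float]) -> "WavelengthGrid":
        """Infer a uniform grid from an explicit wavelength vector.

        The step is inferred from the data rather than assumed, since
        deposited spectra may be on coarser grids than the instrument's
        native 1 nm resolution.
        """
        w = np.asarray(wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise GridError("need at least two wavelengths to infer a grid")
        diffs = np.diff(w)
        if np.any(diffs <= 0):
            raise GridError("wavelengths are not strictly increasing")
        step = float(np.median(diffs))
        if np.max(np.abs(diffs - step)) > _GRID_TOL * max(1.0, step):
            raise GridError("wavelengths are not uniformly spaced")
        return cls(float(w[0]), float(w[-1]), step)

    def indices_between(self, low_nm: float, high_nm: float) -> np.ndarray:
        """Column indices whose wavelength lies in [low_nm, high_nm]."""
        w = self.wavelengths
        return np.flatnonzero((w >= low_nm - _GRID_TOL) & (w <= high_nm + _GRID_TOL))


#: Reference convention: ASD-type instruments span 350-2500 nm; 1 nm steps
#: (2151 points) are declared the canonical grid for this package.
CANONICAL_GRID = WavelengthGrid(350.0, 2500.0, 1.0)


@dataclass(frozen=True)
class MosquitoRecord:
    """Per-mosquito metadata attached to one spectrum."""

    study: str
    species: str
    sex: str
    preservation: str
    age_days: float

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise MetadataError(f"age_days must be >= 0, got {self.age_days}")
        if self.sex not in ("male", "female"):
            raise MetadataError(f"sex must be 'male' or 'female', got {self.sex!r}")


class SpectraDataset:
    """Absorbance matrix on a shared grid plus aligned per-row metadata.

    Parameters
    ----------
    grid:
        The wavelength grid shared by every row.
    absorbance:
        Array of shape ``(n_mosquitoes, len(grid))``; unitless absorbance.
    meta:
        DataFrame with at least the columns in :data:`METADATA_COLUMNS`,
        one row per spectrum.
    """

    def __init__(self, grid: WavelengthGrid, absorbance, meta: pd.DataFrame):
        absorbance = np.asarray(absorbance, dtype=float)
        if absorbance.ndim != 2:
            raise FormatError("absorbance must be a 2-d matrix")
        if absorbance.shape[1] != len(grid):
            raise GridError(
                f"absorbance has {absorbance.shape[1]} columns but grid has "
                f"{len(grid)} points"
            )
        if len(meta) != absorbance.shape[0]:
            raise MetadataError(
                f"{len(meta)} metadata rows for {absorbance.shape[0]} spectra"
            )
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise MetadataError(f"metadata columns missing: {missing}")
        if not np.all(np.isfinite(absorbance)):
            bad = np.flatnonzero(~np.isfinite(absorbance).all(axis=1))
            raise MissingDataError(
                f"non-finite absorbance values in rows {bad[:20].tolist()}"
            )
        ages = meta["age_days"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ages)) or np.any(ages < 0):
            raise MetadataError("age_days must be finite and >= 0 for every row")
        self.grid = grid
        self.absorbance = absorbance
        self.meta = meta.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def __len__(self) -> int:
        return self.n_samples

    @property
    def ages(self) -> np.ndarray:
        return self.meta["age_days"].to_numpy(dtype=float)

    @property
    def studies(self) -> list[str]:
        return sorted(self.meta["study"].astype(str).unique())

    @property
    def records(self) -> list[MosquitoRecord]:
        return [
            MosquitoRecord(
                study=str(r.study),
                species=str(r.species),
                sex=str(r.sex),
                preservation=str(r.preservation),
                age_days=float(r.age_days),
            )
            for r in self.meta.itertuples()
        ]

    def subset(self, indices) -> "SpectraDataset":
        """New dataset holding the given rows (copy, original order kept)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraDataset(
            self.grid, self.absorbance[idx].copy(), self.meta.iloc[idx].copy()
        )

    def for_study(self, study: str) -> "SpectraDataset":
        return self.subset(np.flatnonzero(self.meta["study"].astype(str) == study))

    def equals(self, other: "SpectraDataset") -> bool:
        return (
            self.grid == other.grid
            and np.array_equal(self.absorbance, other.absorbance)
            and self.meta[list(METADATA_COLUMNS)].equals(
                other.meta[list(METADATA_COLUMNS)]
            )
        )


# ---------------------------------------------------------------------------
# Wide-CSV loader / writer
# ---------------------------------------------------------------------------

def load_spectra_table(path, *, sort_wavelengths: bool = False) -> SpectraDataset:
    """Load a wide-CSV spectral table.

    The header must contain the metadata columns of :data:`METADATA_COLUMNS`
    plus numeric wavelength labels (nm).  Wavelength columns must be strictly
    increasing unless ``sort_wavelengths`` is set, in which case they are
    sorted into grid order.

    Raises
    ------
    FormatError, GridError, MetadataError, MissingDataError
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as dialect error
        raise FormatError(f"could not parse {path}: {exc}") from exc

    missing_meta = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing_meta:
        raise MetadataError(f"{path}: metadata columns missing: {missing_meta}")

    wl_labels = [c for c in frame.columns if c not in METADATA_COLUMNS]
    if not wl_labels:
        raise FormatError(f"{path}: no wavelength columns found")
    try:
        wavelengths = np.array([float(c) for c in wl_labels])
    except ValueError as exc:
        raise FormatError(
            f"{path}: wavelength column labels must be numeric nm values "
            f"({exc})"
        ) from exc

    order = np.argsort(wavelengths)
    if not np.all(order == np.arange(order.size)):
        if not sort_wavelengths:
            raise GridError(
                f"{path}: wavelength columns are not in increasing order "
                "(pass sort_wavelengths=True to reorder)"
            )
        wavelengths = wavelengths[order]
        wl_labels = [wl_labels[i] for i in order]

    grid = WavelengthGrid.from_wavelengths(wavelengths)
    absorbance = frame[wl_labels].to_numpy(dtype=float)
    bad_rows = np.flatnonzero(~np.isfinite(absorbance).all(axis=1))
    if bad_rows.size:
        raise MissingDataError(
            f"{path}: rows with missing absorbance values rejected: "
            f"{bad_rows[:20].tolist()}"
            + (" ..." if bad_rows.size > 20 else "")
        )
    meta = frame[list(METADATA_COLUMNS)].copy()
    if meta.isna().any().any():
        cols = meta.columns[meta.isna().any()].tolist()
        raise MetadataError(f"{path}: missing metadata values in columns {cols}")
    return SpectraDataset(grid, absorbance, meta)


def write_spectra_table(ds: SpectraDataset, path) -> None:
    """Write a dataset in the same wide-CSV dialect read by the loader."""
    wl = ds.grid.wavelengths
    labels = [_format_wavelength(v) for v in wl]
    frame = pd.concat(
        [
            ds.meta[list(METADATA_COLUMNS)].reset_index(drop=True),
            pd.DataFrame(ds.absorbance, columns=labels),
        ],
        axis=1,
    )
    frame.to_csv(path, index=False)


def _format_wavelength(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# Age-group summary (published-table style)
# ---------------------------------------------------------------------------

def age_group_counts(
    ds: SpectraDataset,
    bin_edges: Sequence[float] = DEFAULT_AGE_BIN_EDGES,
) -> pd.DataFrame:
    """Count mosquitoes per study per age group.

    Bins follow the left-open / right-closed convention used in published
    study summaries: ``<=e1, (e1, e2], ..., >e_last``.  Counts conserve mass:
    the table total equals the dataset size, and empty bins are reported
    as zeros.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise ConfigurationError("bin_edges must be strictly increasing")
    labels = [f"<={_fmt(edges[0])}"]
    labels += [
        f"({_fmt(lo)},{_fmt(hi)}]" for lo, hi in zip(edges[:-1], edges[1:])
    ]
    labels += [f">{_fmt(edges[-1])}"]
    if ds.n_samples == 0:
        return pd.DataFrame(columns=labels, dtype=int)
    cut = pd.cut(
        ds.ages,
        bins=np.concatenate(([-np.inf], edges, [np.inf])),
        labels=labels,
        right=True,
    )
    table = (
        pd.crosstab(ds.meta["study"].astype(str), cut)
        .reindex(columns=labels, fill_value=0)
        .astype(int)
    )
    table.index.name = "study"
    table.columns.name = "age_group"
    return table


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


# ---------------------------------------------------------------------------
# Train / validation / test splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Three-way split proportions plus the seed that fixes the permutation.

    The conventional protocol holds out 30% of the data as a test set and
    splits the remaining 70% again into an inner training set (70% of it)
    and a validation set (30% of it), i.e. fractions (0.49, 0.21, 0.30) of
    the full dataset.
    """

    train_frac: float = 0.49
    val_frac: float = 0.21
    test_frac: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("train_frac", self.train_frac),
            ("val_frac", self.val_frac),
            ("test_frac", self.test_frac),
        ):
            if not 0.0 < v < 1.0:
                raise SizeError(f"{name} must lie in (0, 1), got {v}")
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise SizeError(f"fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train / validation / test partitions of a dataset."""

    train: SpectraDataset
    val: SpectraDataset
    test: SpectraDataset
    train_idx: np.ndarray = field(repr=False, default=None)
    val_idx: np.ndarray = field(repr=False, default=None)
    test_idx: np.ndarray = field(repr=False, default=None)

    def __iter__(self):
        return iter((self.train, self.val, self.test))


def split_train_val_test(
    ds: SpectraDataset,
    spec: SplitSpec | None = None,
    *,
    stratify_by_age: bool = True,
) -> SplitResult:
    """Reproducibly partition a dataset into train / validation / test.

    Sizes follow a nested rounding rule: the test size is ``round(n *
    test_frac)``; of the remainder, the inner-train size is
    ``floor(remainder * train_frac / (train_frac + val_frac))`` and the
    validation set takes what is left.  By default rows are stratified by
    age quintile so every partition spans the observed age range, which
    protects downstream bias-correction fits from unsupported age regions.
    """
    spec = spec or SplitSpec()
    n = ds.n_samples
    if n == 0:
        raise SizeError("cannot split an empty dataset")
    n_test = int(round(n * spec.test_frac))
    n_rest = n - n_test
    n_train = int(math.floor(n_rest * spec.train_frac / (spec.train_frac + spec.val_frac)))
    n_val = n_rest - n_train
    if min(n_train, n_val, n_test) < 1:
        raise SizeError(
            f"split of n={n} with fractions "
            f"({spec.train_frac}, {spec.val_frac}, {spec.test_frac}) leaves an "
            f"empty partition (sizes {n_train}/{n_val}/{n_test})"
        )

    strata = _age_strata(ds.ages) if stratify_by_age else np.zeros(n, dtype=int)
    rng = np.random.default_rng(spec.seed)
    stratum_ids = np.unique(strata)
    stratum_sizes = np.array([(strata == s).sum() for s in stratum_ids])

    alloc_test = _largest_remainder(stratum_sizes * n_test / n, n_test, stratum_sizes)
    remaining = stratum_sizes - alloc_test
    alloc_train = _largest_remainder(stratum_sizes * n_train / n, n_train, remaining)
    alloc_val = remaining - alloc_train  # sums to n_val by construction

    train_idx, val_idx, test_idx = [], [], []
    for s, a_tr, a_va, a_te in zip(stratum_ids, alloc_train, alloc_val, alloc_test):
        members = np.flatnonzero(strata == s)
        members = members[rng.permutation(members.size)]
        train_idx.append(members[:a_tr])
        val_idx.append(members[a_tr : a_tr + a_va])
        test_idx.append(members[a_tr + a_va :])
        assert members.size == a_tr + a_va + a_te
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return SplitResult(
        ds.subset(train_idx),
        ds.subset(val_idx),
        ds.subset(test_idx),
        train_idx,
        val_idx,
        test_idx,
    )


def split_train_val(
    ds: SpectraDataset,
    val_frac: float = 0.3,
    seed: int = 0,
    *,
    stratify_by_age: bool = True,
) -> SplitResult:
    """Two-way train/validation split (empty test set).

    Used when the held-out test set already lives outside the dataset,
    e.g. inside learning-curve replicates.
    """
    if not 0.0 < val_frac < 1.0:
        raise SizeError(f"val_frac must lie in (0, 1), got {val_frac}")
    n = ds.n_samples
    if n == 0:
        raise SizeError("cannot split an empty dataset")
    n_val = int(round(n * val_frac))
    n_train = n - n_val
    if min(n_train, n_val) < 1:
        raise SizeError(f"n={n} with val_frac={val_frac} leaves an empty part")
    strata = _age_strata(ds.ages) if stratify_by_age else np.zeros(n, dtype=int)
    rng = np.random.default_rng(seed)
    stratum_ids = np.unique(strata)
    stratum_sizes = np.array([(strata == s).sum() for s in stratum_ids])
    alloc_val = _largest_remainder(stratum_sizes * n_val / n, n_val, stratum_sizes)
    train_idx, val_idx = [], []
    for s, a_va in zip(stratum_ids, alloc_val):
        members = np.flatnonzero(strata == s)
        members = members[rng.permutation(members.size)]
        val_idx.append(members[:a_va])
        train_idx.append(members[a_va:])
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx))
    empty = np.array([], dtype=int)
    return SplitResult(
        ds.subset(train_idx), ds.subset(val_idx), ds.subset(empty),
        train_idx, val_idx, empty,
    )


def _age_strata(ages: np.ndarray, n_strata: int = 5) -> np.ndarray:
    """Quintile labels; ties collapse strata rather than erroring."""
    qs = np.quantile(ages, np.linspace(0, 1, n_strata + 1)[1:-1])
    return np.searchsorted(np.unique(qs), ages, side="left")


def _largest_remainder(quotas: np.ndarray, total: int, caps: np.ndarray) -> np.ndarray:
    """Integer apportionment of `total` across strata respecting `caps`."""
    base = np.minimum(np.floor(quotas).astype(int), caps)
    short = total - base.sum()
    frac = quotas - np.floor(quotas)
    # Distribute the shortfall to strata with the largest fractional parts
    # (stable order for determinism), skipping strata at capacity.
    order = np.argsort(-frac, kind="stable")
    i = 0
    while short > 0:
        s = order[i % order.size]
        if base[s] < caps[s]:
            base[s] += 1
            short -= 1
        i += 1
        if i > 10 * order.size and short > 0:  # pragma: no cover - safety
            raise SizeError("could not apportion split sizes within capacity")
    return base
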