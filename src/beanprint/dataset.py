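"""Data model and file I/O for replicated NIR spectral datasets.

A :class:`SpectralDataset` couples a strictly increasing wavelength grid (nm)
with an ``n_spectra x n_wavelengths`` absorbance matrix and a per-spectrum
metadata table. Spectra are grouped into physical samples (replicated scans of
the same bag of beans), and every sample carries one country label and an
optional region label. :class:`LabelScheme` maps samples onto the class set of
a discrimination task (country-vs-rest, a set of countries, or a set of
regions), possibly excluding samples.

Files are plain wide CSV: the spectra table has ``spectrum_id`` as its first
column and one column per wavelength (header = wavelength in nm); the metadata
table has columns ``spectrum_id,sample_id,replicate,country,region,variety,
process``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = [
    "spectrum_id",
    "sample_id",
    "replicate",
    "country",
    "region",
    "variety",
    "process",
]

#: label-scheme granularities
LEVELS = ("country-vs-rest", "country-set", "region-set")


class SpectralDataError(ValueError):
    """Raised when a spectral table or its metadata violates an invariant."""


@dataclass
class SpectralDataset:
    """Wavelength grid + absorbance matrix + per-spectrum metadata.

    Parameters
    ----------
    wavelengths_nm : ndarray, shape (n_wavelengths,)
        Strictly increasing wavelength grid in nanometres.
    absorbance : ndarray, shape (n_spectra, n_wavelengths)
        Absorbance values (AU); must be finite.
    meta : DataFrame
        One row per spectrum with columns ``META_COLUMNS``; row order matches
        ``absorbance``.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        wl = self.wavelengths_nm
        if wl.ndim != 1 or wl.size == 0:
            raise SpectralDataError("wavelength grid must be a non-empty 1-D vector")
        if np.any(np.diff(wl) <= 0):
            raise SpectralDataError(
                "wavelengths must be strictly increasing with no duplicates"
            )
        if self.absorbance.shape[1] != wl.size:
            raise SpectralDataError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {wl.size} wavelengths"
            )
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise SpectralDataError(
                f"non-finite absorbance at spectrum row {bad[0]}, "
                f"wavelength column {bad[1]}"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SpectralDataError(f"metadata missing columns: {missing}")
        if len(self.meta) != self.absorbance.shape[0]:
            raise SpectralDataError(
                f"{self.absorbance.shape[0]} spectra but {len(self.meta)} "
                "metadata rows"
            )
        if self.meta["spectrum_id"].duplicated().any():
            dup = self.meta.loc[self.meta["spectrum_id"].duplicated(), "spectrum_id"]
            raise SpectralDataError(f"duplicate spectrum_id: {dup.iloc[0]!r}")
        # each sample maps to exactly one (country, region) pair
        per_sample = self.meta.groupby("sample_id")[["country", "region"]].nunique()
        conflict = per_sample[(per_sample > 1).any(axis=1)]
        if len(conflict):
            raise SpectralDataError(
                f"sample {conflict.index[0]!r} carries more than one "
                "country/region label"
            )

    # -- conveniences -----------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size

    @property
    def sample_ids(self) -> np.ndarray:
        """Unique sample ids in first-appearance order."""
        return self.meta["sample_id"].drop_duplicates().to_numpy()

    def sample_table(self) -> pd.DataFrame:
        """One row per sample with its country/region labels."""
        return (
            self.meta.drop_duplicates("sample_id")
            .set_index("sample_id")[["country", "region"]]
        )

    def take(self, idx: Sequence[int] | np.ndarray) -> "SpectralDataset":
        """Row-subset by spectrum index, preserving order of ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            self.wavelengths_nm.copy(),
            self.absorbance[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def replicate_counts(self) -> pd.Series:
        return self.meta.groupby("sample_id").size()

    def check_replicates(self, expected: int = 4) -> None:
        """Validate the acquisition protocol of ``expected`` scans per sample."""
        counts = self.replicate_counts()
        off = counts[counts != expected]
        if len(off):
            raise SpectralDataError(
                f"sample {off.index[0]!r} has {off.iloc[0]} replicate spectra, "
                f"expected {expected}"
            )


@dataclass
class LabelScheme:
    """Assignment of samples to the classes of one discrimination task.

    ``mapping`` sends sample_id -> class name; samples absent from the mapping
    are excluded from the task (e.g. the single Oceania sample when comparing
    Yemen against the four major producing continents).
    """

    level: str
    classes: list[str]
    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise SpectralDataError(f"level must be one of {LEVELS}, got {self.level!r}")
        unknown = set(self.mapping.values()) - set(self.classes)
        if unknown:
            raise SpectralDataError(
                f"mapping assigns classes not in the declared list: {sorted(unknown)}"
            )

    @classmethod
    def from_metadata(
        cls,
        ds: SpectralDataset,
        level: str = "country-set",
        classes: Sequence[str] | None = None,
        positive: str | None = None,
        rest_label: str = "Other",
    ) -> "LabelScheme":
        """Build a scheme from the country or region column of ``ds``.

        ``country-vs-rest`` folds every country except ``positive`` into
        ``rest_label``. ``region-set`` keeps only samples with a non-empty
        region label. ``classes`` restricts (and orders) the class set;
        samples outside it are excluded.
        """
        table = ds.sample_table()
        if level == "country-vs-rest":
            if positive is None:
                raise SpectralDataError("country-vs-rest needs a positive class")
            mapping = {
                s: (positive if c == positive else rest_label)
                for s, c in table["country"].items()
            }
            return cls(level, [positive, rest_label], mapping)
        column = "region" if level == "region-set" else "country"
        labels = table[column]
        labels = labels[labels.astype(str).str.len() > 0]
        if classes is None:
            classes = sorted(labels.unique())
        mapping = {s: c for s, c in labels.items() if c in set(classes)}
        return cls(level, list(classes), mapping)


# ---------------------------------------------------------------------------
# file I/O


def read_dataset(spectra_path: str | Path, meta_path: str | Path) -> SpectralDataset:
    """Read a wide-CSV spectra table and its metadata table.

    The spectra header row holds wavelengths in nm; the first column is
    ``spectrum_id``. Every spectrum must have a metadata row; metadata rows
    are re-ordered to match the spectra file.
    """
    spectra_path, meta_path = Path(spectra_path), Path(meta_path)
    with open(spectra_path) as fh:
        header = fh.readline().strip().split(",")[1:]
    try:
        wavelengths = np.array([float(c) for c in header])
    except ValueError as exc:
        raise SpectralDataError(
            f"{spectra_path.name}: non-numeric wavelength header: {exc}"
        ) from None
    if len(set(header)) != len(header):
        raise SpectralDataError(
            f"{spectra_path.name}: duplicated wavelength column in header"
        )
    raw = pd.read_csv(spectra_path, index_col=0)
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        r, c = np.argwhere(np.isnan(values))[0]
        raise SpectralDataError(
            f"{spectra_path.name}: non-numeric or missing cell at spectrum "
            f"{raw.index[r]!r}, wavelength {raw.columns[c]}"
        )
    meta = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SpectralDataError(f"{meta_path.name}: missing columns {missing}")
    meta = meta.set_index("spectrum_id", drop=False)
    absent = [sid for sid in raw.index if sid not in meta.index]
    if absent:
        raise SpectralDataError(
            f"{meta_path.name}: no metadata row for spectrum {absent[0]!r}"
        )
    meta = meta.loc[raw.index].reset_index(drop=True)
    meta["replicate"] = meta["replicate"].astype(int)
    return SpectralDataset(wavelengths, values, meta)


def write_dataset(
    ds: SpectralDataset, spectra_path: str | Path, meta_path: str | Path
) -> None:
    """Write the wide-CSV pair read back by :func:`read_dataset`."""
    frame = pd.DataFrame(
        ds.absorbance,
        index=pd.Index(ds.meta["spectrum_id"], name="spectrum_id"),
        columns=[format(w, ".10g") for w in ds.wavelengths_nm],
    )
    frame.to_csv(spectra_path, float_format="%.10g")
    ds.meta[META_COLUMNS].to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# dataset operations


def trim_wavelengths(ds: SpectralDataset, lo_nm: float, hi_nm: float) -> SpectralDataset:
    """Keep wavelengths with ``lo_nm <= lambda <= hi_nm`` (inclusive both ends)."""
    if lo_nm >= hi_nm:
        raise SpectralDataError(f"empty window: lo {lo_nm} >= hi {hi_nm}")
    keep = (ds.wavelengths_nm >= lo_nm) & (ds.wavelengths_nm <= hi_nm)
    if not keep.any():
        raise SpectralDataError(
            f"window {lo_nm}-{hi_nm} nm does not overlap the grid "
            f"({ds.wavelengths_nm[0]:g}-{ds.wavelengths_nm[-1]:g} nm)"
        )
    return SpectralDataset(
        ds.wavelengths_nm[keep], ds.absorbance[:, keep], ds.meta.reset_index(drop=True)
    )


def subset_by_labels(
    ds: SpectralDataset, scheme: LabelScheme
) -> tuple[SpectralDataset, np.ndarray]:
    """Drop spectra of excluded samples; return the subset and aligned labels.

    Every retained sample keeps all of its replicate spectra. Raises if any
    declared class ends up with zero spectra.
    """
    labels = ds.meta["sample_id"].map(dict(scheme.mapping))
    keep = labels.notna().to_numpy()
    if not keep.any():
        raise SpectralDataError("scheme excludes every sample in the dataset")
    sub = ds.take(np.flatnonzero(keep))
    y = labels[keep].to_numpy(dtype=object)
    present = set(y)
    empty = [c for c in scheme.classes if c not in present]
    if empty:
        raise SpectralDataError(f"class {empty[0]!r} has zero spectra after subsetting")
    return sub, y
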