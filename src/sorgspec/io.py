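"""Spectral and reference-chemistry tables: containers, CSV I/O, alignment.

The on-disk dialect is plain UTF-8 CSV.  A spectra file has a ``sample_id``
column, an optional ``format`` column, and one numeric column per wavenumber
(cm^-1).  A reference file has ``sample_id`` plus the eight analyte columns
(g kg^-1) and optionally a ``grade`` column; unknown extra columns are kept
as metadata and ignored by the analytics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical analyte names, g kg^-1
ANALYTES = (
    "starch",
    "protein",
    "fat",
    "tannin",
    "cellulose",
    "hemicellulose",
    "lignin",
    "ash",
)

#: recognised per-sample scan formats
SAMPLE_FORMATS = (
    "whole_grain",
    "whole_grain_flour",
    "hulled_flour",
    "hull_less_flour",
)


class SpectraFormatError(ValueError):
    """Malformed spectra/reference file (bad header, non-numeric grid...)."""


class SpectraValidationError(ValueError):
    """Structurally valid file whose content violates an invariant."""


@dataclass
class SpectraSet:
    """Absorbance spectra on a common, strictly ascending wavenumber grid.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample labels, one per row of ``absorbance``.
    wavenumbers : ndarray, shape (p,)
        Strictly increasing grid in cm^-1.
    absorbance : ndarray, shape (n, p)
        Absorbance (log 1/R) values; finite, no missing cells.
    sample_format : list of str, optional
        Per-sample tag from :data:`SAMPLE_FORMATS`.
    """

    sample_ids: list[str]
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_format: list[str] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraValidationError("duplicate sample_id")
        if self.absorbance.shape != (len(self.sample_ids), self.wavenumbers.size):
            raise SpectraValidationError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavenumbers.size} wavenumbers"
            )
        if not np.all(np.isfinite(self.wavenumbers)):
            raise SpectraValidationError("non-finite wavenumber")
        if np.any(np.diff(self.wavenumbers) <= 0):
            # canonicalise: sort ascending (FT instruments often export descending)
            order = np.argsort(self.wavenumbers)
            if np.any(np.diff(self.wavenumbers[order]) <= 0):
                raise SpectraValidationError("duplicate wavenumbers in grid")
            self.wavenumbers = self.wavenumbers[order]
            self.absorbance = self.absorbance[:, order]
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraValidationError("missing or non-finite absorbance value")
        if self.sample_format is not None:
            self.sample_format = [str(f) for f in self.sample_format]
            if len(self.sample_format) != len(self.sample_ids):
                raise SpectraValidationError("sample_format length mismatch")
            bad = set(self.sample_format) - set(SAMPLE_FORMATS)
            if bad:
                raise SpectraValidationError(f"unknown sample format(s): {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return int(self.wavenumbers.size)

    def subset(self, indices) -> "SpectraSet":
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in indices],
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[indices],
            sample_format=(
                [self.sample_format[i] for i in indices]
                if self.sample_format is not None
                else None
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.absorbance,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.wavenumbers,
        )
        if self.sample_format is not None:
            df.insert(0, "format", self.sample_format)
        return df


@dataclass
class ReferenceChemistry:
    """Wet-chemistry reference values for the eight analytes (g kg^-1)."""

    sample_ids: list[str]
    analytes: pd.DataFrame  # columns = ANALYTES, index = sample_ids
    grade: list[str] | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraValidationError("duplicate sample_id")
        missing = set(ANALYTES) - set(self.analytes.columns)
        if missing:
            raise SpectraValidationError(f"missing analyte column(s): {sorted(missing)}")
        self.analytes = self.analytes.loc[:, list(ANALYTES)].astype(float)
        self.analytes.index = pd.Index(self.sample_ids, name="sample_id")
        values = self.analytes.to_numpy()
        if not np.all(np.isfinite(values)):
            raise SpectraValidationError("non-finite analyte value")
        if np.any(values < 0):
            raise SpectraValidationError("negative analyte value")
        if self.grade is not None and len(self.grade) != len(self.sample_ids):
            raise SpectraValidationError("grade length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def value(self, sample_id: str, analyte: str) -> float:
        return float(self.analytes.at[str(sample_id), analyte])

    def column(self, analyte: str) -> np.ndarray:
        if analyte not in ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}")
        return self.analytes[analyte].to_numpy()

    def subset(self, indices) -> "ReferenceChemistry":
        indices = np.asarray(indices, dtype=int)
        ids = [self.sample_ids[i] for i in indices]
        return ReferenceChemistry(
            sample_ids=ids,
            analytes=self.analytes.iloc[indices].copy(),
            grade=[self.grade[i] for i in indices] if self.grade is not None else None,
            metadata=self.metadata.iloc[indices].copy() if self.metadata is not None else None,
        )


@dataclass
class AlignedDataset:
    """A SpectraSet and ReferenceChemistry sharing one ordered sample_id list."""

    spectra: SpectraSet
    reference: ReferenceChemistry
    dropped_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra.sample_ids != self.reference.sample_ids:
            raise SpectraValidationError("spectra/reference sample_id sequences differ")

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples

    def subset(self, indices) -> "AlignedDataset":
        return AlignedDataset(self.spectra.subset(indices), self.reference.subset(indices))


def read_spectra(path, **read_csv_kwargs) -> SpectraSet:
    """Read a wide-format spectra CSV into a :class:`SpectraSet`.

    Columns other than ``sample_id`` / ``format`` must have numeric
    wavenumber headers; descending grids are reordered ascending.
    """
    df = pd.read_csv(path, dtype={"sample_id": str}, **read_csv_kwargs)
    if "sample_id" not in df.columns:
        raise SpectraFormatError("spectra CSV must have a 'sample_id' column")
    fmt = df["format"].tolist() if "format" in df.columns else None
    wn_cols = [c for c in df.columns if c not in ("sample_id", "format")]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber header: {exc}") from None
    block = df[wn_cols]
    if block.isna().any().any():
        raise SpectraValidationError("missing absorbance cell(s)")
    return SpectraSet(
        sample_ids=df["sample_id"].tolist(),
        wavenumbers=wavenumbers,
        absorbance=block.to_numpy(dtype=float),
        sample_format=fmt,
    )


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` as CSV (lossless to ~12 significant digits)."""
    df = spectra.to_frame().reset_index()
    df.columns = ["sample_id"] + (
        ["format"] if spectra.sample_format is not None else []
    ) + [f"{w:.12g}" for w in spectra.wavenumbers]
    df.to_csv(path, index=False, float_format="%.12g")


def read_reference(path) -> ReferenceChemistry:
    """Read a reference-chemistry CSV (sample_id + eight analytes, g kg^-1)."""
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except pd.errors.EmptyDataError:
        raise SpectraFormatError("empty reference file") from None
    if "sample_id" not in df.columns:
        raise SpectraFormatError("reference CSV must have a 'sample_id' column")
    if df.shape[0] == 0:
        raise SpectraValidationError("reference file has no samples")
    grade = df["grade"].tolist() if "grade" in df.columns else None
    known = set(ANALYTES) | {"sample_id", "grade"}
    extra = [c for c in df.columns if c not in known]
    return ReferenceChemistry(
        sample_ids=df["sample_id"].tolist(),
        analytes=df.reindex(columns=list(ANALYTES)),
        grade=grade,
        metadata=df[extra].copy() if extra else None,
    )


def write_reference(reference: ReferenceChemistry, path) -> None:
    df = reference.analytes.reset_index()
    if reference.grade is not None:
        df["grade"] = reference.grade
    df.to_csv(path, index=False, float_format="%.12g")


def align_dataset(spectra: SpectraSet, reference: ReferenceChemistry) -> AlignedDataset:
    """Inner-join spectra and reference on sample_id, preserving spectra order.

    Samples present in only one table are dropped with a warning and recorded
    in ``dropped_ids``.  Raises if the two tables share no sample.
    """
    ref_pos = {sid: i for i, sid in enumerate(reference.sample_ids)}
    keep_spec, keep_ref, dropped = [], [], []
    for i, sid in enumerate(spectra.sample_ids):
        if sid in ref_pos:
            keep_spec.append(i)
            keep_ref.append(ref_pos[sid])
        else:
            dropped.append(sid)
    dropped.extend(sid for sid in reference.sample_ids if sid not in set(spectra.sample_ids))
    if not keep_spec:
        raise SpectraValidationError("spectra and reference share no sample_id")
    if dropped:
        warnings.warn(f"align_dataset dropped {len(dropped)} unmatched sample(s)", stacklevel=2)
    return AlignedDataset(
        spectra=spectra.subset(keep_spec),
        reference=reference.subset(keep_ref),
        dropped_ids=dropped,
    )
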