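"""Density datasets: the training currency of the surrogate study.

A :class:`DensityDataset` is an ordered table of Lennard-Jones parameter
vectors with the bulk-phase density (kg/m^3) each one produced and a validity
flag marking failed pseudo-simulations.  Datasets round-trip losslessly
through delimited text with the schema::

    sigma_C,sigma_H,eps_C,eps_H,density,valid

(units nm, nm, kJ/mol, kJ/mol, kg/m^3, 0/1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError
from .space import LJ_PARAM_NAMES

log = logging.getLogger(__name__)

DATASET_COLUMNS = list(LJ_PARAM_NAMES) + ["density", "valid"]


@dataclass(frozen=True)
class DensityRecord:
    """One (parameter set -> density) observation."""

    sigma_C: float
    sigma_H: float
    eps_C: float
    eps_H: float
    density: float
    valid: bool


@dataclass
class DensityDataset:
    """Named, ordered collection of density records backed by a DataFrame."""

    name: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ContractError(f"dataset '{self.name}' missing columns {missing}")
        self.frame = self.frame[DATASET_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def params(self) -> np.ndarray:
        """Parameter vectors as an (n, 4) array in canonical order."""
        return self.frame[list(LJ_PARAM_NAMES)].to_numpy(dtype=float)

    @property
    def densities(self) -> np.ndarray:
        return self.frame["density"].to_numpy(dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return self.frame["valid"].to_numpy(dtype=bool)

    def all_valid(self) -> bool:
        return bool(self.valid.all())

    def records(self) -> list[DensityRecord]:
        return [
            DensityRecord(
                r.sigma_C, r.sigma_H, r.eps_C, r.eps_H, r.density, bool(r.valid)
            )
            for r in self.frame.itertuples(index=False)
        ]

    def subset(self, indices: np.ndarray, name: str | None = None) -> "DensityDataset":
        return DensityDataset(
            name or self.name, self.frame.iloc[np.asarray(indices)].reset_index(drop=True)
        )

    @classmethod
    def from_arrays(
        cls,
        name: str,
        params: np.ndarray,
        densities: np.ndarray,
        valid: np.ndarray | None = None,
    ) -> "DensityDataset":
        params = np.asarray(params, dtype=float)
        densities = np.asarray(densities, dtype=float)
        if params.ndim != 2 or params.shape[1] != 4:
            raise ContractError(f"params must be (n, 4), got {params.shape}")
        if len(densities) != len(params):
            raise ContractError("params/densities length mismatch")
        if valid is None:
            valid = np.ones(len(params), dtype=bool)
        frame = pd.DataFrame(params, columns=list(LJ_PARAM_NAMES))
        frame["density"] = densities
        frame["valid"] = np.asarray(valid, dtype=bool)
        return cls(name, frame)


def preprocess(
    ds: DensityDataset, plaus_low: float = 0.0, plaus_high: float = 1500.0
) -> tuple[DensityDataset, int]:
    """Drop invalid records and densities outside the plausibility window.

    Keeps exactly the records with ``valid`` set and
    ``plaus_low < density <= plaus_high`` (order preserved); returns the
    filtered dataset and the number of removed records.  The default window
    (0, 1500] kg/m^3 brackets the range liquid alkane pseudo-simulations can
    plausibly produce.
    """
    if not plaus_low < plaus_high:
        raise ContractError(f"need plaus_low < plaus_high, got ({plaus_low}, {plaus_high})")
    keep = ds.valid & (ds.densities > plaus_low) & (ds.densities <= plaus_high)
    removed = int((~keep).sum())
    if removed:
        log.info("preprocess(%s): removed %d of %d records", ds.name, removed, len(ds))
    return ds.subset(np.flatnonzero(keep)), removed


def write_dataset(path: str | Path, ds: DensityDataset) -> None:
    """Write a dataset as delimited text at 12 significant digits."""
    frame = ds.frame.copy()
    frame["valid"] = frame["valid"].astype(int)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_dataset(path: str | Path, name: str | None = None) -> DensityDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises :class:`FormatError` naming the offending column or the 1-based
    line number of the first malformed row.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    missing = [c for c in DATASET_COLUMNS if c not in raw.columns]
    extra = [c for c in raw.columns if c not in DATASET_COLUMNS]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    converted = {}
    for col in DATASET_COLUMNS:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() & raw[col].notna()
        if bad.any() or raw[col].isna().any():
            row = int((bad | raw[col].isna()).idxmax())
            raise FormatError(
                f"{path}: malformed value in column '{col}' at line {row + 2}"
            )
        converted[col] = values
    frame = pd.DataFrame(converted)
    frame["valid"] = frame["valid"].astype(float).astype(bool)
    return DensityDataset(name or path.stem, frame)
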