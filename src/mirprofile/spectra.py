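"""Container for sets of mid-infrared spectra with per-sample metadata.

A :class:`SpectraSet` couples a common wavenumber grid (cm^-1) with an
absorbance matrix (samples x points, AU) and a metadata table carrying, per
sample, the spiked analyte concentration (mg/100 mL), acquisition day,
replicate index and role (``calibration`` / ``validation`` / ``blank``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("calibration", "validation", "blank")

META_COLUMNS = ["sample_id", "la_conc", "day", "replicate", "role"]


@dataclass
class SpectraSet:
    """Wavenumber grid + absorbance matrix + per-sample metadata."""

    wavenumbers: np.ndarray  # (p,), cm^-1, strictly increasing
    absorbance: np.ndarray  # (n, p), AU
    meta: pd.DataFrame  # columns META_COLUMNS, one row per sample

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has "
                f"{self.wavenumbers.size} points"
            )
        if self.absorbance.shape[0] != len(self.meta):
            raise ValueError("metadata row count does not match sample count")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if (self.meta["la_conc"] < 0).any():
            raise ValueError("la_conc must be non-negative")
        blanks = self.meta["role"] == "blank"
        if (self.meta.loc[blanks, "la_conc"] != 0).any():
            raise ValueError("blank samples must have la_conc == 0")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    @property
    def concentrations(self) -> np.ndarray:
        return self.meta["la_conc"].to_numpy(dtype=float)

    def select_points(self, mask: np.ndarray) -> "SpectraSet":
        """Return a copy restricted to grid points where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_points:
            raise ValueError("mask length does not match number of points")
        if not mask.any():
            raise ValueError("point selection is empty")
        return SpectraSet(self.wavenumbers[mask], self.absorbance[:, mask], self.meta.copy())

    def select_samples(self, idx: np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            self.wavenumbers.copy(),
            self.absorbance[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def with_absorbance(self, absorbance: np.ndarray, wavenumbers: np.ndarray | None = None) -> "SpectraSet":
        wn = self.wavenumbers.copy() if wavenumbers is None else wavenumbers
        return SpectraSet(wn, absorbance, self.meta.copy())

    # ------------------------------------------------------------------ I/O
    def to_csv(self, spectra_path: str | Path, meta_path: str | Path) -> None:
        """Write wide spectra CSV (header row = wavenumbers) + metadata CSV."""
        df = pd.DataFrame(self.absorbance, columns=[f"{w:.6g}" for w in self.wavenumbers])
        df.insert(0, "sample_id", self.meta["sample_id"].to_numpy())
        df.to_csv(spectra_path, index=False)
        self.meta[META_COLUMNS].to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, spectra_path: str | Path, meta_path: str | Path) -> "SpectraSet":
        df = pd.read_csv(spectra_path)
        meta = pd.read_csv(meta_path)
        if list(df["sample_id"]) != list(meta["sample_id"]):
            raise ValueError("sample_id mismatch between spectra and metadata files")
        wn = np.array([float(c) for c in df.columns[1:]])
        return cls(wn, df.iloc[:, 1:].to_numpy(dtype=float), meta)
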