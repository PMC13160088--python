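"""Core domain types for single-cell Raman/SERS spectral cytometry.

A :class:`SpectraSet` is the unit every pipeline stage consumes and
produces: a shared wavenumber axis plus an ordered list of single-cell
:class:`Spectrum` records with acquisition metadata (donor, class label,
time since co-culture start, acquisition batch).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassLabel",
    "BiochemicalClass",
    "WavenumberAxis",
    "Spectrum",
    "SpectraSet",
    "BandDefinition",
    "band_channels",
]


class ClassLabel(str, Enum):
    """Cell condition / cell type labels used across the pipeline."""

    CAR = "CAR"
    MOCK = "MOCK"
    UNSTIM = "UNSTIM"
    TCELL = "TCELL"
    BCELL_PRIMARY = "BCELL_PRIMARY"
    BCELL_JEKO = "BCELL_JEKO"
    RBC = "RBC"
    OTHER = "OTHER"


class BiochemicalClass(str, Enum):
    """Biochemical assignment of a vibrational band."""

    PROTEIN_AROMATIC = "PROTEIN_AROMATIC"
    NUCLEIC_ACID = "NUCLEIC_ACID"
    MITOCHONDRIAL = "MITOCHONDRIAL"
    MEMBRANE_LIPID = "MEMBRANE_LIPID"
    HEMOPROTEIN = "HEMOPROTEIN"


_VALID_LABELS = frozenset(m.value for m in ClassLabel)

# Physical limits of the Raman shift axis accepted by the pipeline; the
# biological fingerprint window used throughout is 700-1700 cm^-1.
AXIS_MIN_CM1 = 400.0
AXIS_MAX_CM1 = 3200.0


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1, shared by a SpectraSet."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavenumber axis must be a 1-D array of length >= 2")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if vals[0] < AXIS_MIN_CM1 or vals[-1] > AXIS_MAX_CM1:
            raise ValueError(
                f"axis must lie within [{AXIS_MIN_CM1}, {AXIS_MAX_CM1}] cm^-1"
            )

    @property
    def n_channels(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


def default_axis(start: float = 700.0, stop: float = 1700.0, step: float = 1.0) -> WavenumberAxis:
    """Default working axis: the 700-1700 cm^-1 fingerprint region at 1 cm^-1."""
    n = int(round((stop - start) / step)) + 1
    return WavenumberAxis(start + step * np.arange(n))


@dataclass
class Spectrum:
    """One single-cell measurement: raw intensities plus acquisition metadata."""

    intensities: np.ndarray
    spectrum_id: str
    donor_id: str
    class_label: str
    batch_id: str
    time_min: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError(f"spectrum {self.spectrum_id!r}: intensities must be 1-D")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"spectrum {self.spectrum_id!r}: non-finite intensity")
        if isinstance(self.class_label, ClassLabel):
            self.class_label = self.class_label.value
        if self.class_label not in _VALID_LABELS:
            raise ValueError(
                f"spectrum {self.spectrum_id!r}: unknown class label "
                f"{self.class_label!r}"
            )
        if self.time_min is not None:
            self.time_min = float(self.time_min)
            if not np.isfinite(self.time_min):
                raise ValueError(f"spectrum {self.spectrum_id!r}: non-finite time_min")


class SpectraSet:
    """An ordered collection of spectra on one shared wavenumber axis.

    Order is stable under preprocessing: excluded spectra are removed,
    the rest keep their relative (acquisition) order.
    """

    def __init__(
        self,
        axis: WavenumberAxis,
        spectra: Sequence[Spectrum],
        provenance: Iterable[str] = (),
    ) -> None:
        self.axis = axis
        self.spectra = list(spectra)
        self.provenance: list[str] = list(provenance)
        seen: set[str] = set()
        for s in self.spectra:
            if s.intensities.size != axis.n_channels:
                raise ValueError(
                    f"spectrum {s.spectrum_id!r} has {s.intensities.size} channels, "
                    f"axis has {axis.n_channels}"
                )
            if s.spectrum_id in seen:
                raise ValueError(f"duplicate spectrum_id {s.spectrum_id!r}")
            seen.add(s.spectrum_id)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    # ---- array views -------------------------------------------------

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_channels) float matrix of intensities."""
        if not self.spectra:
            return np.empty((0, self.axis.n_channels))
        return np.vstack([s.intensities for s in self.spectra])

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spectrum_id": [s.spectrum_id for s in self.spectra],
                "donor_id": [s.donor_id for s in self.spectra],
                "class_label": [s.class_label for s in self.spectra],
                "time_min": [s.time_min for s in self.spectra],
                "batch_id": [s.batch_id for s in self.spectra],
            }
        )

    def ids(self) -> list[str]:
        return [s.spectrum_id for s in self.spectra]

    def labels(self) -> np.ndarray:
        return np.array([s.class_label for s in self.spectra])

    def donors(self) -> np.ndarray:
        return np.array([s.donor_id for s in self.spectra])

    def times(self) -> np.ndarray:
        """time_min per spectrum; raises if any spectrum lacks a time."""
        out = np.empty(len(self.spectra))
        for i, s in enumerate(self.spectra):
            if s.time_min is None:
                raise ValueError(f"spectrum {s.spectrum_id!r} has no time_min")
            out[i] = s.time_min
        return out

    # ---- derived sets ------------------------------------------------

    def subset(self, indices: Sequence[int], note: str | None = None) -> "SpectraSet":
        spectra = [self.spectra[i] for i in indices]
        prov = self.provenance + ([note] if note else [])
        return SpectraSet(self.axis, spectra, prov)

    def select(self, mask: np.ndarray, note: str | None = None) -> "SpectraSet":
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        return self.subset(idx.tolist(), note)

    def with_intensities(self, matrix: np.ndarray, note: str | None = None) -> "SpectraSet":
        """Copy of the set with replaced intensities (same metadata and order)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self.spectra), self.axis.n_channels):
            raise ValueError("replacement matrix shape mismatch")
        spectra = [
            Spectrum(
                intensities=matrix[i],
                spectrum_id=s.spectrum_id,
                donor_id=s.donor_id,
                class_label=s.class_label,
                batch_id=s.batch_id,
                time_min=s.time_min,
            )
            for i, s in enumerate(self.spectra)
        ]
        prov = self.provenance + ([note] if note else [])
        return SpectraSet(self.axis, spectra, prov)

    def log(self, note: str) -> None:
        self.provenance.append(note)


@dataclass(frozen=True)
class BandDefinition:
    """A wavenumber band [center - width/2, center + width/2], both ends closed."""

    center_cm1: float
    biochemical_class: BiochemicalClass
    width_cm1: float = 20.0

    @property
    def low(self) -> float:
        return self.center_cm1 - self.width_cm1 / 2.0

    @property
    def high(self) -> float:
        return self.center_cm1 + self.width_cm1 / 2.0


def band_channels(band: BandDefinition, axis: WavenumberAxis) -> np.ndarray:
    """Contiguous channel indices whose wavenumbers lie in the closed band.

    Endpoints are inclusive; a small tolerance guards against floating
    representation of grid values.
    """
    vals = axis.values
    tol = 1e-9 * max(1.0, abs(band.high))
    if band.low < vals[0] - tol or band.high > vals[-1] + tol:
        raise ValueError(
            f"band [{band.low}, {band.high}] outside axis range "
            f"[{vals[0]}, {vals[-1]}]"
        )
    mask = (vals >= band.low - tol) & (vals <= band.high + tol)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"band [{band.low}, {band.high}] contains no axis channel"
        )
    return idx
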