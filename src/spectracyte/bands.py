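"""Default vibrational band catalog and the activation-tracking band panel.

Band assignments follow standard Raman biochemistry of immune cells:
adenine ring breathing near 728, DNA backbone PO2- stretch near 1092-1095,
phenylalanine ring breathing at 1002, amide III around 1222-1262, broad
protein/aromatic structure near 1560-1660, cytochrome-c-associated
mitochondrial modes at 755/1130/1310/1584, membrane phospholipid headgroup
modes near 719/875, and hemoprotein markers at 1128/1225/1567/1622.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spectra import BandDefinition, BiochemicalClass

__all__ = ["CatalogBand", "BandCatalog", "default_catalog", "BandPanel", "default_panel"]

_P = BiochemicalClass.PROTEIN_AROMATIC
_N = BiochemicalClass.NUCLEIC_ACID
_M = BiochemicalClass.MITOCHONDRIAL
_L = BiochemicalClass.MEMBRANE_LIPID
_H = BiochemicalClass.HEMOPROTEIN


@dataclass(frozen=True)
class CatalogBand:
    """A generator catalog entry: band center, peak FWHM and base amplitude."""

    center_cm1: float
    width_cm1: float
    base_amplitude: float
    biochemical_class: BiochemicalClass


@dataclass(frozen=True)
class BandCatalog:
    """Collection of catalog bands used by the synthetic generator."""

    bands: tuple[CatalogBand, ...]

    def centers(self, biochemical_class: BiochemicalClass | None = None) -> list[float]:
        return [
            b.center_cm1
            for b in self.bands
            if biochemical_class is None or b.biochemical_class is biochemical_class
        ]

    def amplitudes(self) -> list[float]:
        return [b.base_amplitude for b in self.bands]


# Base amplitudes are relative peak heights of a resting T cell; they are
# free parameters of the generator, not measured values.  FWHM 12 cm^-1 is a
# typical fingerprint-region Raman linewidth.
_DEFAULT_FWHM = 12.0

_DEFAULT_BANDS: tuple[CatalogBand, ...] = (
    # nucleic acid
    CatalogBand(728.0, _DEFAULT_FWHM, 1.00, _N),
    CatalogBand(964.0, _DEFAULT_FWHM, 0.40, _N),
    CatalogBand(1095.0, _DEFAULT_FWHM, 0.70, _N),
    CatalogBand(1334.0, _DEFAULT_FWHM, 0.60, _N),
    CatalogBand(1453.0, _DEFAULT_FWHM, 0.50, _N),
    # protein / aromatic
    CatalogBand(898.0, _DEFAULT_FWHM, 0.50, _P),
    CatalogBand(1002.0, _DEFAULT_FWHM, 1.00, _P),
    CatalogBand(1025.0, _DEFAULT_FWHM, 0.50, _P),
    CatalogBand(1222.0, _DEFAULT_FWHM, 0.40, _P),
    CatalogBand(1262.0, _DEFAULT_FWHM, 0.50, _P),
    CatalogBand(1602.0, _DEFAULT_FWHM, 0.70, _P),
    CatalogBand(1660.0, _DEFAULT_FWHM, 0.80, _P),
    # mitochondrial (cytochrome c associated)
    CatalogBand(755.0, _DEFAULT_FWHM, 0.50, _M),
    CatalogBand(1130.0, _DEFAULT_FWHM, 0.40, _M),
    CatalogBand(1310.0, _DEFAULT_FWHM, 0.40, _M),
    CatalogBand(1584.0, _DEFAULT_FWHM, 0.50, _M),
    # membrane / lipid
    CatalogBand(719.0, _DEFAULT_FWHM, 0.30, _L),
    CatalogBand(875.0, _DEFAULT_FWHM, 0.40, _L),
    CatalogBand(1460.0, _DEFAULT_FWHM, 0.50, _L),
    # hemoprotein
    CatalogBand(1128.0, _DEFAULT_FWHM, 0.30, _H),
    CatalogBand(1225.0, _DEFAULT_FWHM, 0.20, _H),
    CatalogBand(1567.0, _DEFAULT_FWHM, 0.30, _H),
    CatalogBand(1622.0, _DEFAULT_FWHM, 0.30, _H),
)


def default_catalog() -> BandCatalog:
    return BandCatalog(_DEFAULT_BANDS)


# Analysis bands tracked through time (20 cm^-1 wide, closed intervals).
PROTEIN_PANEL_CENTERS = (898.0, 1002.0, 1025.0, 1222.0, 1262.0, 1602.0)
NUCLEIC_PANEL_CENTERS = (728.0, 1092.0, 1334.0)


@dataclass(frozen=True)
class BandPanel:
    """The band panel whose intensities are tracked over activation time."""

    protein_bands: tuple[BandDefinition, ...] = field(
        default_factory=lambda: tuple(
            BandDefinition(c, _P, 20.0) for c in PROTEIN_PANEL_CENTERS
        )
    )
    nucleic_bands: tuple[BandDefinition, ...] = field(
        default_factory=lambda: tuple(
            BandDefinition(c, _N, 20.0) for c in NUCLEIC_PANEL_CENTERS
        )
    )

    def by_class(self) -> dict[BiochemicalClass, tuple[BandDefinition, ...]]:
        return {_P: self.protein_bands, _N: self.nucleic_bands}

    def all_bands(self) -> tuple[BandDefinition, ...]:
        return self.protein_bands + self.nucleic_bands


def default_panel() -> BandPanel:
    return BandPanel()
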