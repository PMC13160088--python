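"""Delimited tabular readers/writers for SpectraSets.

Two comma-delimited UTF-8 dialects:

* ``wide_table`` — one row per spectrum: metadata columns
  ``spectrum_id, donor_id, class_label, time_min, batch_id`` followed by one
  intensity column per wavenumber, headed by the numeric wavenumber printed
  with up to 4 decimals.
* ``long_table`` — a spectra table ``(spectrum_id, wavenumber, intensity)``
  plus a metadata table keyed by ``spectrum_id`` stored alongside it
  (``<stem>.meta<suffix>``).

Intensities and metadata round-trip bit-exactly (floats are written at full
repr precision).  A missing ``time_min`` is encoded as an empty field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import SpectraSet, Spectrum, WavenumberAxis

__all__ = ["read_spectra", "write_spectra"]

_META_COLUMNS = ["spectrum_id", "donor_id", "class_label", "time_min", "batch_id"]
_STR_DTYPES = {c: str for c in ("spectrum_id", "donor_id", "class_label", "batch_id")}


def _format_wavenumber(v: float) -> str:
    s = f"{v:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta" + path.suffix)


def _time_of(row_value) -> float | None:
    if row_value is None or (isinstance(row_value, float) and np.isnan(row_value)):
        return None
    return float(row_value)


def write_spectra(data: SpectraSet, path: str | Path, format: str = "wide_table") -> None:
    """Write a SpectraSet to ``path`` in the given dialect."""
    path = Path(path)
    meta = data.metadata_frame()
    if format == "wide_table":
        wide = meta.copy()
        mat = data.intensity_matrix()
        cols = [_format_wavenumber(v) for v in data.axis.values]
        wide = pd.concat(
            [wide, pd.DataFrame(mat, columns=cols, index=wide.index)], axis=1
        )
        # repr round-trips float64 exactly; pandas' default float writer
        # drops the last significant digit
        wide.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    elif format == "long_table":
        n, p = len(data), data.axis.n_channels
        long = pd.DataFrame(
            {
                "spectrum_id": np.repeat(np.asarray(data.ids(), dtype=object), p),
                "wavenumber": np.tile(data.axis.values, n),
                "intensity": data.intensity_matrix().ravel(),
            }
        )
        long.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
        meta.to_csv(_meta_path(path), index=False, float_format=lambda v: repr(float(v)))
    else:
        raise ValueError(f"unknown format {format!r}")


def _validate_meta_columns(df: pd.DataFrame, path: Path) -> None:
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required metadata column(s) {missing}")


def read_spectra(
    path: str | Path,
    format: str = "wide_table",
    metadata_path: str | Path | None = None,
    axis: WavenumberAxis | None = None,
) -> SpectraSet:
    """Read a SpectraSet written by :func:`write_spectra`.

    ``axis`` is only needed to type an empty long table, where no wavenumber
    grid can be recovered from the data.
    """
    path = Path(path)
    if format == "wide_table":
        df = pd.read_csv(path, dtype=_STR_DTYPES, float_precision="round_trip")
        _validate_meta_columns(df, path)
        wn_cols = [c for c in df.columns if c not in _META_COLUMNS]
        try:
            wns = np.array([float(c) for c in wn_cols])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric wavenumber column header") from exc
        ax = WavenumberAxis(wns)
        spectra = [
            Spectrum(
                intensities=df.loc[i, wn_cols].to_numpy(dtype=float),
                spectrum_id=df.loc[i, "spectrum_id"],
                donor_id=df.loc[i, "donor_id"],
                class_label=df.loc[i, "class_label"],
                batch_id=df.loc[i, "batch_id"],
                time_min=_time_of(df.loc[i, "time_min"]),
            )
            for i in df.index
        ]
        return SpectraSet(ax, spectra, [f"read wide_table {path.name}"])

    if format == "long_table":
        mpath = Path(metadata_path) if metadata_path is not None else _meta_path(path)
        long = pd.read_csv(path, dtype={"spectrum_id": str}, float_precision="round_trip")
        meta = pd.read_csv(mpath, dtype=_STR_DTYPES, float_precision="round_trip")
        _validate_meta_columns(meta, mpath)
        for col in ("spectrum_id", "wavenumber", "intensity"):
            if col not in long.columns:
                raise ValueError(f"{path}: missing column {col!r} in long table")
        if len(long) == 0:
            if axis is None:
                raise ValueError(
                    f"{path}: empty long table; pass an explicit axis to read it"
                )
            return SpectraSet(axis, [], [f"read long_table {path.name}"])
        groups = {sid: g for sid, g in long.groupby("spectrum_id", sort=False)}
        first_id = meta["spectrum_id"].iloc[0] if len(meta) else long["spectrum_id"].iloc[0]
        ax = WavenumberAxis(groups[first_id]["wavenumber"].to_numpy(dtype=float))
        spectra = []
        for _, row in meta.iterrows():
            sid = row["spectrum_id"]
            if sid not in groups:
                raise ValueError(f"{path}: spectrum {sid!r} missing from long table")
            g = groups[sid]
            wns = g["wavenumber"].to_numpy(dtype=float)
            if wns.shape != ax.values.shape or not np.array_equal(wns, ax.values):
                raise ValueError(
                    f"{path}: spectrum {sid!r} has a mismatched wavenumber axis"
                )
            spectra.append(
                Spectrum(
                    intensities=g["intensity"].to_numpy(dtype=float),
                    spectrum_id=sid,
                    donor_id=row["donor_id"],
                    class_label=row["class_label"],
                    batch_id=row["batch_id"],
                    time_min=_time_of(row["time_min"]),
                )
            )
        return SpectraSet(ax, spectra, [f"read long_table {path.name}"])

    raise ValueError(f"unknown format {format!r}")
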