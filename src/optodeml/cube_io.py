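"""Hyperspectral cube and calibration-table I/O.

Cubes are stored as ENVI header (.hdr) + band-sequential raw binary (.raw)
pairs, little-endian, float32 by default, with a mandatory wavelength list —
the de-facto interchange format of the hyperspectral camera ecosystem.
Calibration tables are plain CSV: canonical column order is ``ph, po2,
provenance`` followed by one column per wavelength, named by its band centre
in nm.  Malformed inputs are rejected with errors naming the offending field;
nothing is silently coerced.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCube",
    "CalibrationTable",
    "CubeFormatError",
    "TableFormatError",
    "read_cube",
    "write_cube",
    "read_table",
    "write_table",
]


class CubeFormatError(ValueError):
    """Raised when an ENVI header/binary pair is inconsistent or malformed."""


class TableFormatError(ValueError):
    """Raised when a calibration-table CSV is malformed."""


# ENVI numeric data-type codes
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectralCube:
    """An H x W x B intensity array with an explicit wavelength axis (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise CubeFormatError(
                f"cube data must be 3-D (H, W, bands), got shape {self.data.shape}"
            )
        if self.data.shape[2] != self.wavelengths.size:
            raise CubeFormatError(
                f"band count mismatch: data has {self.data.shape[2]} bands but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise CubeFormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise CubeFormatError("cube intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel(self, row: int, col: int) -> np.ndarray:
        """Spectrum at 0-based (row, col)."""
        return self.data[row, col, :]


@dataclass
class CalibrationTable:
    """Labeled spectra: one row = one spectrum + its (pH, pO2) labels."""

    spectra: np.ndarray  # (N, B)
    wavelengths: np.ndarray  # (B,)
    ph: np.ndarray  # (N,)
    po2: np.ndarray  # (N,) hPa
    provenance: np.ndarray | None = None  # (N,) str, RoI/source ids

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        n = self.spectra.shape[0]
        if self.spectra.ndim != 2:
            raise TableFormatError("spectra must be a 2-D (rows, bands) array")
        if self.spectra.shape[1] != self.wavelengths.size:
            raise TableFormatError(
                f"band count mismatch: spectra have {self.spectra.shape[1]} bands, "
                f"{self.wavelengths.size} wavelengths given"
            )
        if self.ph.shape != (n,) or self.po2.shape != (n,):
            raise TableFormatError("label vectors must match the number of rows")
        if n and not (np.all(np.isfinite(self.ph)) and np.all(np.isfinite(self.po2))):
            raise TableFormatError("labels must be finite")
        if np.any(self.po2 < 0):
            raise TableFormatError("po2 must be >= 0")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape != (n,):
                raise TableFormatError("provenance must match the number of rows")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def subset(self, indices) -> "CalibrationTable":
        indices = np.asarray(indices)
        return CalibrationTable(
            spectra=self.spectra[indices],
            wavelengths=self.wavelengths,
            ph=self.ph[indices],
            po2=self.po2[indices],
            provenance=None if self.provenance is None else self.provenance[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"ph": self.ph, "po2": self.po2}
        if self.provenance is not None:
            cols["provenance"] = self.provenance
        frame = pd.DataFrame(cols)
        spec = pd.DataFrame(
            self.spectra, columns=[f"{w:g}" for w in self.wavelengths]
        )
        return pd.concat([frame, spec], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CalibrationTable":
        for label in ("ph", "po2"):
            if label not in frame.columns:
                raise TableFormatError(f"missing required label column '{label}'")
        wl_cols = []
        for c in frame.columns:
            if c in ("ph", "po2", "provenance"):
                continue
            try:
                wl_cols.append((float(c), c))
            except ValueError:
                continue
        if not wl_cols:
            raise TableFormatError("no numeric wavelength columns found")
        wl_cols.sort()
        names = [c for _, c in wl_cols]
        for col in ["ph", "po2"] + names:
            series = pd.to_numeric(frame[col], errors="coerce")
            bad = series.index[series.isna() & frame[col].notna()]
            if len(bad):
                raise TableFormatError(
                    f"non-numeric cell in column '{col}' at row {bad[0]}"
                )
            if frame[col].isna().any():
                raise TableFormatError(
                    f"missing value in column '{col}' at row "
                    f"{frame.index[frame[col].isna()][0]}"
                )
        return cls(
            spectra=frame[names].to_numpy(dtype=float),
            wavelengths=np.array([w for w, _ in wl_cols]),
            ph=frame["ph"].to_numpy(dtype=float),
            po2=frame["po2"].to_numpy(dtype=float),
            provenance=(
                frame["provenance"].to_numpy(dtype=object)
                if "provenance" in frame.columns
                else None
            ),
        )


def _paths(path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".hdr", ".raw"):
        base = base.with_suffix("")
    return base.with_suffix(".hdr"), base.with_suffix(".raw")


def write_cube(cube: SpectralCube, path, dtype=np.float32) -> None:
    """Write an ENVI .hdr/.raw pair (band-sequential, little-endian)."""
    hdr_path, raw_path = _paths(path)
    dtype = np.dtype(dtype)
    if dtype not in _ENVI_CODES:
        raise CubeFormatError(f"unsupported dtype {dtype}")
    h, w, b = cube.shape
    wl = ", ".join(f"{v:.6f}" for v in cube.wavelengths)
    meta = "".join(
        f"{k} = {v}\n" for k, v in cube.metadata.items() if re.fullmatch(r"\w+", str(k))
    )
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n" + meta
    )
    arr = np.ascontiguousarray(cube.data.transpose(2, 0, 1), dtype=dtype)
    arr.astype(dtype.newbyteorder("<")).tofile(raw_path)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise CubeFormatError("missing ENVI magic line in header")
    # collapse brace-delimited multi-line values before splitting into fields
    text = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def read_cube(path) -> SpectralCube:
    """Read an ENVI .hdr/.raw pair written by :func:`write_cube` (or compatible)."""
    hdr_path, raw_path = _paths(path)
    if not hdr_path.exists():
        raise CubeFormatError(f"missing header file {hdr_path}")
    if not raw_path.exists():
        raise CubeFormatError(f"missing binary file {raw_path}")
    fields = _parse_envi_header(hdr_path.read_text())

    def intfield(name: str) -> int:
        if name not in fields:
            raise CubeFormatError(f"header missing required field '{name}'")
        try:
            return int(fields[name])
        except ValueError as exc:
            raise CubeFormatError(f"header field '{name}' is not an integer") from exc

    w, h, b = intfield("samples"), intfield("lines"), intfield("bands")
    code = intfield("data type")
    if code not in _ENVI_DTYPES:
        raise CubeFormatError(f"unsupported 'data type' code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise CubeFormatError(f"unsupported interleave '{interleave}' (need bsq)")
    if fields.get("byte order", "0").strip() != "0":
        raise CubeFormatError("unsupported 'byte order' (need 0, little-endian)")
    if "wavelength" not in fields:
        raise CubeFormatError("header missing required field 'wavelength'")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise CubeFormatError("header field 'wavelength' must be a { } list")
    try:
        wavelengths = np.array(
            [float(tok) for tok in wl_text[1:-1].replace("\n", " ").split(",") if tok.strip()]
        )
    except ValueError as exc:
        raise CubeFormatError("non-numeric entry in 'wavelength' list") from exc
    if wavelengths.size != b:
        raise CubeFormatError(
            f"header field 'bands' ({b}) disagrees with 'wavelength' list "
            f"length ({wavelengths.size})"
        )
    expected = h * w * b * dtype.itemsize
    actual = raw_path.stat().st_size
    if actual != expected:
        raise CubeFormatError(
            f"binary size {actual} B does not match header 'samples' x 'lines' x "
            f"'bands' x itemsize = {expected} B"
        )
    raw = np.fromfile(raw_path, dtype=dtype.newbyteorder("<"))
    data = raw.reshape(b, h, w).transpose(1, 2, 0)
    metadata = {
        k: v
        for k, v in fields.items()
        if k
        not in {
            "samples", "lines", "bands", "header offset", "file type",
            "data type", "interleave", "byte order", "wavelength",
            "wavelength units",
        }
    }
    return SpectralCube(data=data, wavelengths=wavelengths, metadata=metadata)


def write_table(table: CalibrationTable, path) -> None:
    """Write a calibration table as CSV in canonical column order."""
    table.to_frame().to_csv(path, index=False)


def read_table(path) -> CalibrationTable:
    """Read a calibration-table CSV.

    Wavelength columns are sniffed by numeric header names; 'ph' and 'po2'
    label columns are mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such table file: {path}")
    frame = pd.read_csv(path)
    if frame.empty and frame.columns.empty:
        warnings.warn(f"empty calibration table {path}")
    return CalibrationTable.from_frame(frame)
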