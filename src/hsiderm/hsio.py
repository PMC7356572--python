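"""On-disk artifacts for the hyperspectral dermatology pipeline.

Cubes are stored as ENVI pairs (a plain-text ``.hdr`` plus a raw binary
raster): BSQ interleave, little-endian IEEE-754 32-bit float, wavelengths
in nanometres in the header.  Lesion masks are single-channel 8-bit PNGs
with 0 = skin/background and 255 = pigmented skin lesion (PSL); any
nonzero value reads as positive.  Reference libraries are CSV.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CubeState",
    "InstrumentProfile",
    "HSCube",
    "ReferenceFrames",
    "BinaryMask",
    "FormatError",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "read_library",
    "write_library",
]


class FormatError(ValueError):
    """A file exists but does not follow the expected on-disk layout."""


class CubeState(str, enum.Enum):
    RAW = "raw"
    CALIBRATED = "calibrated"
    PREPROCESSED = "preprocessed"


@dataclass(frozen=True)
class InstrumentProfile:
    """Snapshot VNIR camera geometry: 50x50 px over a 12x12 mm field,
    125 bands covering 450-950 nm at ~8 nm FWHM spectral resolution.

    The sampling interval is (lambda_max - lambda_min)/(n_bands - 1),
    about 4.03 nm; the 8 nm figure is the optical FWHM, not the grid step.
    """

    n_bands: int = 125
    lambda_min_nm: float = 450.0
    lambda_max_nm: float = 950.0
    spatial_rows: int = 50
    spatial_cols: int = 50
    spectral_resolution_nm: float = 8.0
    effective_area_mm: tuple[float, float] = (12.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if not self.lambda_min_nm < self.lambda_max_nm:
            raise ValueError("lambda_min_nm must be < lambda_max_nm")

    def wavelengths(self) -> np.ndarray:
        """Uniform, strictly increasing wavelength grid in nm."""
        return np.linspace(self.lambda_min_nm, self.lambda_max_nm, self.n_bands)


@dataclass
class HSCube:
    """A hyperspectral cube: ``values[row, col, band]`` reflectance (or raw
    counts while state is 'raw') with a per-band wavelength axis."""

    values: np.ndarray
    wavelengths_nm: np.ndarray
    state: CubeState = CubeState.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("cube values must be rows x cols x bands")
        if self.values.shape[2] != self.wavelengths_nm.size:
            raise ValueError("band count must equal wavelength count")
        if self.wavelengths_nm.size >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.state = CubeState(self.state)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def pixels(self) -> np.ndarray:
        """Spectra as an (n_pixels, n_bands) matrix, row-major pixel order."""
        r, c, b = self.values.shape
        return self.values.reshape(r * c, b)


@dataclass
class ReferenceFrames:
    """White and dark reference captures used for radiometric calibration."""

    white: HSCube
    dark: HSCube

    def __post_init__(self) -> None:
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share shape")
        if not np.array_equal(self.white.wavelengths_nm, self.dark.wavelengths_nm):
            raise ValueError("white and dark frames must share the wavelength grid")


@dataclass
class BinaryMask:
    """Per-pixel boolean grid; True marks PSL pixels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be a 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# ENVI cube I/O (BSQ, little-endian, float32)

_ENVI_DATA_TYPE = 4  # IEEE-754 32-bit float
_STATE_KEY = "cube state"


def write_cube(cube: HSCube, path: str | Path) -> Path:
    """Write an ENVI header/binary pair; returns the header path.

    ``path`` may point at either member of the pair; the companion file
    gets the same stem with the other suffix (.hdr / .raw).
    """
    hdr_path, bin_path = _envi_pair(path)
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {hsiderm hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DATA_TYPE}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"{_STATE_KEY} = {cube.state.value}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(header)
    # BSQ: band-sequential, each band a full rows x cols plane
    bsq = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f4")
    bsq.tofile(bin_path)
    return hdr_path


def read_cube(path: str | Path) -> HSCube:
    """Read an ENVI header/binary pair written by :func:`write_cube` or any
    standard BSQ/BIL/BIP float or integer ENVI export with a wavelength list."""
    hdr_path, bin_path = _envi_pair(path)
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    if not bin_path.exists():
        raise FileNotFoundError(bin_path)
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as missing:
        raise FormatError(f"ENVI header missing field: {missing}") from None
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength list")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    dtypes = {1: "u1", 2: "<i2", 3: "<i4", 4: "<f4", 5: "<f8", 12: "<u2"}
    if dtype_code not in dtypes:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    byte_order = int(fields.get("byte order", 0))
    dt = np.dtype(dtypes[dtype_code])
    if byte_order == 1:
        dt = dt.newbyteorder(">")
    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(bin_path, dtype=dt, offset=offset)
    if raw.size != rows * cols * bands:
        raise FormatError(
            f"binary holds {raw.size} values, header implies {rows * cols * bands}"
        )
    interleave = fields.get("interleave", "bsq").lower()
    if interleave == "bsq":
        values = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2)
    elif interleave == "bil":
        values = np.moveaxis(raw.reshape(rows, bands, cols), 1, 2)
    elif interleave == "bip":
        values = raw.reshape(rows, cols, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    state = CubeState(fields.get(_STATE_KEY, "raw"))
    return HSCube(values=values.astype(np.float32), wavelengths_nm=wavelengths, state=state)


def _envi_pair(path: str | Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix == ".hdr":
        return path, path.with_suffix(".raw")
    if path.suffix:
        return path.with_suffix(".hdr"), path
    return path.with_suffix(".hdr"), path.with_suffix(".raw")


def _parse_envi_header(text: str) -> dict[str, str]:
    # ENVI headers are "key = value" lines; {...} values may span lines.
    text = re.sub(r"^\s*ENVI\s*", "", text)
    fields: dict[str, str] = {}
    pattern = re.compile(r"^([^=\n{}]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE)
    for match in pattern.finditer(text):
        key = match.group(1).strip().lower()
        value = match.group(2).strip()
        if value.startswith("{"):
            value = value[1:-1].replace("\n", " ").strip()
        fields[key] = value
    return fields


# ---------------------------------------------------------------------------
# Mask I/O (8-bit single-channel PNG)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    img = Image.fromarray(np.where(mask.values, 255, 0).astype(np.uint8), mode="L")
    img.save(path, format="PNG")
    return path


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = Image.open(path)
    if img.mode != "L":
        raise FormatError(f"mask must be single-channel 8-bit, got mode {img.mode!r}")
    return BinaryMask(values=np.asarray(img) != 0)


# ---------------------------------------------------------------------------
# Reference-library CSV I/O

_CLASS_VOCAB = ("skin", "benign", "malignant")


def write_library(lib, path: str | Path) -> Path:
    """Write a reference library as CSV: name, class, then one column per
    wavelength (nm, 6 decimal places)."""
    path = Path(path)
    cols = [f"{w:.17g}" for w in lib.wavelengths_nm]
    rows = [
        {"name": name, "class": cls, **dict(zip(cols, spectrum))}
        for name, cls, spectrum in lib.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
    return path


def read_library(path: str | Path):
    from .library import ReferenceLibrary

    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError("library CSV has no entries")
    if list(df.columns[:2]) != ["name", "class"]:
        raise FormatError("library CSV must start with 'name' and 'class' columns")
    if df["name"].duplicated().any():
        raise FormatError("duplicate entry names in library CSV")
    bad = set(df["class"]) - set(_CLASS_VOCAB)
    if bad:
        raise FormatError(f"unknown classes in library CSV: {sorted(bad)}")
    wavelengths = np.array([float(c) for c in df.columns[2:]])
    entries = [
        (row["name"], row["class"], row.iloc[2:].to_numpy(dtype=float))
        for _, row in df.iterrows()
    ]
    return ReferenceLibrary(entries=entries, wavelengths_nm=wavelengths)
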