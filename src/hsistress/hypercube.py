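"""ENVI-style hyperspectral cube I/O and reflectance calibration.

A line-scan VNIR imaging system produces raw intensity cubes of shape
(rows, cols, bands) together with a dark reference frame (shutter closed,
reflectance ~0) and a white reference frame (reflectance standard, ~100%).
Raw counts are converted to reflectance band-wise as

    R = (I_raw - B) / (W - B)

which removes the source/detector spectral response.  Cubes travel on disk
in the minimal ENVI dialect: an ASCII ``.hdr`` with an ``ENVI`` magic line,
lowercase keys and a braced wavelength list in nm, next to a bare binary
file in band-sequential (bsq), band-interleaved-by-line (bil) or
band-interleaved-by-pixel (bip) order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HyperCube",
    "ReferenceFrame",
    "CalibrationReport",
    "EnviFormatError",
    "GeometryError",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_reflectance",
]

# ENVI numeric codes for the two dtypes this dialect uses
_DTYPE_TO_CODE = {np.dtype("float32"): 4, np.dtype("uint16"): 12}
_CODE_TO_DTYPE = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                  5: np.float64, 12: np.uint16}

_INTERLEAVES = ("bil", "bip", "bsq")

#: white - dark differences below this are treated as dead detector elements
DEGENERATE_EPS = 1e-12


class EnviFormatError(ValueError):
    """Header/binary contents violate the ENVI dialect contract."""


class GeometryError(ValueError):
    """Array shapes of cube, mask or references do not agree."""


@dataclass
class HyperCube:
    """A (rows, cols, bands) image cube with its wavelength axis in nm.

    ``kind`` distinguishes raw sensor counts from calibrated reflectance.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"cube data must be 3-D, got ndim={self.data.ndim}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise EnviFormatError(
                f"wavelength count {len(self.wavelengths)} does not match "
                f"band count {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise EnviFormatError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class ReferenceFrame:
    """Dark or white reference, stored as a single scan line (1, cols, bands).

    Line-scan systems record references once per acquisition; the frame is
    broadcast down the scan (row) axis during calibration.  A full
    (rows, cols, bands) frame is also accepted.
    """

    data: np.ndarray
    role: str = "white"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:  # (cols, bands) -> (1, cols, bands)
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise GeometryError("reference frame must be 2-D or 3-D")
        if self.role not in ("dark", "white"):
            raise ValueError(f"role must be 'dark' or 'white', got {self.role!r}")


@dataclass
class CalibrationReport:
    """Bookkeeping from reflectance calibration."""

    n_pixels: int
    n_degenerate: int

    @property
    def degenerate_fraction(self) -> float:
        return self.n_degenerate / self.n_pixels if self.n_pixels else 0.0

    def to_text(self) -> str:
        return (
            f"n_pixels: {self.n_pixels}\n"
            f"n_degenerate: {self.n_degenerate}\n"
            f"degenerate_fraction: {self.degenerate_fraction:.6g}\n"
        )


def _parse_header(text: str, path: Path) -> dict:
    lines = text.splitlines()
    if not lines or lines[0].strip().upper() != "ENVI":
        raise EnviFormatError(f"{path}: missing ENVI magic line")
    # join brace-continued values
    body = "\n".join(lines[1:])
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([a-z][a-z0-9 _]*?)\s*=\s*(\{[^}]*\}|[^\n]*)",
                         re.MULTILINE | re.DOTALL)
    for m in pattern.finditer(body):
        fields[m.group(1).strip()] = m.group(2).strip()
    return fields


def read_envi_cube(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/binary pair into a (row, col, band) cube.

    The binary layout declared by ``interleave`` is undone so the in-memory
    order is always (row, col, band).
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_header(header_path.read_text(), header_path)

    for key in ("samples", "lines", "bands", "data type", "interleave", "wavelength"):
        if key not in fields:
            raise EnviFormatError(f"{header_path}: missing header field '{key}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"{header_path}: unknown interleave '{interleave}'")
    if code not in _CODE_TO_DTYPE:
        raise EnviFormatError(f"{header_path}: unsupported data type code {code}")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise EnviFormatError(f"{header_path}: wavelength must be a braced list")
    wavelengths = np.array(
        [float(tok) for tok in wl_text[1:-1].replace("\n", " ").split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise EnviFormatError(
            f"{header_path}: header declares {bands} bands but lists "
            f"{len(wavelengths)} wavelengths"
        )

    binary_path = header_path.with_suffix("." + interleave)
    if not binary_path.exists():
        raise FileNotFoundError(binary_path)
    dtype = np.dtype(_CODE_TO_DTYPE[code])
    flat = np.fromfile(binary_path, dtype=dtype)
    expected = samples * lines * bands
    if flat.size != expected:
        raise EnviFormatError(
            f"{binary_path}: {flat.size} elements on disk, header implies {expected}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        data = flat.reshape(lines, samples, bands)
    kind = "reflectance" if dtype == np.float32 else "raw"
    return HyperCube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_envi_cube(cube: HyperCube, base_path: str | Path,
                    interleave: str = "bsq") -> tuple[Path, Path]:
    """Write ``cube`` as a header/binary pair; returns (header, binary) paths.

    Reflectance cubes are stored as 32-bit float, raw cubes as 16-bit
    unsigned integers.
    """
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}, got {interleave!r}")
    base_path = Path(base_path)
    rows, cols, bands = cube.shape
    dtype = np.dtype("float32") if cube.kind == "reflectance" else np.dtype("uint16")
    data = cube.data.astype(dtype)
    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    else:
        ordered = data
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        f"data type = {_DTYPE_TO_CODE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path = base_path.with_suffix(".hdr")
    binary_path = base_path.with_suffix("." + interleave)
    header_path.write_text(header)
    np.ascontiguousarray(ordered).tofile(binary_path)
    return header_path, binary_path


def _broadcast_reference(ref: ReferenceFrame, shape: tuple[int, int, int],
                         name: str) -> np.ndarray:
    data = ref.data
    if data.shape == shape:
        return data
    if data.shape == (1, shape[1], shape[2]):
        return np.broadcast_to(data, shape)
    raise GeometryError(
        f"{name} reference shape {data.shape} is not broadcastable to cube {shape}"
    )


def calibrate_reflectance(raw: HyperCube, dark: ReferenceFrame,
                          white: ReferenceFrame, *, strict: bool = False) -> HyperCube:
    """Convert raw counts to reflectance via R = (raw - dark)/(white - dark).

    Elements where ``white - dark`` is below :data:`DEGENERATE_EPS` are set
    to 0 and counted in the attached :class:`CalibrationReport`
    (``cube.meta['calibration_report']``).  When more than 1% of elements
    are degenerate a warning is emitted, escalated to an error under
    ``strict=True`` — a dead reference usually means a failed acquisition.
    """
    import warnings

    shape = raw.shape
    b = _broadcast_reference(dark, shape, "dark")
    w = _broadcast_reference(white, shape, "white")
    denom = w - b
    degenerate = np.abs(denom) < DEGENERATE_EPS
    n_degen = int(degenerate.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data.astype(float) - b) / np.where(degenerate, 1.0, denom)
    refl = np.where(degenerate, 0.0, refl)
    report = CalibrationReport(n_pixels=int(refl.size), n_degenerate=n_degen)
    if report.degenerate_fraction > 0.01:
        msg = (f"{report.degenerate_fraction:.1%} of elements have white==dark; "
               "check the reference frames")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    out = HyperCube(refl, raw.wavelengths.copy(), kind="reflectance")
    out.meta["calibration_report"] = report
    return out
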