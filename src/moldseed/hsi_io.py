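"""ENVI hyperspectral cube I/O and white/dark reflectance calibration.

The cube layout is ``(line, sample, band)`` with an ordered band-center
wavelength grid in nanometres.  Calibration converts raw sensor counts to
relative reflectance using a whiteboard frame and a dark-current frame::

    reflectance = (raw - dark) / (white - dark)

References may be full frames or per-band spectra; they broadcast over the
spatial axes.  Calibrated values are not clipped — specular pixels may
legitimately exceed 1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HyperCube",
    "CalibrationPair",
    "read_envi",
    "write_envi",
    "calibrate",
    "nearest_band",
    "FormatError",
]


class FormatError(ValueError):
    """Raised for malformed ENVI headers or inconsistent cube metadata."""


# ENVI "data type" codes <-> numpy dtypes (little-endian).
_ENVI_DTYPES = {
    1: np.dtype("u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """A 3-D spectral image indexed ``(line, sample, band)``.

    Parameters
    ----------
    data : ndarray, shape (lines, samples, bands)
        Raw counts or reflectance; all values finite.
    wavelengths_nm : ndarray, shape (bands,)
        Strictly increasing band-center wavelengths in nm.
    meta : dict
        Free-form acquisition metadata, preserved through ENVI roundtrips.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"cube data must be 3-D, got ndim={self.data.ndim}")
        if self.data.shape[2] != self.wavelengths_nm.shape[0]:
            raise FormatError(
                f"band axis length {self.data.shape[2]} != "
                f"{self.wavelengths_nm.shape[0]} wavelengths"
            )
        if self.wavelengths_nm.size > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("cube contains non-finite values")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationPair:
    """Whiteboard and dark-current reference frames.

    Each may be a full ``(lines, samples, bands)`` cube, a ``(samples, bands)``
    strip, or a per-band spectrum ``(bands,)``; the two must share a shape.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError(
                f"white {self.white.shape} and dark {self.dark.shape} shapes differ"
            )


def _parse_header(text: str) -> dict:
    """Parse an ENVI .hdr file into a flat dict (keys lower-cased)."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    fields: dict = {}
    # Join brace-delimited multi-line values first.
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(r"^\s*([\w\s]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.S | re.M)
    pos = 0
    while pos < len(body):
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
        pos = m.end()
    return fields


def _header_path_pair(header_path: Path) -> tuple[Path, Path]:
    header_path = Path(header_path)
    for ext in (".img", ".dat", ".raw", ".bsq", ".bil", ".bip", ""):
        candidate = header_path.with_suffix(ext)
        if candidate != header_path and candidate.exists():
            return header_path, candidate
    raise FileNotFoundError(f"no binary companion found for {header_path}")


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI cube (``.hdr`` text header + raw binary).

    Supports BIL/BIP/BSQ interleaves, little-endian data.  The header must
    carry a ``wavelength`` list; a missing or non-monotone list is a
    :class:`FormatError`.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header not found: {header_path}")
    header_path, binary_path = _header_path_pair(header_path)
    fields = _parse_header(header_path.read_text())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"header missing required field: {exc}") from exc
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    if "wavelength" not in fields:
        raise FormatError("header has no wavelength list")

    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array(
        [float(tok) for tok in wl_text.replace("\n", ",").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )

    dtype = _ENVI_DTYPES[dtype_code]
    flat = np.fromfile(binary_path, dtype=dtype)
    expected = lines * samples * bands
    if flat.size != expected:
        raise FormatError(
            f"binary holds {flat.size} values, expected {expected}"
        )
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines, samples, bands)

    meta = {
        k: v
        for k, v in fields.items()
        if k
        not in (
            "lines", "samples", "bands", "interleave", "data type",
            "wavelength", "byte order", "header offset", "file type",
        )
    }
    return HyperCube(data=np.ascontiguousarray(data), wavelengths_nm=wavelengths, meta=meta)


def write_envi(
    cube: HyperCube,
    header_path: str | Path,
    interleave: str = "bip",
    dtype: np.dtype | str | None = None,
) -> None:
    """Write a cube as an ENVI ``.hdr`` + ``.img`` pair (little-endian)."""
    header_path = Path(header_path)
    binary_path = header_path.with_suffix(".img")
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")

    data = cube.data
    if dtype is not None:
        data = data.astype(np.dtype(dtype))
    native = data.dtype.newbyteorder("<")
    if native not in _DTYPE_CODES:
        data = data.astype("<f8")
        native = data.dtype
    code = _DTYPE_CODES[np.dtype(native)]

    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    np.ascontiguousarray(out, dtype=native).tofile(binary_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths_nm)
    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {cube.n_samples}",
        f"lines = {cube.n_lines}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        f"data type = {code}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"wavelength = {{ {wl} }}",
    ]
    for key, value in cube.meta.items():
        lines.append(f"{key} = {value}")
    header_path.write_text("\n".join(lines) + "\n")


def calibrate(
    raw: HyperCube,
    refs: CalibrationPair,
    epsilon: float = 1e-8,
) -> HyperCube:
    """Convert raw counts to reflectance: ``(raw - dark) / (white - dark)``.

    Where ``white - dark <= 0`` (dead pixels) the denominator is clamped to
    ``epsilon`` and a warning is logged rather than aborting the cube.
    Output is float64 and NOT clipped to [0, 1].
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    white, dark = refs.white, refs.dark
    try:
        np.broadcast_shapes(raw.data.shape, white.shape)
    except ValueError as exc:
        raise ValueError(
            f"references of shape {white.shape} not broadcastable to cube "
            f"{raw.data.shape}"
        ) from exc

    denom = white - dark
    n_bad = int(np.count_nonzero(denom <= 0))
    if n_bad:
        logger.warning(
            "calibration: %d reference locations with white <= dark; "
            "denominator clamped to epsilon=%g", n_bad, epsilon,
        )
    denom = np.maximum(denom, epsilon)
    reflectance = (raw.data.astype(np.float64) - dark) / denom
    return HyperCube(
        data=reflectance,
        wavelengths_nm=raw.wavelengths_nm.copy(),
        meta=dict(raw.meta, calibrated="true"),
    )


def nearest_band(cube: HyperCube, target_nm: float) -> int:
    """Index of the band whose center is closest to ``target_nm``.

    Ties break toward the lower index.
    """
    if cube.n_bands == 0:
        raise ValueError("cube has no bands")
    return int(np.argmin(np.abs(cube.wavelengths_nm - target_nm)))
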