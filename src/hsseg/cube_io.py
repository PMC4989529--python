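"""Raw hyperspectral cube I/O.

A cube on disk is a headerless binary block of ``lines × samples × bands``
values plus a sidecar text header (ENVI-like ``key = value`` dialect, written
next to the data file with an extra ``.hdr`` suffix).  Two interleaves are
supported:

* **BIL** (band-interleaved-by-line, the canonical layout): for each image
  row, all bands of that row are stored contiguously, band-major — the byte
  offset of element ``(m, n, i)`` is ``((m·bands + i)·samples + n)·itemsize``.
  This layout is what makes the fast partial-row read of the screening
  segmentation possible: the first ``k`` rows occupy exactly the first
  ``k·samples·bands`` values of the file.
* **BSQ** (band-sequential): one full image plane per band; supported for
  interchange only, partial-row reads are refused for it.

In-memory cubes are always ``float64`` arrays indexed ``(row, col, band)``,
0-based.  The 1-based ``(m, n, i)`` convention used in the field maps onto
this by subtracting one from each index.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DimensionError, FormatError, RangeError

__all__ = [
    "CubeHeader",
    "HyperCube",
    "read_cube",
    "read_partial_rows",
    "write_cube",
    "read_header",
    "write_header",
    "load_cube",
    "save_cube",
    "read_mask",
    "write_mask",
    "bil_offset",
]

_DTYPE_CODES = {"uint8": "u1", "uint16": "u2", "float32": "f4"}
_BYTE_ORDERS = {"little": "<", "big": ">"}
_INTERLEAVES = ("bil", "bsq")


@dataclass(frozen=True)
class CubeHeader:
    """Sidecar description of a raw cube file.

    Parameters mirror the acquisition geometry: ``lines`` (M, rows),
    ``samples`` (N, columns), ``bands`` (I), a strictly increasing wavelength
    axis in µm, and the sensor dynamic range in bits (12 for the target
    camera, stored in 16-bit words by default).
    """

    lines: int
    samples: int
    bands: int
    wavelengths: tuple = field(default=())
    dtype_code: str = "uint16"
    byte_order: str = "little"
    interleave: str = "bil"
    dynamic_range_bits: int = 12

    def __post_init__(self) -> None:
        for name in ("lines", "samples", "bands"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.dtype_code not in _DTYPE_CODES:
            raise ConfigError(
                f"unknown dtype_code {self.dtype_code!r}; expected one of {sorted(_DTYPE_CODES)}"
            )
        if self.byte_order not in _BYTE_ORDERS:
            raise ConfigError(f"byte_order must be 'little' or 'big', got {self.byte_order!r}")
        if self.interleave not in _INTERLEAVES:
            raise ConfigError(f"interleave must be 'bil' or 'bsq', got {self.interleave!r}")
        if not 8 <= self.dynamic_range_bits <= 16:
            raise ConfigError(
                f"dynamic_range_bits must be in [8, 16], got {self.dynamic_range_bits}"
            )
        if self.dtype_code == "uint8" and self.dynamic_range_bits > 8:
            raise ConfigError(
                f"uint8 storage cannot hold a {self.dynamic_range_bits}-bit dynamic range"
            )
        wl = tuple(float(w) for w in self.wavelengths)
        if not wl:
            # default axis: evenly spaced placeholder over 0.4-1.0 um
            wl = tuple(np.linspace(0.4, 1.0, self.bands))
        if len(wl) != self.bands:
            raise ConfigError(
                f"wavelengths length {len(wl)} != bands {self.bands}"
            )
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ConfigError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(_BYTE_ORDERS[self.byte_order] + _DTYPE_CODES[self.dtype_code])

    @property
    def itemsize(self) -> int:
        return self.dtype.itemsize

    @property
    def nbytes(self) -> int:
        return self.lines * self.samples * self.bands * self.itemsize

    @property
    def shape(self) -> tuple:
        return (self.lines, self.samples, self.bands)

    def replace(self, **kw) -> "CubeHeader":
        return replace(self, **kw)


@dataclass
class HyperCube:
    """A cube in memory: a ``(lines, samples, bands)`` float array plus header."""

    header: CubeHeader
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.header.shape:
            raise DimensionError(
                f"values shape {self.values.shape} != header shape {self.header.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise RangeError("cube values must be finite")
        if self.header.dtype_code != "float32":
            top = 2 ** self.header.dynamic_range_bits - 1
            if self.values.min() < 0 or self.values.max() > top:
                raise RangeError(
                    f"integer cube values must lie in [0, {top}] "
                    f"for dynamic_range_bits={self.header.dynamic_range_bits}"
                )

    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray(self.header.wavelengths, dtype=np.float64)

    @property
    def shape(self) -> tuple:
        return self.values.shape


def bil_offset(header: CubeHeader, m: int, n: int, i: int) -> int:
    """Byte offset of element ``(m, n, i)`` in a BIL file."""
    return ((m * header.bands + i) * header.samples + n) * header.itemsize


def _as_file(path_or_file) -> tuple:
    if hasattr(path_or_file, "read"):
        return path_or_file, False
    return open(path_or_file, "rb"), True


def read_cube(path, header: CubeHeader) -> HyperCube:
    """Read a full raw cube.

    The file size must equal ``lines·samples·bands·itemsize`` exactly;
    mismatches raise :class:`FormatError` naming the expected and actual
    byte counts.  ``path`` may also be an open binary file object.
    """
    expected = header.nbytes
    f, close = _as_file(path)
    try:
        data = f.read(expected + 1)
    finally:
        if close:
            f.close()
    if len(data) != expected:
        actual = len(data) if len(data) <= expected else f">{expected}"
        raise FormatError(
            f"cube file size mismatch: expected {expected} bytes "
            f"({header.lines}x{header.samples}x{header.bands} {header.dtype_code}), got {actual}"
        )
    flat = np.frombuffer(data, dtype=header.dtype)
    if header.interleave == "bil":
        vals = flat.reshape(header.lines, header.bands, header.samples).transpose(0, 2, 1)
    else:  # bsq
        vals = flat.reshape(header.bands, header.lines, header.samples).transpose(1, 2, 0)
    return HyperCube(header, vals.astype(np.float64))


def read_partial_rows(path, header: CubeHeader, row_count: int) -> HyperCube:
    """Read only the first ``row_count`` image rows of a BIL cube.

    Exactly ``row_count·samples·bands·itemsize`` bytes are read from the
    start of the file — the contract that makes the screening fast path
    cheap.  BSQ cubes interleave rows across the whole file, so a partial
    read is refused for them.
    """
    if header.interleave != "bil":
        raise ConfigError(
            "partial-row reads require BIL interleave; BSQ needs a full read"
        )
    if not 1 <= row_count <= header.lines:
        raise ConfigError(f"row_count must be in [1, {header.lines}], got {row_count}")
    nbytes = row_count * header.samples * header.bands * header.itemsize
    f, close = _as_file(path)
    try:
        data = f.read(nbytes)
    finally:
        if close:
            f.close()
    if len(data) != nbytes:
        raise FormatError(
            f"cube file too short: expected at least {nbytes} bytes, got {len(data)}"
        )
    flat = np.frombuffer(data, dtype=header.dtype)
    vals = flat.reshape(row_count, header.bands, header.samples).transpose(0, 2, 1)
    sub = header.replace(lines=row_count)
    return HyperCube(sub, vals.astype(np.float64))


def write_cube(cube: HyperCube, path) -> None:
    """Write a cube as raw binary, the byte-exact inverse of :func:`read_cube`."""
    h = cube.header
    vals = cube.values
    if h.dtype_code != "float32":
        vals = np.rint(vals)
    arr = vals.astype(h.dtype)
    if h.interleave == "bil":
        ordered = arr.transpose(0, 2, 1)  # (lines, bands, samples)
    else:
        ordered = arr.transpose(2, 0, 1)  # (bands, lines, samples)
    data = np.ascontiguousarray(ordered).tobytes()
    if hasattr(path, "write"):
        path.write(data)
    else:
        with open(path, "wb") as f:
            f.write(data)


# ---------------------------------------------------------------------------
# sidecar header text format

_HEADER_MAGIC = "HSSEG cube header"


def write_header(header: CubeHeader, path) -> None:
    wl = ", ".join(f"{w:.6f}" for w in header.wavelengths)
    text = (
        f"{_HEADER_MAGIC}\n"
        f"lines = {header.lines}\n"
        f"samples = {header.samples}\n"
        f"bands = {header.bands}\n"
        f"data type = {header.dtype_code}\n"
        f"byte order = {header.byte_order}\n"
        f"interleave = {header.interleave}\n"
        f"dynamic range bits = {header.dynamic_range_bits}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path, "w") as f:
        f.write(text)


def read_header(path) -> CubeHeader:
    with open(path) as f:
        text = f.read()
    if _HEADER_MAGIC not in text.splitlines()[0]:
        raise FormatError(f"{path}: not a cube header (missing magic line)")
    # join wavelength braces across lines, then parse key = value pairs
    body = text.replace("\n", " \n")
    fields: dict = {}
    if "{" in body:
        pre, rest = body.split("{", 1)
        wl_text, post = rest.split("}", 1)
        fields["wavelength"] = tuple(
            float(t) for t in wl_text.replace(",", " ").split()
        )
        body = pre + post
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    try:
        return CubeHeader(
            lines=int(fields["lines"]),
            samples=int(fields["samples"]),
            bands=int(fields["bands"]),
            wavelengths=fields.get("wavelength", ()),
            dtype_code=fields.get("data type", "uint16"),
            byte_order=fields.get("byte order", "little"),
            interleave=fields.get("interleave", "bil"),
            dynamic_range_bits=int(fields.get("dynamic range bits", 12)),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: header missing required key {exc}") from exc


def save_cube(cube: HyperCube, path) -> None:
    """Write ``path`` (raw data) plus ``path + '.hdr'`` (sidecar header)."""
    write_cube(cube, path)
    write_header(cube.header, str(path) + ".hdr")


def load_cube(path) -> HyperCube:
    """Read a cube whose header lives at ``path + '.hdr'``."""
    header = read_header(str(path) + ".hdr")
    return read_cube(path, header)


# ---------------------------------------------------------------------------
# label masks

def write_mask(mask: np.ndarray, path) -> None:
    """Write a 2D integer label mask.

    ``.pgm``/``.png`` store 8-bit labels; a *binary* mask (labels in {0, 1})
    is scaled to {0, 255} for visibility, other label maps are stored
    verbatim and must not exceed 255.  ``.csv`` stores arbitrary integer
    labels as text.
    """
    from PIL import Image

    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise DimensionError(f"mask must be 2D, got shape {mask.shape}")
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        np.savetxt(path, mask.astype(np.int64), fmt="%d", delimiter=",")
        return
    if ext in (".pgm", ".png"):
        if mask.min() < 0 or mask.max() > 255:
            raise RangeError(
                f"labels in [{mask.min()}, {mask.max()}] do not fit 8-bit "
                f"{ext} output; use CSV"
            )
        out = mask.astype(np.uint8)
        if mask.max() <= 1:
            out = out * 255  # binary masks become {0, 255}
        Image.fromarray(out, mode="L").save(path)
        return
    raise ConfigError(f"unsupported mask format {ext!r}; use .pgm, .png or .csv")


def read_mask(path) -> np.ndarray:
    """Read a mask written by :func:`write_mask`.

    Images whose values are confined to {0, 255} are interpreted as binary
    masks and mapped back to {0, 1}.
    """
    from PIL import Image

    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        arr = np.loadtxt(path, delimiter=",", dtype=np.int64)
        return np.atleast_2d(arr)
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.int64)
    uniq = np.unique(arr)
    if set(uniq.tolist()) <= {0, 255}:
        arr = (arr > 0).astype(np.int64)
    return arr
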