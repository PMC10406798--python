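"""Multispectral cube data model and on-disk format.

A multispectral acquisition is a stack of grayscale images of one scene,
one per narrow wavelength band.  This module holds the containers for that
data (wavelength grid, repeated-frame stacks, the cube itself), the
acquisition arithmetic (pixel-wise frame averaging, the column-major pixel
flattening used when pixels are treated as observations), and readers/
writers for multi-page TIFF band stacks or per-band image directories with
a JSON sidecar carrying the wavelengths and sample labels.

Conventions
-----------
* Cube axis order is ``(row, column, band)``; bands are always stored in
  ascending wavelength order regardless of how they were supplied.
* The public arrays are 0-based; :func:`flatten_pixel_index` exposes the
  1-based column-major contract ``k = (c - 1) R + r`` used when pixels are
  enumerated as statistical samples.
* A cube carries a boolean validity mask (``True`` = usable pixel); all
  downstream statistics exclude invalid pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "KINDS",
    "WavelengthGrid",
    "FrameStack",
    "SpectralCube",
    "average_frames",
    "flatten_pixel_index",
    "unflatten_pixel_index",
    "build_cube",
    "read_cube",
    "write_cube",
]

#: Recognized physical interpretations of cube values.
KINDS = ("intensity", "transmission", "absorbance")

SIDECAR_SUFFIX = ".json"


@dataclass(frozen=True)
class WavelengthGrid:
    """Band-center wavelengths in nanometres, strictly increasing."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float).ravel()
        if wl.size == 0:
            raise ValueError("wavelength grid is empty")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing with no duplicates")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.allclose(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(tuple(self.wavelengths.tolist()))

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        """Inclusive arithmetic grid, e.g. ``from_range(390, 705, 15)`` -> 22 bands."""
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


@dataclass
class FrameStack:
    """Repeated frames acquired at one wavelength.

    ``levels`` is the number of quantization gray levels (256 for the 8-bit
    camera path); ``None`` means the frames are unquantized reals.
    """

    frames: np.ndarray  # (n_frames, rows, cols)
    levels: int | None = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim == 3:
            pass
        elif arr.ndim == 2:
            arr = arr[None]
        else:
            raise ValueError("frames must be a (n, rows, cols) stack or a single 2-D frame")
        if arr.shape[0] == 0:
            raise ValueError("empty frame stack")
        if self.levels is not None:
            if np.any(arr < 0) or np.any(arr > self.levels - 1):
                raise ValueError(f"frame values outside [0, {self.levels - 1}]")
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def average_frames(stack: FrameStack) -> np.ndarray:
    """Pixel-by-pixel arithmetic mean of the repeated frames.

    Averaging the repeated frames suppresses temporal CCD noise by
    ``1/sqrt(n_frames)``.  The result is always floating point, even for
    quantized integer input.
    """
    return np.mean(stack.frames, axis=0, dtype=np.float64)


def flatten_pixel_index(r: int, c: int, n_rows: int) -> int:
    """Column-major 1-based pixel index ``k = (c - 1) R + r``.

    ``r`` runs 1..R down a column, ``c`` 1..C across columns; ``k`` then runs
    1..R*C, enumerating pixels column by column.
    """
    if not 1 <= r <= n_rows:
        raise ValueError(f"row {r} out of range 1..{n_rows}")
    if c < 1:
        raise ValueError(f"column {c} out of range (must be >= 1)")
    return (c - 1) * n_rows + r


def unflatten_pixel_index(k: int, n_rows: int) -> tuple[int, int]:
    """Inverse of :func:`flatten_pixel_index`: ``k`` -> 1-based ``(r, c)``."""
    if k < 1:
        raise ValueError("flat index must be >= 1")
    c, r0 = divmod(k - 1, n_rows)
    return r0 + 1, c + 1


@dataclass
class SpectralCube:
    """3-D multispectral dataset over ``(row, column, band)``.

    ``kind`` states what the values mean: raw camera ``intensity``, sample/
    reference ``transmission`` in (0, 1], or Beer–Lambert ``absorbance``
    (-ln T).  ``group``/``individual`` are sample labels (diet group and eye
    index in the original study design).  ``mask`` is True where the pixel is
    valid; invalid pixels (e.g. dead reference pixels) are excluded from all
    statistics downstream.
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str
    group: str | None = None
    individual: str | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if data.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {data.shape[2]} bands but grid lists {len(self.grid)} wavelengths"
            )
        if self.kind not in KINDS:
            raise ValueError(f"unknown cube kind {self.kind!r}; expected one of {KINDS}")
        self.data = data
        if self.mask is None:
            self.mask = np.ones(data.shape[:2], dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != data.shape[:2]:
                raise ValueError("mask shape must match the cube's spatial shape")
            self.mask = mask
        valid = self.data[self.mask]
        if self.kind == "transmission" and valid.size and np.any(valid <= 0):
            raise ValueError("transmission cube has non-positive values on valid pixels")
        if self.kind == "absorbance" and valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("absorbance cube has non-finite values on valid pixels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_pixels(self) -> np.ndarray:
        """(M, N) matrix of the spectra of valid pixels (M = n_valid)."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "SpectralCube":
        """New cube sharing grid/labels/mask with replaced values."""
        return SpectralCube(
            data=data,
            grid=self.grid,
            kind=self.kind if kind is None else kind,
            group=self.group,
            individual=self.individual,
            mask=self.mask.copy(),
        )


def build_cube(
    images: Sequence[np.ndarray],
    grid: WavelengthGrid,
    kind: str = "intensity",
    group: str | None = None,
    individual: str | None = None,
    wavelengths: Sequence[float] | None = None,
    mask: np.ndarray | None = None,
) -> SpectralCube:
    """Assemble per-band images into a cube, bands sorted by ascending wavelength.

    ``wavelengths`` optionally gives the wavelength of each supplied image when
    the input order does not already match ``grid``; images are then reordered
    to the grid.  Shapes must agree across bands.
    """
    if len(images) != len(grid):
        raise ValueError(f"{len(images)} images supplied for a {len(grid)}-band grid")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"band images disagree in shape: {sorted(shapes)}")
    if wavelengths is not None:
        wl = np.asarray(wavelengths, dtype=float)
        if wl.size != len(images):
            raise ValueError("one wavelength per image required")
        order = np.argsort(wl)
        if not np.allclose(wl[order], grid.wavelengths):
            raise ValueError("supplied wavelengths do not match the grid")
        images = [images[i] for i in order]
    data = np.stack([np.asarray(im, dtype=np.float64) for im in images], axis=-1)
    return SpectralCube(data, grid, kind, group=group, individual=individual, mask=mask)


# ---------------------------------------------------------------------------
# On-disk format: multi-page TIFF (one page per band, ascending wavelength)
# or a directory of per-band TIFFs, plus a JSON sidecar
# {wavelengths_nm, kind, group, individual}.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    if path.is_dir() or path.suffix == "":
        return path / ("sidecar" + SIDECAR_SUFFIX)
    return path.with_suffix(path.suffix + SIDECAR_SUFFIX)


def write_cube(cube: SpectralCube, path: str | Path, as_directory: bool = False) -> Path:
    """Write a cube and its JSON sidecar; returns the sidecar path.

    ``as_directory`` selects one single-band TIFF per wavelength inside
    ``path`` instead of one multi-page TIFF at ``path``.
    """
    path = Path(path)
    if as_directory:
        path.mkdir(parents=True, exist_ok=True)
        for b, wl in enumerate(cube.grid.wavelengths):
            tifffile.imwrite(path / f"band_{b:03d}_{wl:.0f}nm.tif",
                             cube.data[:, :, b].astype(np.float32),
                             photometric="minisblack")
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        pages = np.moveaxis(cube.data, -1, 0).astype(np.float32)
        tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = _sidecar_path(path)
    meta = {
        "wavelengths_nm": cube.grid.wavelengths.tolist(),
        "kind": cube.kind,
        "group": cube.group,
        "individual": cube.individual,
    }
    if not cube.mask.all():
        meta["mask_invalid_rc"] = np.argwhere(~cube.mask).tolist()
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_cube(path: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_cube` (TIFF stack or band directory).

    The sidecar is authoritative for wavelengths and labels; if it lists
    wavelengths out of order the bands are re-sorted ascending.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    kind = meta.get("kind")
    if kind not in KINDS:
        raise ValueError(f"sidecar has unknown kind tag {kind!r}")
    wl = np.asarray(meta["wavelengths_nm"], dtype=float)
    if path.is_dir():
        band_files = sorted(p for p in path.glob("band_*.tif"))
        images = [tifffile.imread(p) for p in band_files]
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        images = list(arr)
    if len(images) != wl.size:
        raise ValueError(
            f"sidecar lists {wl.size} wavelengths but file holds {len(images)} bands"
        )
    order = np.argsort(wl)
    grid = WavelengthGrid(wl[order])
    data = np.stack([images[i] for i in order], axis=-1).astype(np.float64)
    mask = np.ones(data.shape[:2], dtype=bool)
    for r, c in meta.get("mask_invalid_rc", []):
        mask[r, c] = False
    return SpectralCube(data, grid, kind, group=meta.get("group"),
                        individual=meta.get("individual"), mask=mask)
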