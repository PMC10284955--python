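"""Multi-spectral filter array (MSFA) geometry and the mosaic forward model.

A snapshot mosaic sensor covers its pixel grid with a small n×n mosaic of
spectral filters repeated periodically, so each pixel measures exactly one
of C spectral bands. This module holds:

* :class:`MSFAPattern` — the n×n band-index grid defining the sensor layout;
* :func:`degrade` — the linear degradation operator mapping a full
  hyperspectral cube I (X×Y×C) to its snapshot measurement
  I^s(x, y) = I(x, y, c_{x,y});
* :func:`override_snapshot_pixels` — the hard data-fidelity operator that
  writes measured snapshot values back into a reconstructed cube at their
  sampled positions, making any fidelity metric between the snapshot and
  the degraded reconstruction identically zero;
* :func:`linear_demosaick` — the bilinear-interpolation baseline that
  fills each band from its own sparse sample grid.

Coordinate convention (used package-wide): 0-based indices, x = row,
y = column; the mosaic cell for pixel (x, y) is (x mod n, y mod n); the
spectral band axis is the last axis of a cube.

Cubes and snapshots are plain numpy arrays (X×Y×C and X×Y); validation
helpers enforce the invariants at API boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "MSFAPattern",
    "canonical_pattern",
    "validate_cube",
    "validate_snapshot",
    "degrade",
    "override_snapshot_pixels",
    "linear_demosaick",
    "read_cube",
    "write_cube",
    "read_snapshot",
    "write_snapshot",
]


@dataclass(frozen=True)
class MSFAPattern:
    """An n×n repeating mosaic of band indices.

    Parameters
    ----------
    band_index
        n×n integer grid; entry (i, j) is the spectral band sampled at
        pixels (x, y) with x ≡ i, y ≡ j (mod n).
    n_bands
        Number of spectral bands C. Defaults to ``band_index.max() + 1``.
    """

    band_index: np.ndarray
    n_bands: int = 0

    def __post_init__(self):
        bi = np.asarray(self.band_index, dtype=np.int64)
        if bi.ndim != 2 or bi.shape[0] != bi.shape[1] or bi.shape[0] < 1:
            raise ValueError("band_index must be a square n×n grid with n >= 1")
        object.__setattr__(self, "band_index", bi)
        nb = int(self.n_bands) if self.n_bands else int(bi.max()) + 1
        if bi.min() < 0 or bi.max() >= nb:
            raise ValueError(
                f"band indices must lie in [0, {nb}); got range [{bi.min()}, {bi.max()}]"
            )
        object.__setattr__(self, "n_bands", nb)

    @property
    def size(self) -> int:
        """Mosaic period n."""
        return self.band_index.shape[0]

    def tile(self, X: int, Y: int) -> np.ndarray:
        """Band index c_{x,y} for every pixel of an X×Y sensor."""
        n = self.size
        reps = (-(-X // n), -(-Y // n))  # ceil division
        return np.tile(self.band_index, reps)[:X, :Y]

    def band_cells(self, c: int) -> np.ndarray:
        """(k, 2) array of mosaic cells (i, j) sampling band ``c``."""
        return np.argwhere(self.band_index == c)

    @property
    def is_bijective(self) -> bool:
        """True when each band occupies exactly one mosaic cell."""
        return self.size**2 == self.n_bands and len(np.unique(self.band_index)) == self.n_bands

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "size": self.size,
            "n_bands": self.n_bands,
            "band_index": self.band_index.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MSFAPattern":
        bi = np.asarray(d["band_index"], dtype=np.int64)
        if "size" in d and int(d["size"]) != bi.shape[0]:
            raise ValueError("declared size does not match band_index grid")
        return cls(band_index=bi, n_bands=int(d.get("n_bands", 0)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "MSFAPattern":
        path = Path(path)
        d = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(d)


def canonical_pattern(n: int = 4) -> MSFAPattern:
    """Row-major bijective n×n pattern (band i*n+j at cell (i, j)).

    The layout of commercial sensors is generally proprietary, so this
    row-major default is a configurable convention, not vendor ground
    truth.
    """
    return MSFAPattern(band_index=np.arange(n * n).reshape(n, n))


# ----------------------------------------------------------------------
def validate_cube(cube: np.ndarray) -> np.ndarray:
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError(f"hyperspectral cube must be X×Y×C (3-D); got ndim={cube.ndim}")
    if min(cube.shape) < 1:
        raise ValueError(f"cube dimensions must be >= 1; got {cube.shape}")
    if cube.dtype.kind == "f" and not np.isfinite(cube).all():
        raise ValueError("cube contains non-finite values")
    return cube


def validate_snapshot(snap: np.ndarray) -> np.ndarray:
    snap = np.asarray(snap)
    if snap.ndim != 2:
        raise ValueError(f"snapshot must be a 2-D X×Y array; got ndim={snap.ndim}")
    if min(snap.shape) < 1:
        raise ValueError(f"snapshot dimensions must be >= 1; got {snap.shape}")
    if snap.dtype.kind == "f" and not np.isfinite(snap).all():
        raise ValueError("snapshot contains non-finite values")
    return snap


def degrade(cube: np.ndarray, pattern: MSFAPattern) -> np.ndarray:
    """Apply the mosaic degradation operator: I^s(x,y) = I(x, y, c_{x,y})."""
    cube = validate_cube(cube)
    X, Y, C = cube.shape
    if C < int(pattern.band_index.max()) + 1:
        raise ValueError(
            f"pattern references band {int(pattern.band_index.max())} "
            f"but cube has only {C} bands"
        )
    cxy = pattern.tile(X, Y)
    return np.take_along_axis(cube, cxy[:, :, None], axis=2)[:, :, 0]


def override_snapshot_pixels(
    cube: np.ndarray, snapshot: np.ndarray, pattern: MSFAPattern
) -> np.ndarray:
    """Write measured snapshot values into the cube at their sampled voxels.

    Returns a copy of ``cube`` in which voxel (x, y, c_{x,y}) holds
    ``snapshot[x, y]`` exactly; all other voxels are untouched, so
    ``degrade(result, pattern) == snapshot`` bit-for-bit.
    """
    cube = validate_cube(cube)
    snapshot = validate_snapshot(snapshot)
    if cube.shape[:2] != snapshot.shape:
        raise ValueError(
            f"cube spatial dims {cube.shape[:2]} do not match snapshot {snapshot.shape}"
        )
    X, Y, _ = cube.shape
    cxy = pattern.tile(X, Y)
    out = cube.copy()
    xs, ys = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
    out[xs, ys, cxy] = snapshot
    return out


def _interp_subgrid(
    values: np.ndarray, x0: int, y0: int, n: int, X: int, Y: int
) -> np.ndarray:
    """Separable bilinear interpolation of a regular n-stride subgrid.

    ``values[i, j]`` sits at pixel (x0 + i*n, y0 + j*n). Outside the
    sample hull the edge sample is replicated (np.interp clamps).
    """
    xs = x0 + n * np.arange(values.shape[0])
    ys = y0 + n * np.arange(values.shape[1])
    gx = np.arange(X, dtype=np.float64)
    gy = np.arange(Y, dtype=np.float64)
    # interpolate along rows (x) for each sample column, then along columns
    mid = np.empty((X, values.shape[1]), dtype=np.float64)
    for j in range(values.shape[1]):
        mid[:, j] = np.interp(gx, xs, values[:, j].astype(np.float64))
    out = np.empty((X, Y), dtype=np.float64)
    for i in range(X):
        out[i] = np.interp(gy, ys, mid[i])
    return out


def linear_demosaick(snapshot: np.ndarray, pattern: MSFAPattern) -> np.ndarray:
    """Bilinear-interpolation demosaicking baseline.

    Each band is reconstructed from its own sparse sample positions by
    separable bilinear interpolation on the band's regular n-stride
    subgrid, with edge replication beyond the outermost samples. Bands
    occupying several mosaic cells are interpolated from the union of
    their subgrids via scattered linear interpolation.
    """
    snapshot = validate_snapshot(snapshot)
    X, Y = snapshot.shape
    n = pattern.size
    if X < n or Y < n:
        raise ValueError(
            f"snapshot {snapshot.shape} smaller than one mosaic period ({n}×{n})"
        )
    C = pattern.n_bands
    cube = np.empty((X, Y, C), dtype=np.float64)
    for c in range(C):
        cells = pattern.band_cells(c)
        if len(cells) == 0:
            raise ValueError(f"band {c} has no sample position in the pattern")
        if len(cells) == 1:
            x0, y0 = (int(v) for v in cells[0])
            vals = snapshot[x0::n, y0::n]
            cube[:, :, c] = _interp_subgrid(vals, x0, y0, n, X, Y)
        else:
            cube[:, :, c] = _interp_scattered(snapshot, cells, n, X, Y)
    return cube


def _interp_scattered(
    snapshot: np.ndarray, cells: np.ndarray, n: int, X: int, Y: int
) -> np.ndarray:
    """Linear interpolation from a union of regular subgrids (rare,
    non-bijective patterns); nearest-sample fill outside the hull."""
    from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

    pts, vals = [], []
    for x0, y0 in cells:
        sx = np.arange(int(x0), X, n)
        sy = np.arange(int(y0), Y, n)
        mx, my = np.meshgrid(sx, sy, indexing="ij")
        pts.append(np.column_stack([mx.ravel(), my.ravel()]))
        vals.append(snapshot[mx, my].ravel())
    pts = np.concatenate(pts).astype(np.float64)
    vals = np.concatenate(vals).astype(np.float64)
    gx, gy = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(np.float64)
    lin = LinearNDInterpolator(pts, vals)
    out = lin(grid)
    hole = np.isnan(out)
    if hole.any():
        out[hole] = NearestNDInterpolator(pts, vals)(grid[hole])
    return out.reshape(X, Y)


# ----------------------------------------------------------------------
# File I/O. Cubes travel as multi-page TIFF (one page per band) or as an
# .npz container with keys "data" and "wavelengths"; snapshots as
# single-channel 8/16-bit PNG/TIFF, normalised to [0, 1] on read.


def write_cube(path: str | Path, cube: np.ndarray, wavelengths: np.ndarray | None = None) -> None:
    import tifffile

    path = Path(path)
    cube = validate_cube(cube)
    if path.suffix == ".npz":
        wl = np.zeros(cube.shape[2]) if wavelengths is None else np.asarray(wavelengths)
        np.savez_compressed(path, data=cube, wavelengths=wl)
    else:
        tifffile.imwrite(
            path,
            np.ascontiguousarray(cube.transpose(2, 0, 1)).astype(np.float32),
            photometric="minisblack",
        )


def read_cube(path: str | Path) -> np.ndarray:
    import tifffile

    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return validate_cube(z["data"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return validate_cube(np.ascontiguousarray(pages.transpose(1, 2, 0)).astype(np.float64))


def write_snapshot(path: str | Path, snapshot: np.ndarray, bit_depth: int = 16) -> None:
    import imageio.v3 as iio

    snapshot = validate_snapshot(snapshot)
    if bit_depth == 16:
        arr = np.clip(np.round(snapshot * 65535.0), 0, 65535).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.clip(np.round(snapshot * 255.0), 0, 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), arr)


def read_snapshot(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim != 2:
        raise ValueError(f"snapshot file must be single-channel; got shape {arr.shape}")
    if arr.dtype.kind in "ui":
        return arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    return validate_snapshot(arr.astype(np.float64))
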