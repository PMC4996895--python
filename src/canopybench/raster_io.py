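"""Raster and sample-table handling.

Containers for single-band rasters, co-registered predictor stacks and
tabular sample sets, plus the preprocessing steps that turn a
fine-resolution canopy height model (CHM) into the 100-m mean canopy
height (MCH) response used throughout the pipeline:

* block-mean aggregation of a fine grid to a coarse grid,
* validity masking (land-cover mask plus a minimum-height rule),
* random extraction of training/test samples from a stack.

Grid convention: indices are 0-based and row-major; pixel (r, c) covers
the half-open square ``[r*s, (r+1)*s) x [c*s, (c+1)*s)`` in metres, where
``s`` is the pixel size, so pixel centers sit at ``(r+0.5)*s``.

Files are plain TIFF (via :mod:`tifffile`) with the grid geometry and
nodata value stored as JSON in the image description tag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    CoRegistrationError,
    InvalidInputError,
    InvalidParameterError,
    SamplingError,
)

logger = logging.getLogger(__name__)

#: Valid band role tags: optical (L), radar backscatter (A), elevation (S),
#: derived texture (T).
ROLES = ("L", "A", "S", "T")


@dataclass(frozen=True)
class GridTransform:
    """Mapping from grid indices to planar coordinates (metres)."""

    pixel_size: float = 100.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError(
                f"pixel_size must be positive, got {self.pixel_size}")

    def pixel_centers(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Return (n, 2) array of (x, y) centers for index pairs."""
        s = self.pixel_size
        x = self.x0 + (np.asarray(cols) + 0.5) * s
        y = self.y0 + (np.asarray(rows) + 0.5) * s
        return np.column_stack([x, y])


@dataclass
class Raster:
    """A single-band georeferenced grid with a validity mask.

    ``nodata_mask`` is True where the pixel is INVALID; masked cells are
    excluded from every statistic computed downstream.
    """

    values: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError(
                f"raster values must be 2-D, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise InvalidInputError("raster is empty")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise InvalidInputError(
                "values and nodata_mask shapes differ: "
                f"{self.values.shape} vs {self.nodata_mask.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.transform,
                      self.nodata_mask.copy())

    def same_grid(self, other: "Raster") -> bool:
        return (self.shape == other.shape
                and self.transform == other.transform)


def _require_same_grid(a: Raster, b: Raster, what: str) -> None:
    if not a.same_grid(b):
        raise CoRegistrationError(
            f"{what}: rasters are not co-registered "
            f"(shapes {a.shape} vs {b.shape}, "
            f"transforms {a.transform} vs {b.transform})")


@dataclass
class LayerStack:
    """A set of co-registered predictor rasters with role tags."""

    bands: list[Raster]
    roles: list[str]
    names: list[str]

    def __post_init__(self) -> None:
        if not self.bands:
            raise InvalidInputError("LayerStack needs at least one band")
        if not (len(self.bands) == len(self.roles) == len(self.names)):
            raise InvalidInputError("bands, roles and names lengths differ")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise InvalidParameterError(
                f"unknown role tags {sorted(bad)}; allowed: {ROLES}")
        first = self.bands[0]
        for b in self.bands[1:]:
            _require_same_grid(first, b, "LayerStack")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands[0].shape

    @property
    def transform(self) -> GridTransform:
        return self.bands[0].transform

    @property
    def valid_mask(self) -> np.ndarray:
        """Joint validity: the intersection of per-band validity."""
        m = self.bands[0].valid_mask.copy()
        for b in self.bands[1:]:
            m &= b.valid_mask
        return m

    def select_roles(self, roles: str) -> "LayerStack":
        """Subset bands whose role tag occurs in ``roles`` (e.g. 'LAS')."""
        keep = [i for i, r in enumerate(self.roles) if r in roles]
        if not keep:
            raise InvalidParameterError(f"no band with role in {roles!r}")
        return LayerStack([self.bands[i] for i in keep],
                          [self.roles[i] for i in keep],
                          [self.names[i] for i in keep])

    def append(self, band: Raster, role: str, name: str) -> None:
        _require_same_grid(self.bands[0], band, "append")
        if role not in ROLES:
            raise InvalidParameterError(f"unknown role {role!r}")
        self.bands.append(band)
        self.roles.append(role)
        self.names.append(name)

    def as_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Pixel-by-band matrix over ``mask`` (default: joint valid mask)."""
        if mask is None:
            mask = self.valid_mask
        return np.column_stack([b.values[mask] for b in self.bands])


@dataclass
class SampleSet:
    """Rows of (predictor vector, response value, pixel coordinate)."""

    X: np.ndarray
    y: np.ndarray | None = None
    names: list[str] | None = None
    row_col: np.ndarray | None = None
    xy: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InvalidInputError("X must be 2-D (n_samples, n_predictors)")
        n = self.X.shape[0]
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (n,):
                raise InvalidInputError(
                    f"y length {self.y.shape} != n_samples {n}")
        if self.names is None:
            self.names = [f"x{i}" for i in range(self.X.shape[1])]
        for attr in ("row_col", "xy"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n, 2):
                    raise InvalidInputError(f"{attr} must have shape (n, 2)")
                setattr(self, attr, v)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "SampleSet":
        return SampleSet(
            self.X[idx],
            None if self.y is None else self.y[idx],
            list(self.names),
            None if self.row_col is None else self.row_col[idx],
            None if self.xy is None else self.xy[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        if self.row_col is not None:
            cols["row"], cols["col"] = self.row_col[:, 0], self.row_col[:, 1]
        if self.xy is not None:
            cols["x"], cols["y"] = self.xy[:, 0], self.xy[:, 1]
        if self.y is not None:
            cols["response"] = self.y
        for j, name in enumerate(self.names):
            cols[name] = self.X[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSet":
        df = pd.read_csv(path)
        special = [c for c in ("row", "col", "x", "y", "response")
                   if c in df.columns]
        pred_cols = [c for c in df.columns if c not in special]
        row_col = (df[["row", "col"]].to_numpy()
                   if {"row", "col"} <= set(special) else None)
        xy = df[["x", "y"]].to_numpy() if {"x", "y"} <= set(special) else None
        y = df["response"].to_numpy() if "response" in special else None
        return cls(df[pred_cols].to_numpy(float), y, pred_cols, row_col, xy)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def aggregate_mean(fine: Raster, factor: int) -> Raster:
    """Aggregate a fine raster to coarse resolution by block averaging.

    Each coarse cell is the arithmetic mean of the unmasked fine cells in
    its ``factor x factor`` block; a coarse cell whose block is entirely
    masked is itself masked.  Trailing partial blocks at the grid edge are
    dropped (and logged), not padded.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise InvalidParameterError(
            f"aggregation factor must be a positive integer, got {factor!r}")
    nr, nc = fine.shape
    cr, cc = nr // factor, nc // factor
    if cr == 0 or cc == 0:
        raise InvalidInputError(
            f"grid {fine.shape} smaller than one {factor}x{factor} block")
    if nr % factor or nc % factor:
        logger.info("aggregate_mean: dropping partial edge blocks "
                    "(%d rows, %d cols)", nr % factor, nc % factor)
    vals = fine.values[:cr * factor, :cc * factor]
    valid = fine.valid_mask[:cr * factor, :cc * factor]

    blocks = (vals * valid).reshape(cr, factor, cc, factor)
    counts = valid.reshape(cr, factor, cc, factor).sum(axis=(1, 3))
    sums = blocks.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    coarse_t = GridTransform(fine.transform.pixel_size * factor,
                             fine.transform.x0, fine.transform.y0)
    return Raster(means, coarse_t, nodata_mask=(counts == 0))


@dataclass(frozen=True)
class MaskCounts:
    """Pixels removed by each validity rule."""

    removed_landcover: int
    removed_height: int


def apply_validity_mask(mch: Raster, landcover_mask: Raster,
                        min_height: float = 1.0) -> tuple[Raster, MaskCounts]:
    """Mask non-vegetated pixels and pixels with MCH <= ``min_height``.

    ``landcover_mask`` is a binary raster (non-zero = vegetated).  The
    land-cover rule is applied first; the height rule then removes further
    pixels from the remainder, so a pixel failing both rules is counted
    under land cover.  Returns the masked raster and the per-rule counts.
    """
    _require_same_grid(mch, landcover_mask, "apply_validity_mask")
    vegetated = (landcover_mask.values != 0) & landcover_mask.valid_mask
    valid0 = mch.valid_mask
    lc_removed = int((valid0 & ~vegetated).sum())
    after_lc = valid0 & vegetated
    tall = mch.values > min_height
    h_removed = int((after_lc & ~tall).sum())
    out = mch.copy()
    out.nodata_mask = ~(after_lc & tall)
    return out, MaskCounts(lc_removed, h_removed)


def extract_samples(stack: LayerStack, response: Raster,
                    n: int | None = None, rng_seed: int | None = None
                    ) -> SampleSet:
    """Sample ``n`` jointly valid pixels uniformly without replacement.

    ``n=None`` takes every valid pixel (in a random permutation).  The
    draw is reproducible under a fixed ``rng_seed``.
    """
    _require_same_grid(stack.bands[0], response, "extract_samples")
    joint = stack.valid_mask & response.valid_mask
    rows, cols = np.nonzero(joint)
    n_valid = rows.size
    if n is None:
        n = n_valid
    if n > n_valid:
        raise SamplingError(
            f"requested {n} samples but only {n_valid} valid pixels")
    rng = np.random.default_rng(rng_seed)
    pick = rng.choice(n_valid, size=n, replace=False)
    r, c = rows[pick], cols[pick]
    X = np.column_stack([b.values[r, c] for b in stack.bands])
    return SampleSet(
        X, response.values[r, c], list(stack.names),
        row_col=np.column_stack([r, c]),
        xy=stack.transform.pixel_centers(r, c),
    )


# ---------------------------------------------------------------------------
# TIFF I/O (grid geometry stored as JSON in the image description)
# ---------------------------------------------------------------------------

def write_raster(path, raster: Raster, nodata: float = -9999.0) -> None:
    vals = np.where(raster.nodata_mask, nodata, raster.values)
    meta = {"pixel_size": raster.transform.pixel_size,
            "x0": raster.transform.x0, "y0": raster.transform.y0,
            "nodata": nodata}
    tifffile.imwrite(path, vals.astype(np.float64),
                     description=json.dumps(meta))


def read_raster(path) -> Raster:
    with tifffile.TiffFile(path) as tf:
        vals = tf.asarray()
        desc = tf.pages[0].description or "{}"
    meta = json.loads(desc)
    t = GridTransform(meta.get("pixel_size", 100.0),
                      meta.get("x0", 0.0), meta.get("y0", 0.0))
    nodata = meta.get("nodata")
    mask = None if nodata is None else (vals == nodata)
    return Raster(vals, t, mask)


def write_stack(path, stack: LayerStack, nodata: float = -9999.0) -> None:
    arr = np.stack([np.where(b.nodata_mask, nodata, b.values)
                    for b in stack.bands])
    t = stack.transform
    meta = {"pixel_size": t.pixel_size, "x0": t.x0, "y0": t.y0,
            "nodata": nodata, "roles": stack.roles, "names": stack.names}
    tifffile.imwrite(path, arr.astype(np.float64),
                     description=json.dumps(meta))


def read_stack(path) -> LayerStack:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or "{}"
    meta = json.loads(desc)
    if arr.ndim == 2:
        arr = arr[None]
    t = GridTransform(meta.get("pixel_size", 100.0),
                      meta.get("x0", 0.0), meta.get("y0", 0.0))
    nodata = meta.get("nodata")
    names = meta.get("names", [f"band{i}" for i in range(arr.shape[0])])
    roles = meta.get("roles", ["L"] * arr.shape[0])
    bands = [Raster(a, t, None if nodata is None else (a == nodata))
             for a in arr]
    return LayerStack(bands, roles, names)
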