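"""Binding-site grid geometry and scalar grids with OpenDX IO.

The canonical grid covers 24 x 24 x 24 A^3 at 0.5 A spacing (48^3 voxels),
cell-centered: voxel k along an axis has its center at
``center - extent/2 + (k + 0.5) * spacing``.
"""

from __future__ import annotations

import os
import re
import tempfile
from dataclasses import dataclass

import numpy as np
from gridData import Grid as _DXGrid


@dataclass(frozen=True)
class GridSpec:
    center: tuple = (0.0, 0.0, 0.0)
    extent: float = 24.0
    spacing: float = 0.5

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.extent <= 0:
            raise ValueError("extent must be > 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def dims(self) -> int:
        return int(round(self.extent / self.spacing))

    @property
    def shape(self) -> tuple:
        d = self.dims
        return (d, d, d)

    @property
    def origin_corner(self) -> np.ndarray:
        """Minimum corner of the grid volume."""
        return np.asarray(self.center) - self.extent / 2.0

    @property
    def first_center(self) -> np.ndarray:
        """Center of voxel (0,0,0)."""
        return self.origin_corner + self.spacing / 2.0

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def axis_centers(self) -> np.ndarray:
        k = np.arange(self.dims)
        return self.first_center[:, None] + k[None, :] * self.spacing  # (3, D)

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers, shape (D, D, D, 3)."""
        ax = self.axis_centers()
        X, Y, Z = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def voxel_index(self, points: np.ndarray) -> np.ndarray:
        """Containing-cell indices for points, shape (N, 3); may be out of
        range for points outside the grid."""
        points = np.atleast_2d(points)
        return np.floor((points - self.origin_corner) / self.spacing).astype(int)

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return np.all((idx >= 0) & (idx < self.dims), axis=1)

    def center_of(self, idx) -> np.ndarray:
        return self.first_center + np.asarray(idx, float) * self.spacing


@dataclass
class ScalarGrid:
    spec: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.spec.shape}"
            )

    @classmethod
    def zeros(cls, spec: GridSpec) -> "ScalarGrid":
        return cls(spec, np.zeros(spec.shape))


def write_grid(grid: ScalarGrid) -> str:
    """Serialize to OpenDX text (origin = first voxel center)."""
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("grid contains non-finite values")
    s = grid.spec
    g = _DXGrid(grid.values, origin=s.first_center, delta=[s.spacing] * 3)
    with tempfile.TemporaryDirectory() as tmp:
        path = os.path.join(tmp, "grid.dx")
        g.export(path, file_format="dx")
        with open(path) as fh:
            return fh.read()


def _validate_dx_counts(text: str) -> None:
    """Check that the body holds as many items as the header declares.

    Guards against truncated input before handing off to gridData, whose
    lexer does not terminate cleanly on unexpected EOF.
    """
    m = re.search(r"items\s+(\d+)\s+data follows", text)
    if m is None:
        raise ValueError("OpenDX input lacks an 'items ... data follows' header")
    declared = int(m.group(1))
    n = 0
    for line in text[m.end():].splitlines():
        line = line.strip()
        if line.startswith(("attribute", "object", "#")):
            break
        n += len(line.split())
    if n < declared:
        raise ValueError(
            f"OpenDX body truncated: {n} values found, header declares {declared}"
        )


def read_grid(text: str) -> ScalarGrid:
    """Read OpenDX text back into a ScalarGrid.

    The header's counts must match the data length; the grid must be cubic
    with isotropic spacing (that is the only geometry this package emits).
    """
    _validate_dx_counts(text)
    try:
        with tempfile.TemporaryDirectory() as tmp:
            path = os.path.join(tmp, "grid.dx")
            with open(path, "w") as fh:
                fh.write(text)
            g = _DXGrid()
            g.load(path, file_format="dx")
    except Exception as exc:  # gridData raises assorted types on bad input
        raise ValueError(f"cannot parse OpenDX input: {exc}") from exc
    shape = g.grid.shape
    if len(set(shape)) != 1:
        raise ValueError(f"only cubic grids are supported, got {shape}")
    delta = np.diag(g.delta) if g.delta.ndim == 2 else np.asarray(g.delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError("anisotropic spacing not supported")
    spacing = float(delta[0])
    d = shape[0]
    origin = np.asarray(g.origin, float)  # first voxel center
    extent = d * spacing
    center = origin - spacing / 2.0 + extent / 2.0
    spec = GridSpec(center=tuple(center), extent=extent, spacing=spacing)
    return ScalarGrid(spec, np.asarray(g.grid, float))
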