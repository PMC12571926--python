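"""Pixel grid geometry: barcode-pair -> coordinate mapping, affine
registration onto a bright-field image, and k-nearest-neighbour smoothing.

Convention: barcode A indexes rows, barcode B indexes columns, both
1-based; pixel (A_i, B_j) sits at grid coordinate (row=i, col=j). The
image frame is x-right / y-down pixel coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class AffineTransform:
    """2-D affine map: image_xy = matrix @ (row, col) + offset."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residuals: np.ndarray | None = None  # per-point fit residual norms

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.offset

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "matrix": self.matrix.tolist(), "offset": self.offset.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["matrix"], float), np.asarray(d["offset"], float))


@dataclass
class PixelGrid:
    """The A x B combinatorial barcode grid of tissue pixels."""

    rows: int
    cols: int
    pixel_size_um: float = 50.0
    transform: AffineTransform | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    def coord(self, a_index: int, b_index: int) -> tuple[int, int]:
        """Map a (barcode A, barcode B) index pair to (row, col), 1-based."""
        if not (1 <= a_index <= self.rows and 1 <= b_index <= self.cols):
            raise ValueError(f"barcode pair ({a_index},{b_index}) outside grid")
        return (a_index, b_index)

    def linear_index(self, a_index: int, b_index: int) -> int:
        """Row-major 0-based position of pixel (A_i, B_j)."""
        r, c = self.coord(a_index, b_index)
        return (r - 1) * self.cols + (c - 1)

    def coordinates(self) -> np.ndarray:
        """(n_pixels, 2) array of (row, col), row-major, 1-based."""
        rr, cc = np.meshgrid(np.arange(1, self.rows + 1),
                             np.arange(1, self.cols + 1), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def make_grid(n_a: int, n_b: int, pixel_size_um: float = 50.0) -> PixelGrid:
    """Build the pixel grid addressed by n_a barcode-A x n_b barcode-B pairs."""
    return PixelGrid(rows=n_a, cols=n_b, pixel_size_um=pixel_size_um)


def register_affine(grid_points: np.ndarray, image_points: np.ndarray) -> AffineTransform:
    """Least-squares affine registration of grid coordinates onto image pixels.

    Requires >= 3 non-collinear correspondences; solves the normal equations
    via ``lstsq`` on the homogeneous design [row, col, 1]. Exact for inputs
    that are themselves affine images of the grid points.
    """
    gp = np.asarray(grid_points, dtype=float)
    ip = np.asarray(image_points, dtype=float)
    if gp.shape != ip.shape or gp.ndim != 2 or gp.shape[1] != 2:
        raise ValueError("grid_points and image_points must both be (n, 2)")
    if gp.shape[0] < 3:
        raise ValueError("at least 3 correspondences required")
    centred = gp - gp.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9) < 2:
        raise ValueError("correspondence points are collinear")
    design = np.column_stack([gp, np.ones(len(gp))])
    coef, *_ = np.linalg.lstsq(design, ip, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    fitted = design @ coef
    residuals = np.linalg.norm(fitted - ip, axis=1)
    return AffineTransform(matrix=matrix, offset=offset, residuals=residuals)


def _knn_indices(grid: PixelGrid, k: int, wrap: bool = False) -> np.ndarray:
    """k nearest pixels (self excluded) per pixel, deterministic ties.

    Ties in Euclidean distance are broken by (row, col) lexicographic order
    of the neighbour. ``wrap=True`` measures distance on a torus, used to
    obtain equal-size neighbourhoods without boundary effects.
    """
    coords = grid.coordinates()
    n = len(coords)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the pixel count {n}")
    dr = np.abs(coords[:, None, 0] - coords[None, :, 0])
    dc = np.abs(coords[:, None, 1] - coords[None, :, 1])
    if wrap:
        dr = np.minimum(dr, grid.rows - dr)
        dc = np.minimum(dc, grid.cols - dc)
    d2 = dr * dr + dc * dc
    np.fill_diagonal(d2, np.inf)
    # lexicographic tie-break: argsort is stable and pixels are already in
    # (row, col) order, so mergesort on distance alone suffices
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def nn_smooth(values: np.ndarray, grid: PixelGrid, k: int,
              include_self: bool = False, wrap: bool = False) -> np.ndarray:
    """Uniform k-nearest-neighbour smoothing of a per-pixel field.

    Each pixel's value becomes the mean over its k nearest pixels by
    Euclidean grid distance (plus itself when ``include_self``). Missing
    values (NaN) are excluded from every mean; a pixel whose whole
    neighbourhood is missing stays missing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    v = np.asarray(values, dtype=float).ravel()
    if v.size != grid.n_pixels:
        raise ValueError(f"values length {v.size} != pixel count {grid.n_pixels}")
    nbr = _knn_indices(grid, k, wrap=wrap)
    neigh_vals = v[nbr]  # (n, k)
    if include_self:
        neigh_vals = np.column_stack([v, neigh_vals])
    obs = ~np.isnan(neigh_vals)
    n_obs = obs.sum(axis=1)
    sums = np.where(obs, neigh_vals, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), np.nan)
    return out
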