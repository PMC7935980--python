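"""Micromagnet shapes and array lattices.

A chip carries a rectilinear lattice of thin-film micromagnets (cobalt layer
under a planarizing spin-on-glass layer), magnetized in-plane along +x.  This
module defines the magnet footprint shapes studied on such chips (circle,
square, equilateral triangle, rectangle), their closed-form areas, a raster
discretization of the footprint into volume cells used by the field solver,
and the lattice of magnet placements.

Coordinates are right-handed: x is the transport direction and the
magnetization axis, z is the chip normal with z = 0 at the top surface of the
magnetic layer.  The spin-on glass occupies z in [0, glass_thickness].
Interfaces use micrometres (thicknesses in nanometres); conversion to SI
metres happens at the field-solver boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapeSpec",
    "ArraySpec",
    "footprint_area",
    "rasterize_footprint",
    "build_lattice",
    "standard_shape",
    "standard_array",
    "STANDARD_GEOMETRIES",
]

_KINDS = ("circle", "square", "triangle", "rectangle")


@dataclass(frozen=True)
class ShapeSpec:
    """Footprint shape of a single micromagnet.

    Parameters
    ----------
    kind:
        One of ``circle``, ``square``, ``triangle``, ``rectangle``.
    lateral_dims:
        Lateral dimensions in micrometres: diameter for a circle, side for a
        square or (equilateral) triangle, ``(x_side, y_side)`` for a
        rectangle.
    thickness_nm:
        Magnetic-layer thickness in nanometres (default 100 nm cobalt).
    triangle_apex_sign:
        Orientation of the triangle: one side is parallel to y and the
        opposite vertex points toward +x (``+1``, default) or -x (``-1``).
        Triangle profiles are not x-symmetric, so the orientation is explicit.
    """

    kind: str
    lateral_dims: tuple[float, ...]
    thickness_nm: float = 100.0
    triangle_apex_sign: int = +1

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; expected one of {_KINDS}")
        dims = tuple(float(d) for d in np.atleast_1d(self.lateral_dims))
        if self.kind == "rectangle":
            if len(dims) != 2:
                raise ValueError("rectangle requires (x_side, y_side) lateral_dims")
        else:
            if len(dims) != 1:
                raise ValueError(f"{self.kind} requires a single lateral dimension")
        if any(d <= 0 for d in dims) or self.thickness_nm <= 0:
            raise ValueError("all dimensions must be positive")
        if self.triangle_apex_sign not in (-1, +1):
            raise ValueError("triangle_apex_sign must be +1 or -1")
        object.__setattr__(self, "lateral_dims", dims)

    # -- closed-form footprint geometry ------------------------------------

    @property
    def area_um2(self) -> float:
        return footprint_area(self)

    @property
    def x_extent_um(self) -> float:
        """Full extent of the footprint along x."""
        if self.kind == "circle":
            return self.lateral_dims[0]
        if self.kind == "square":
            return self.lateral_dims[0]
        if self.kind == "triangle":
            return self.lateral_dims[0] * math.sqrt(3.0) / 2.0
        return self.lateral_dims[0]

    @property
    def y_extent_um(self) -> float:
        if self.kind == "rectangle":
            return self.lateral_dims[1]
        return self.lateral_dims[0]

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-footprint test in magnet-local μm coordinates.

        The footprint is centred on its centroid at (0, 0).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "circle":
            r = self.lateral_dims[0] / 2.0
            return x * x + y * y <= r * r
        if self.kind == "square":
            h = self.lateral_dims[0] / 2.0
            return (np.abs(x) <= h) & (np.abs(y) <= h)
        if self.kind == "rectangle":
            hx = self.lateral_dims[0] / 2.0
            hy = self.lateral_dims[1] / 2.0
            return (np.abs(x) <= hx) & (np.abs(y) <= hy)
        # equilateral triangle, centroid at origin, base parallel to y,
        # apex toward triangle_apex_sign * x
        s = self.lateral_dims[0]
        h = s * math.sqrt(3.0) / 2.0
        xs = self.triangle_apex_sign * x
        # base at xs = -h/3, apex at xs = +2h/3
        inside_x = (xs >= -h / 3.0) & (xs <= 2.0 * h / 3.0)
        half_width = (s / 2.0) * (1.0 - (xs + h / 3.0) / h)
        return inside_x & (np.abs(y) <= half_width)


@dataclass(frozen=True)
class ArraySpec:
    """A rectilinear lattice of identical micromagnets.

    Placement (i, j) sits at ``origin + (i * pitch_x, j * pitch_y)`` for
    i in [0, n_x), j in [0, n_y).  Defaults reproduce the reference chip:
    8 μm pitch, 80 kA/m magnetization along +x, 100 nm Co under 600 nm glass.
    """

    shape: ShapeSpec
    pitch_x_um: float = 8.0
    pitch_y_um: float = 8.0
    n_x: int = 1
    n_y: int = 1
    magnetization_a_m: float = 80.0e3
    glass_thickness_nm: float = 600.0
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.pitch_x_um < self.shape.x_extent_um:
            raise ValueError("pitch_x must be at least the shape's x extent")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("n_x and n_y must be >= 1")
        if self.magnetization_a_m <= 0:
            raise ValueError("magnetization must be positive")

    @property
    def glass_top_um(self) -> float:
        """Height of the spin-on-glass top surface above the magnet top (μm)."""
        return self.glass_thickness_nm * 1e-3

    def bead_plane_um(self, bead_radius_um: float = 1.4) -> float:
        """Default bead-center evaluation height above the magnet top (μm)."""
        return self.glass_top_um + bead_radius_um


def footprint_area(shape: ShapeSpec) -> float:
    """Closed-form footprint area in μm²."""
    d = shape.lateral_dims
    if shape.kind == "circle":
        return math.pi * (d[0] / 2.0) ** 2
    if shape.kind == "square":
        return d[0] ** 2
    if shape.kind == "triangle":
        return math.sqrt(3.0) / 4.0 * d[0] ** 2
    if shape.kind == "rectangle":
        return d[0] * d[1]
    raise ValueError(f"unknown shape kind {shape.kind!r}")


def rasterize_footprint(
    shape: ShapeSpec, cell_size_um: float = 0.25, subsamples: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a magnet footprint into volume cells.

    Cells are squares of side ``cell_size_um`` tiling the footprint bounding
    box; each cell carries a volume proportional to the fraction of its area
    inside the footprint (estimated on a ``subsamples`` × ``subsamples``
    subgrid), so the total rasterized volume tracks the closed-form
    area × thickness closely even for sloped or curved boundaries.  Cell
    centres carry a z coordinate at magnet mid-thickness (half the layer
    thickness below z = 0), which is where the field solver places the
    per-cell dipoles.

    Returns
    -------
    centers : (n, 3) float array of cell-centre coordinates in μm
    cell_volumes_um3 : (n,) per-cell volumes in μm³
    """
    min_dim = min(shape.lateral_dims)
    if cell_size_um > min_dim / 8.0 + 1e-12:
        raise ValueError(
            f"cell_size {cell_size_um} μm too coarse: must be <= "
            f"{min_dim / 8.0:.4g} μm (min lateral dimension / 8)"
        )
    hx = shape.x_extent_um / 2.0
    hy = shape.y_extent_um / 2.0
    # symmetric grid of cell centres covering the bounding box
    nx = int(math.ceil(2.0 * hx / cell_size_um))
    ny = int(math.ceil(2.0 * hy / cell_size_um))
    xs = (np.arange(nx) - (nx - 1) / 2.0) * cell_size_um
    ys = (np.arange(ny) - (ny - 1) / 2.0) * cell_size_um
    # triangle centroid offset: bounding box is not centred on the centroid
    if shape.kind == "triangle":
        s = shape.lateral_dims[0]
        h = s * math.sqrt(3.0) / 2.0
        # footprint spans xs-local [-h/3, 2h/3]: shift grid to cover it
        xs = xs + shape.triangle_apex_sign * (h / 6.0)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    # fractional coverage on a subgrid within each cell
    sub = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    coverage = np.zeros_like(X)
    for du in sub:
        for dv in sub:
            coverage += shape.contains(X + du * cell_size_um, Y + dv * cell_size_um)
    coverage /= subsamples**2
    mask = coverage > 0.0
    if not np.any(mask):
        raise ValueError("rasterization produced no cells")
    z_mid = -shape.thickness_nm * 1e-3 / 2.0
    centers = np.column_stack(
        [X[mask], Y[mask], np.full(int(mask.sum()), z_mid)]
    )
    volumes = coverage[mask] * cell_size_um**2 * shape.thickness_nm * 1e-3
    return centers, volumes


def build_lattice(array: ArraySpec) -> np.ndarray:
    """Magnet centre placements, shape (n_x * n_y, 2), in μm."""
    ox, oy = array.origin_um
    i = np.arange(array.n_x)
    j = np.arange(array.n_y)
    I, J = np.meshgrid(i, j, indexing="xy")
    return np.column_stack(
        [ox + I.ravel() * array.pitch_x_um, oy + J.ravel() * array.pitch_y_um]
    )


# -- the four reference geometries ----------------------------------------

def standard_shape(code: str) -> ShapeSpec:
    """Reference magnet shapes: C(ircle), S(quare), T(riangle), R(ectangle).

    5 μm critical dimension; the rectangle is 5 x 12.5 μm.
    """
    code = code.upper()
    if code == "C":
        return ShapeSpec("circle", (5.0,))
    if code == "S":
        return ShapeSpec("square", (5.0,))
    if code == "T":
        return ShapeSpec("triangle", (5.0,))
    if code == "R":
        return ShapeSpec("rectangle", (5.0, 12.5))
    raise ValueError(f"unknown geometry code {code!r}; expected C, S, T or R")


def standard_array(code: str, n_x: int = 1, n_y: int = 1) -> ArraySpec:
    """Reference arrays: 8 μm pitch (8 x 16 μm for the rectangle array)."""
    shape = standard_shape(code)
    pitch_y = 16.0 if code.upper() == "R" else 8.0
    return ArraySpec(shape=shape, pitch_x_um=8.0, pitch_y_um=pitch_y, n_x=n_x, n_y=n_y)


STANDARD_GEOMETRIES = ("C", "S", "T", "R")
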