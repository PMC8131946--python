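"""Phase-field grids, the double-well potential and discrete operators.

The inpainting model evolves an order parameter ``phi`` whose pure phases
``phi = -1`` (background) and ``phi = +1`` (ink) encode the two colours of a
binary image.  Everything here is cell-averaged on a uniform rectangular
grid, the natural discretization for raster images: one finite-volume cell
per pixel.

The module provides the Ginzburg-Landau double well ``H(phi) =
(phi^2-1)^2/4`` and its convex/concave ("contractive"/"expansive") split
``H = H_c - H_e`` with ``H_c = (phi^4+1)/4`` and ``H_e = phi^2/2``, the
five-point Laplacian with reflecting (no-flux) ghost cells, and the discrete
free energy

    E[phi] = dx*dy * sum_cells H(phi)
           + (eps^2/2) * dx*dy * sum_faces (d_face phi)^2

whose decay under the semi-implicit scheme is the solver's stability
property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhaseField",
    "FidelityField",
    "double_well",
    "double_well_prime",
    "convex_split",
    "convex_split_derivatives",
    "laplacian_noflux",
    "discrete_free_energy",
    "build_fidelity",
]


class ShapeError(ValueError):
    """Grid shapes do not line up."""


class ConfigError(ValueError):
    """Invalid numerical parameter (cell size, tolerance, ...)."""


@dataclass
class PhaseField:
    """Cell-averaged phase field on a uniform ``ny x nx`` grid.

    ``values[j, i]`` is the average of ``phi`` over cell ``(i, j)`` with row
    index ``j`` counting from the top of the image and column index ``i``
    from the left.  ``dx`` and ``dy`` are the cell sizes (pixel pitch,
    default 1 as in the image setting).
    """

    values: np.ndarray
    dx: float = 1.0
    dy: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"phase field must be 2-D, got shape {self.values.shape}")
        if not (self.dx > 0 and self.dy > 0):
            raise ConfigError(f"cell sizes must be positive, got dx={self.dx}, dy={self.dy}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase field contains non-finite values")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def copy(self) -> "PhaseField":
        return PhaseField(self.values.copy(), self.dx, self.dy)


@dataclass
class FidelityField:
    """Per-cell fidelity weights ``lam`` keeping undamaged cells anchored.

    ``lam`` is 0 on the inpainting domain D (``mask`` true) and ``lam0``
    elsewhere, so the penalty ``lam * (phi0 - phi)`` acts only outside the
    damage.
    """

    lam: np.ndarray
    lam0: float
    mask: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lam.shape


def double_well(phi):
    """Ginzburg-Landau double-well potential ``H(phi) = (phi^2 - 1)^2 / 4``.

    Non-negative, with minima (value 0) exactly at the two pure phases
    ``phi = -1`` and ``phi = +1``.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("double_well requires finite input")
    out = 0.25 * (phi * phi - 1.0) ** 2
    return out if out.ndim else float(out)


def double_well_prime(phi):
    """Derivative ``H'(phi) = phi^3 - phi``."""
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("double_well_prime requires finite input")
    out = phi**3 - phi
    return out if out.ndim else float(out)


def convex_split(phi):
    """Convex split ``H = H_c - H_e``: returns ``(H_c, H_e)``.

    ``H_c(phi) = (phi^4 + 1)/4`` (contractive, treated implicitly) and
    ``H_e(phi) = phi^2/2`` (expansive, treated explicitly); both convex.
    """
    phi = np.asarray(phi, dtype=float)
    hc = 0.25 * (phi**4 + 1.0)
    he = 0.5 * phi * phi
    if phi.ndim:
        return hc, he
    return float(hc), float(he)


def convex_split_derivatives(phi):
    """Derivatives of the convex split: ``(H_c'(phi), H_e'(phi)) = (phi^3, phi)``.

    The identity ``H_c' - H_e' = H'`` holds for every phi.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("convex_split_derivatives requires finite input")
    hc_p = phi**3
    he_p = phi.copy() if phi.ndim else float(phi)
    if phi.ndim:
        return hc_p, he_p
    return float(hc_p), float(he_p)


def laplacian_noflux(grid: np.ndarray, dx: float = 1.0, dy: float = 1.0) -> np.ndarray:
    """Five-point Laplacian with reflecting ghost cells (zero normal gradient).

    Ghost values equal the adjacent interior value, so boundary faces carry
    zero flux and the output sums to zero over the grid (discrete divergence
    theorem).  Axis 0 is y (rows), axis 1 is x (columns).
    """
    if not (dx > 0 and dy > 0):
        raise ConfigError(f"cell sizes must be positive, got dx={dx}, dy={dy}")
    g = np.asarray(grid, dtype=float)
    if g.ndim != 2:
        raise ShapeError(f"expected a 2-D grid, got shape {g.shape}")
    out = np.zeros_like(g)
    if g.shape[1] > 1:
        inv_dx2 = 1.0 / (dx * dx)
        out[:, 1:-1] += (g[:, 2:] - 2.0 * g[:, 1:-1] + g[:, :-2]) * inv_dx2
        out[:, 0] += (g[:, 1] - g[:, 0]) * inv_dx2
        out[:, -1] += (g[:, -2] - g[:, -1]) * inv_dx2
    if g.shape[0] > 1:
        inv_dy2 = 1.0 / (dy * dy)
        out[1:-1, :] += (g[2:, :] - 2.0 * g[1:-1, :] + g[:-2, :]) * inv_dy2
        out[0, :] += (g[1, :] - g[0, :]) * inv_dy2
        out[-1, :] += (g[-2, :] - g[-1, :]) * inv_dy2
    return out


def discrete_free_energy(fld: PhaseField, eps: float) -> float:
    """Discrete Ginzburg-Landau free energy of a phase field.

    Bulk term: cell area times the double well summed over cells.  Gradient
    term: forward differences across interior faces, matching the stencil of
    :func:`laplacian_noflux` so that the convex-splitting step decays exactly
    this quantity.  Zero iff the field is uniformly +1 or -1.
    """
    if eps <= 0:
        raise ConfigError(f"eps must be positive, got {eps}")
    phi = fld.values
    area = fld.cell_area
    bulk = area * float(np.sum(double_well(phi)))
    gx = (phi[:, 1:] - phi[:, :-1]) / fld.dx
    gy = (phi[1:, :] - phi[:-1, :]) / fld.dy
    grad = 0.5 * eps * eps * area * (float(np.sum(gx * gx)) + float(np.sum(gy * gy)))
    return bulk + grad


def build_fidelity(mask: np.ndarray, lam0: float, shape: tuple[int, int] | None = None) -> FidelityField:
    """Build the fidelity grid: ``lam = 0`` on masked (damaged) cells, ``lam0`` elsewhere.

    ``shape``, if given, is the target image shape the mask must match.
    """
    if lam0 < 0:
        raise ConfigError(f"lam0 must be non-negative, got {lam0}")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ShapeError(f"mask must be 2-D, got shape {mask.shape}")
    if shape is not None and tuple(mask.shape) != tuple(shape):
        raise ShapeError(f"mask shape {mask.shape} does not match image shape {tuple(shape)}")
    lam = np.where(mask, 0.0, float(lam0))
    return FidelityField(lam=lam, lam0=float(lam0), mask=mask)
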