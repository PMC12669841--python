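"""Local tricubic interpolation on a regular grid (Lekien–Marsden scheme).

Each grid cell carries a full tricubic polynomial determined by the values
and mixed derivatives (f, fx, fy, fz, fxy, fxz, fyz, fxyz) at its eight
corners.  Corner derivatives are estimated by finite differences on the node
lattice with five-point stencils (fourth-order central in the interior,
one-sided near the edges), which differentiate polynomials up to degree four
exactly; the interpolant therefore reproduces any field that is a tricubic
polynomial, and is C1 across cell boundaries because adjacent cells share
corner data.

Queries must stay at least one node ring away from the grid boundary; points
outside that interior raise :class:`~romkit.errors.OutOfDomainError`.
"""

from __future__ import annotations

import numpy as np

from .errors import OutOfDomainError

__all__ = ["TricubicInterpolator"]


def _diff_weights(offsets: np.ndarray) -> np.ndarray:
    """First-derivative stencil weights at offset 0 for the given node offsets.

    Solves the Vandermonde moment conditions, so a stencil over ``m`` nodes is
    exact for polynomials of degree ``m - 1``.
    """
    offsets = np.asarray(offsets, dtype=float)
    m = len(offsets)
    A = np.vander(offsets, m, increasing=True).T  # A[k, j] = offsets[j]**k
    b = np.zeros(m)
    b[1] = 1.0  # first derivative of x**k at 0 is delta_{k,1}
    return np.linalg.solve(A, b)


def _axis_derivative(values: np.ndarray, axis: int) -> np.ndarray:
    """Differentiate along one axis in node-index units."""
    n = values.shape[axis]
    width = min(5, n)
    v = np.moveaxis(values, axis, 0)
    out = np.empty_like(v)
    for i in range(n):
        lo = min(max(i - width // 2, 0), n - width)
        w = _diff_weights(np.arange(lo, lo + width) - i)
        out[i] = np.tensordot(w, v[lo:lo + width], axes=(0, 0))
    return np.moveaxis(out, 0, axis)


def _lm_matrix_inverse() -> np.ndarray:
    """Inverse of the 64x64 constraint matrix on the unit cell.

    Coefficient order: a[i + 4j + 16k] multiplies x^i y^j z^k.  Constraint
    order: derivative index d = dx + 2dy + 4dz (0/1 each), corner index
    c = cx + 2cy + 4cz, row = 8d + c.
    """
    B = np.zeros((64, 64))
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                d = dx + 2 * dy + 4 * dz
                for cz in (0, 1):
                    for cy in (0, 1):
                        for cx in (0, 1):
                            c = cx + 2 * cy + 4 * cz
                            row = 8 * d + c
                            for k in range(4):
                                for j in range(4):
                                    for i in range(4):
                                        col = i + 4 * j + 16 * k
                                        B[row, col] = (
                                            _mono_deriv(i, dx, cx)
                                            * _mono_deriv(j, dy, cy)
                                            * _mono_deriv(k, dz, cz)
                                        )
    return np.linalg.inv(B)


def _mono_deriv(power: int, order: int, x: float) -> float:
    if order == 0:
        return float(x ** power)
    if power == 0:
        return 0.0
    return float(power * x ** (power - 1))


_BINV = _lm_matrix_inverse()

# stack order indexed by d = dx + 2dy + 4dz
_DERIV_SPECS = [(), (0,), (1,), (0, 1), (2,), (0, 2), (1, 2), (0, 1, 2)]

_CORNERS = np.array(
    [[cx, cy, cz] for cz in (0, 1) for cy in (0, 1) for cx in (0, 1)]
)  # c = cx + 2cy + 4cz ordering

_DOMAIN_TOL = 1e-9

_I_IDX = np.arange(64) % 4
_J_IDX = (np.arange(64) // 4) % 4
_K_IDX = np.arange(64) // 16


class TricubicInterpolator:
    """On-demand tricubic evaluation of a scalar field on a regular grid.

    Parameters
    ----------
    values
        Node values, shape ``(nx, ny, nz)`` with every axis >= 4.
    origin
        World coordinates of node ``(0, 0, 0)``.
    spacing
        Uniform node spacing (same for all axes).
    """

    def __init__(self, values: np.ndarray, origin, spacing: float):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or min(values.shape) < 4:
            raise ValueError("need a 3-D grid with at least 4 nodes per axis")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid values must be finite")
        self.origin = np.asarray(origin, dtype=float)
        self.spacing = float(spacing)
        self.shape = values.shape
        # Precompute the 8 derivative stacks in node-index units.
        stacks = [values]
        for spec in _DERIV_SPECS[1:]:
            d = values
            for ax in spec:
                d = _axis_derivative(d, ax)
            stacks.append(d)
        self._stack = np.stack(stacks)  # (8, nx, ny, nz)
        # per-cell interpolation coefficients, filled lazily; a flat array
        # cache for grids of ordinary size, a dict above ~300k cells
        n_cells = int(np.prod(np.array(self.shape) - 1))
        self._use_array_cache = n_cells <= 300_000
        if self._use_array_cache:
            self._coeff_arr = np.empty((n_cells, 64))
            self._coeff_known = np.zeros(n_cells, dtype=bool)
        self._coeff_cache: dict[int, np.ndarray] = {}

    # ------------------------------------------------------------------
    def _locate(self, points: np.ndarray):
        g = (points - self.origin) / self.spacing
        n = np.array(self.shape)
        lo, hi = 1.0 - _DOMAIN_TOL, (n - 2.0) + _DOMAIN_TOL
        bad = np.any((g < lo) | (g > hi), axis=-1)
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise OutOfDomainError(
                f"point {points.reshape(-1, 3)[idx]} outside the interpolable "
                f"interior of the grid (one-node boundary ring excluded)"
            )
        cell = np.clip(np.floor(g).astype(int), 1, n - 3)
        local = g - cell
        return cell, local

    def _assemble_rhs(self, cell: np.ndarray) -> np.ndarray:
        ix, iy, iz = cell[:, 0], cell[:, 1], cell[:, 2]
        rhs = np.empty((64, len(cell)))
        for d in range(8):
            grid = self._stack[d]
            for c, (ox, oy, oz) in enumerate(_CORNERS):
                rhs[8 * d + c] = grid[ix + ox, iy + oy, iz + oz]
        return rhs

    def _cell_coefficients(self, cell: np.ndarray) -> np.ndarray:
        """Per-point coefficient columns, memoized per grid cell."""
        cy, cz = self.shape[1] - 1, self.shape[2] - 1
        keys = (cell[:, 0] * cy + cell[:, 1]) * cz + cell[:, 2]
        if self._use_array_cache:
            missing = keys[~self._coeff_known[keys]]
            if missing.size:
                uniq = np.unique(missing)
                mcells = np.stack([uniq // (cy * cz), (uniq // cz) % cy,
                                   uniq % cz], axis=-1)
                self._coeff_arr[uniq] = (_BINV @ self._assemble_rhs(mcells)).T
                self._coeff_known[uniq] = True
            return self._coeff_arr[keys].T
        uniq, inv = np.unique(keys, return_inverse=True)
        missing = [k for k in uniq if int(k) not in self._coeff_cache]
        if missing:
            m = np.asarray(missing)
            mcells = np.stack([m // (cy * cz), (m // cz) % cy, m % cz],
                              axis=-1)
            new = _BINV @ self._assemble_rhs(mcells)
            for i, k in enumerate(missing):
                self._coeff_cache[int(k)] = new[:, i]
            if len(self._coeff_cache) > 500_000:
                self._coeff_cache.clear()
        cols = np.stack([self._coeff_cache[int(k)] for k in uniq], axis=1)
        return cols[:, inv]

    # ------------------------------------------------------------------
    def evaluate(self, points, gradient: bool = False):
        """Interpolate at ``points`` (shape ``(n, 3)`` or ``(3,)``).

        With ``gradient=True`` also returns the analytic gradient of the
        interpolant, in world units per mm.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cell, local = self._locate(pts)
        coeff = self._cell_coefficients(cell)  # (64, n); row i+4j+16k ~ x^i y^j z^k
        npts = len(pts)
        pow_ = np.ones((3, 4, npts))
        pow_[:, 1] = local.T
        pow_[:, 2] = pow_[:, 1] * pow_[:, 1]
        pow_[:, 3] = pow_[:, 2] * pow_[:, 1]
        px, py, pz = pow_
        mono = px[_I_IDX] * py[_J_IDX] * pz[_K_IDX]  # (64, n)
        val = np.einsum("cn,cn->n", coeff, mono)
        if not gradient:
            return val if np.ndim(points) > 1 else float(val[0])

        dpow = np.zeros((3, 4, npts))
        dpow[:, 1] = 1.0
        dpow[:, 2] = 2.0 * pow_[:, 1]
        dpow[:, 3] = 3.0 * pow_[:, 2]
        dx, dy, dz = dpow
        grad = np.empty((npts, 3))
        grad[:, 0] = np.einsum("cn,cn->n", coeff,
                               dx[_I_IDX] * py[_J_IDX] * pz[_K_IDX])
        grad[:, 1] = np.einsum("cn,cn->n", coeff,
                               px[_I_IDX] * dy[_J_IDX] * pz[_K_IDX])
        grad[:, 2] = np.einsum("cn,cn->n", coeff,
                               px[_I_IDX] * py[_J_IDX] * dz[_K_IDX])
        grad /= self.spacing
        if np.ndim(points) > 1:
            return val, grad
        return float(val[0]), grad[0]
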