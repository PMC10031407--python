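"""Kirchhoff–Love plate finite elements on a uniform rectangular mesh.

The bending element is the Bogner–Fox–Schmit (BFS) rectangle: a C1-conforming
quadrilateral built from products of 1-D cubic Hermite polynomials, with four
degrees of freedom per node (w, w_x, w_y, w_xy).  On a uniform mesh every
element shares the same reference matrices, so the element stiffness is a
scalar (the bending rigidity D) times a precomputed 16x16 block and assembly
is fully vectorised.

The plate is clamped along the edge x = 0 (the wing base) and free elsewhere.
Transverse dynamics are integrated with the implicit backward Euler scheme
(BDF of order 1) on the first-order form of  M q'' + C q' + K q = F(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh, splu

__all__ = ["PlateModel", "PlateAssemblyError", "SimulationDivergedError"]


class PlateAssemblyError(RuntimeError):
    """Raised when the assembled structural system is unusable (singular/indefinite)."""


class SimulationDivergedError(RuntimeError):
    """Raised when the time integration produces non-finite state."""


# ---------------------------------------------------------------------------
# 1-D cubic Hermite shape functions on [0, L], parameterised by xi = x / L.
# Order: value at 0, slope at 0, value at 1, slope at 1.
# ---------------------------------------------------------------------------

def _hermite(xi: np.ndarray, L: float, deriv: int) -> np.ndarray:
    """Return the four Hermite functions (rows) evaluated at xi (columns)."""
    xi = np.asarray(xi, dtype=float)
    if deriv == 0:
        rows = [
            1 - 3 * xi**2 + 2 * xi**3,
            L * (xi - 2 * xi**2 + xi**3),
            3 * xi**2 - 2 * xi**3,
            L * (-(xi**2) + xi**3),
        ]
    elif deriv == 1:
        rows = [
            (-6 * xi + 6 * xi**2) / L,
            1 - 4 * xi + 3 * xi**2,
            (6 * xi - 6 * xi**2) / L,
            -2 * xi + 3 * xi**2,
        ]
    elif deriv == 2:
        rows = [
            (-6 + 12 * xi) / L**2,
            (-4 + 6 * xi) / L,
            (6 - 12 * xi) / L**2,
            (-2 + 6 * xi) / L,
        ]
    else:  # pragma: no cover - internal misuse
        raise ValueError(deriv)
    return np.vstack(rows)


def _reference_matrices(a: float, b: float, poisson: float):
    """Reference element matrices on an a x b BFS rectangle.

    Returns (K_unit, M_unit, P0, Px, Py) where
      K_unit : 16x16 bending stiffness for unit rigidity D = 1,
      M_unit : 16x16 mass matrix for unit surface density rho*h = 1,
      P0, Px, Py : 16-vectors of the consistent load integrals
        int N dA, int N * x_local dA, int N * y_local dA.
    """
    ng = 4
    gx, wx = np.polynomial.legendre.leggauss(ng)
    xi = 0.5 * (gx + 1.0)      # map to [0, 1]
    wq = 0.5 * wx              # weights on [0, 1]

    hx0 = _hermite(xi, a, 0)
    hx1 = _hermite(xi, a, 1)
    hx2 = _hermite(xi, a, 2)
    hy0 = _hermite(xi, b, 0)
    hy1 = _hermite(xi, b, 1)
    hy2 = _hermite(xi, b, 2)

    # Local DOF ordering: nodes [(0,0), (1,0), (0,1), (1,1)], per node
    # (w, w_x, w_y, w_xy).  Each shape function is Hx[p](x) * Hy[q](y).
    # Index pairs (p, q) into the 1-D Hermite rows:
    pairs = []
    for (i, j) in [(0, 0), (1, 0), (0, 1), (1, 1)]:
        # value/slope rows for x-end i are (2*i, 2*i+1); same for y.
        pairs += [
            (2 * i, 2 * j),          # w
            (2 * i + 1, 2 * j),      # w_x
            (2 * i, 2 * j + 1),      # w_y
            (2 * i + 1, 2 * j + 1),  # w_xy
        ]

    # Shape values and second derivatives at the ng x ng quadrature grid.
    N = np.empty((16, ng, ng))
    Nxx = np.empty((16, ng, ng))
    Nyy = np.empty((16, ng, ng))
    Nxy = np.empty((16, ng, ng))
    for k, (p, q) in enumerate(pairs):
        N[k] = np.outer(hx0[p], hy0[q])
        Nxx[k] = np.outer(hx2[p], hy0[q])
        Nyy[k] = np.outer(hx0[p], hy2[q])
        Nxy[k] = np.outer(hx1[p], hy1[q])

    W = (a * b) * np.outer(wq, wq)  # quadrature weights incl. Jacobian

    C = np.array(
        [[1.0, poisson, 0.0],
         [poisson, 1.0, 0.0],
         [0.0, 0.0, (1.0 - poisson) / 2.0]]
    )
    # Curvature vector kappa = [w_xx, w_yy, 2 w_xy]
    B = np.stack([Nxx, Nyy, 2.0 * Nxy], axis=1).reshape(16, 3, -1)
    K_unit = np.einsum("iap,ab,jbp->ij", B * W.reshape(1, 1, -1), C, B)

    M_unit = np.einsum("ip,jp->ij", N.reshape(16, -1) * W.reshape(1, -1), N.reshape(16, -1))

    xloc = a * xi
    yloc = b * xi
    Xg = np.outer(xloc, np.ones(ng))
    Yg = np.outer(np.ones(ng), yloc)
    P0 = (N * W).reshape(16, -1).sum(axis=1)
    Px = (N * (W * Xg)).reshape(16, -1).sum(axis=1)
    Py = (N * (W * Yg)).reshape(16, -1).sum(axis=1)

    return K_unit, M_unit, P0, Px, Py


@dataclass
class StepRecord:
    """Time-integration output."""

    times: np.ndarray                 # (n_steps + 1,)
    strain: np.ndarray                # (n_nodes, n_steps + 1) spanwise surface strain
    tip_deflection: np.ndarray        # (n_steps + 1,) w at the tip mid-chord node
    q: np.ndarray                     # final displacement state (free DOFs)
    v: np.ndarray                     # final velocity state (free DOFs)
    energy: np.ndarray | None = None  # (n_steps + 1,) strain + kinetic energy


class PlateModel:
    """Assembled clamped-free Kirchhoff plate with nodewise Young's modulus.

    Parameters
    ----------
    span, chord, thickness : float
        Plate dimensions in metres; the clamped edge runs along x = 0.
    density, poisson : float
        Material density (kg m^-3) and Poisson ratio.
    E_nodes : ndarray, shape (n_chord_nodes, n_span_nodes)
        Young's modulus sampled at grid nodes; element rigidity uses the
        mean of its four corner values.
    nx, ny : int
        Element counts along span and chord (nodes are nx+1 by ny+1).
    """

    def __init__(self, span, chord, thickness, density, poisson, E_nodes,
                 nx=50, ny=25):
        self.span = float(span)
        self.chord = float(chord)
        self.thickness = float(thickness)
        self.density = float(density)
        self.poisson = float(poisson)
        self.nx = int(nx)
        self.ny = int(ny)
        if self.nx < 1 or self.ny < 1:
            raise ValueError("mesh must have at least one element per direction")

        E_nodes = np.asarray(E_nodes, dtype=float)
        if E_nodes.shape != (self.ny + 1, self.nx + 1):
            raise ValueError(
                f"E_nodes shape {E_nodes.shape} does not match node grid "
                f"{(self.ny + 1, self.nx + 1)}"
            )
        if not np.all(np.isfinite(E_nodes)) or np.any(E_nodes <= 0):
            raise PlateAssemblyError("Young's modulus must be positive and finite")

        a = self.span / self.nx
        b = self.chord / self.ny
        self.dx, self.dy = a, b

        # node coordinates, x fastest (row-major over (iy, ix))
        xs = np.linspace(0.0, self.span, self.nx + 1)
        ys = np.linspace(0.0, self.chord, self.ny + 1)
        XX, YY = np.meshgrid(xs, ys)          # (ny+1, nx+1)
        self.x_nodes = xs
        self.y_nodes = ys
        self.X = XX.ravel()
        self.Y = YY.ravel()
        self.n_nodes = (self.nx + 1) * (self.ny + 1)
        self.n_dof = 4 * self.n_nodes

        K_unit, M_unit, P0, Px, Py = _reference_matrices(a, b, self.poisson)

        # element -> corner node ids
        ex, ey = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        ex = ex.ravel()
        ey = ey.ravel()
        n00 = ey * (self.nx + 1) + ex
        corners = np.stack([n00, n00 + 1, n00 + (self.nx + 1),
                            n00 + (self.nx + 1) + 1], axis=1)  # (nel, 4)
        edofs = (4 * corners[:, :, None] + np.arange(4)[None, None, :]
                 ).reshape(-1, 16)  # (nel, 16)
        nel = edofs.shape[0]

        Egrid = E_nodes
        Ecorn = np.stack([Egrid[ey, ex], Egrid[ey, ex + 1],
                          Egrid[ey + 1, ex], Egrid[ey + 1, ex + 1]], axis=1)
        E_el = Ecorn.mean(axis=1)
        D_el = E_el * self.thickness**3 / (12.0 * (1.0 - self.poisson**2))
        rho_h = self.density * self.thickness

        rows = np.repeat(edofs, 16, axis=1).ravel()
        cols = np.tile(edofs, (1, 16)).ravel()
        Kdata = (D_el[:, None, None] * K_unit[None]).ravel()
        Mdata = np.tile((rho_h * M_unit).ravel(), nel)
        self.K = sp.coo_matrix((Kdata, (rows, cols)),
                               shape=(self.n_dof, self.n_dof)).tocsr()
        self.M = sp.coo_matrix((Mdata, (rows, cols)),
                               shape=(self.n_dof, self.n_dof)).tocsr()

        # consistent load vectors for p(x, y) = 1, x, y  (per unit pressure)
        x0 = ex * a
        y0 = ey * b
        L0 = np.zeros(self.n_dof)
        LX = np.zeros(self.n_dof)
        LY = np.zeros(self.n_dof)
        np.add.at(L0, edofs.ravel(), np.tile(P0, nel))
        np.add.at(LX, edofs.ravel(), (x0[:, None] * P0[None] + Px[None]).ravel())
        np.add.at(LY, edofs.ravel(), (y0[:, None] * P0[None] + Py[None]).ravel())
        self.L0, self.LX, self.LY = L0, LX, LY

        self.mass = self.span * self.chord * self.thickness * self.density

        # clamped edge x = 0: all four DOFs of nodes with ix == 0
        ix = np.tile(np.arange(self.nx + 1), self.ny + 1)
        clamped_nodes = np.flatnonzero(ix == 0)
        fixed = (4 * clamped_nodes[:, None] + np.arange(4)[None]).ravel()
        free_mask = np.ones(self.n_dof, dtype=bool)
        free_mask[fixed] = False
        self.free = np.flatnonzero(free_mask)

        self.Kff = self.K[self.free][:, self.free].tocsc()
        self.Mff = self.M[self.free][:, self.free].tocsc()
        self.L0f = L0[self.free]
        self.LXf = LX[self.free]
        self.LYf = LY[self.free]

        self._strain_matrix = self._build_strain_matrix()
        # node at tip, mid chord (for convergence diagnostics)
        iy_mid = (self.ny + 1) // 2
        self._tip_w_dof = 4 * (iy_mid * (self.nx + 1) + self.nx)

    # ------------------------------------------------------------------
    def _build_strain_matrix(self) -> sp.csr_matrix:
        """Sparse map from the free DOF vector to nodal surface strain.

        eps_xx = -(h/2) w_xx on the top surface; w_xx at a node is the
        Hermite end-curvature of the spanwise interval(s) touching it,
        averaged where two intervals meet.
        """
        a = self.dx
        rows, cols, vals, counts = [], [], [], np.zeros(self.n_nodes)
        for iy in range(self.ny + 1):
            base = iy * (self.nx + 1)
            for ixl in range(self.nx):
                nL = base + ixl
                nR = nL + 1
                dofs = [4 * nL, 4 * nL + 1, 4 * nR, 4 * nR + 1]  # w_L, wx_L, w_R, wx_R
                left_stencil = [-6 / a**2, -4 / a, 6 / a**2, -2 / a]
                right_stencil = [6 / a**2, 2 / a, -6 / a**2, 4 / a]
                for node, stencil in ((nL, left_stencil), (nR, right_stencil)):
                    rows += [node] * 4
                    cols += dofs
                    vals += stencil
                    counts[node] += 1
        S = sp.coo_matrix((vals, (rows, cols)),
                          shape=(self.n_nodes, self.n_dof)).tocsr()
        S = sp.diags(1.0 / counts) @ S
        S = (-self.thickness / 2.0) * S
        return S[:, self.free].tocsr()

    # ------------------------------------------------------------------
    def eigenfrequencies(self, n_modes: int = 1):
        """Lowest undamped structural eigenfrequencies (rad/s) and mode shapes.

        Solves K phi = omega^2 M phi on the free DOFs via shift-invert
        Lanczos about zero.
        """
        try:
            # fixed start vector keeps repeated runs bit-identical
            v0 = np.ones(self.Kff.shape[0])
            vals, vecs = eigsh(self.Kff, k=n_modes, M=self.Mff,
                               sigma=0.0, which="LM", v0=v0)
        except RuntimeError as exc:  # singular factorization etc.
            raise PlateAssemblyError(f"eigen solve failed: {exc}") from exc
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise PlateAssemblyError("assembled system is not positive definite")
        order = np.argsort(vals)
        omega = np.sqrt(vals[order])
        modes = np.zeros((self.n_dof, n_modes))
        modes[self.free] = vecs[:, order]
        return omega, modes

    # ------------------------------------------------------------------
    def integrate(self, g_x, g_y, dt: float, n_steps: int, c_total: float,
                  q0=None, v0=None, record_energy: bool = False,
                  t0: float = 0.0, Lx=None, Ly=None) -> StepRecord:
        """Backward-Euler (BDF-1) integration of the damped forced plate.

        The transverse load per unit area is p(x, y, t) =
        -rho*h*(g_x(t)*x + g_y(t)*y), the inertial load of the prescribed
        rigid-body motion; g_x and g_y are callables of time.  Damping is
        mass-proportional, C = (c_total / mass) * M, which makes the summed
        nodal damping force on any rigid transverse velocity V equal to
        -c_total * V.  ``Lx``/``Ly`` override the consistent load vectors
        multiplying g_x and g_y (free-DOF length); by default the moment
        arms are x and y measured from the plate origin.
        """
        Lx = self.LXf if Lx is None else Lx
        Ly = self.LYf if Ly is None else Ly
        nf = len(self.free)
        q = np.zeros(nf) if q0 is None else np.asarray(q0, dtype=float).copy()
        v = np.zeros(nf) if v0 is None else np.asarray(v0, dtype=float).copy()

        Cff = (c_total / self.mass) * self.Mff
        A = (self.Mff + dt * Cff + dt * dt * self.Kff).tocsc()
        lu = splu(A)

        rho_h = self.density * self.thickness
        times = t0 + dt * np.arange(n_steps + 1)
        strain = np.empty((self.n_nodes, n_steps + 1))
        tip = np.empty(n_steps + 1)
        energy = np.empty(n_steps + 1) if record_energy else None

        S = self._strain_matrix
        tip_col = np.searchsorted(self.free, self._tip_w_dof)

        def _record(i):
            strain[:, i] = S @ q
            tip[i] = q[tip_col] if self.free[tip_col] == self._tip_w_dof else 0.0
            if record_energy:
                energy[i] = 0.5 * (v @ (self.Mff @ v) + q @ (self.Kff @ q))

        _record(0)
        for i in range(1, n_steps + 1):
            t = t0 + i * dt
            F = -rho_h * (g_x(t) * Lx + g_y(t) * Ly)
            rhs = self.Mff @ v + dt * (F - self.Kff @ q)
            v = lu.solve(rhs)
            q = q + dt * v
            if not np.all(np.isfinite(v)):
                raise SimulationDivergedError(
                    f"integration diverged at step {i} (t = {t:.6g} s)"
                )
            _record(i)

        return StepRecord(times=times, strain=strain, tip_deflection=tip,
                          q=q, v=v, energy=energy)
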