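"""Tikhonov-regularized Newton inversion of boundary data.

The iterative baseline: starting from a homogeneous estimate, repeatedly
linearize the forward model (adjoint-assembled Jacobian of log-amplitude and
phase with respect to nodal mu_a and mu_s'), solve the damped normal system

    min_dx ||J dx - r||^2 + lambda^2 ||L dx||^2

via a stacked least-squares solve, and backtrack on the data misfit.  The
nodal result is barycentrically interpolated onto the 64x64 raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .forward import (
    AcquisitionConfig,
    BoundaryData,
    ForwardSystem,
    assemble_from_nodal,
    detector_nodes,
    source_nodes,
    _element_geometry,
)
from .mesh import Mesh
from .optics import OpticalProperties
from .phantoms import GRID, PropertyImage

# exact integrals of phi_a phi_b phi_c over an element, per unit area:
# 1/10 (all equal), 1/30 (two equal), 1/60 (all distinct)
_C3 = np.empty((3, 3, 3))
for _n in range(3):
    for _i in range(3):
        for _j in range(3):
            _eq = (_n == _i) + (_i == _j) + (_n == _j)
            _C3[_n, _i, _j] = 1 / 10 if _eq == 3 else (1 / 30 if _eq == 1 else 1 / 60)


def _measurement_vector(amp: np.ndarray, pha: np.ndarray) -> np.ndarray:
    """Stack log-amplitude then phase into one real vector."""
    return np.concatenate([np.log(amp).ravel(), pha.ravel()])


def measurements_from_data(data: BoundaryData) -> np.ndarray:
    if data.normalized:
        raise ValueError("inversion needs un-normalized (physical) boundary data")
    return _measurement_vector(data.amplitude, data.phase)


@dataclass
class InverseState:
    """One linearization point of the Newton iteration."""

    mu_a: np.ndarray  # nodal, mm^-1
    mu_s_prime: np.ndarray  # nodal, mm^-1
    fields: np.ndarray | None = None  # (m, N) source fields
    adjoints: np.ndarray | None = None  # (m, N) detector fields
    modeled: np.ndarray | None = None  # (2 m n,) log-amp / phase


def _solve_state(
    mesh: Mesh,
    acq: AcquisitionConfig,
    mu_a: np.ndarray,
    mu_s: np.ndarray,
    omega_over_c: float,
    background_mu_s: float,
) -> InverseState:
    """Forward + adjoint fields and modeled measurements at (mu_a, mu_s)."""
    K = assemble_from_nodal(mesh, mu_a, mu_s, omega_over_c, acq.boundary_coefficient)
    system = ForwardSystem(K, mesh, mu_a, mu_s, omega_over_c, background_mu_s)
    m = acq.n_sources
    srcs = source_nodes(mesh, m, background_mu_s)
    dets = detector_nodes(mesh, m)
    rhs = np.zeros((mesh.n_nodes, 2 * m), dtype=complex)
    rhs[srcs, np.arange(m)] = 1.0
    rhs[dets, m + np.arange(m)] = 1.0
    sol = system.lu().solve(rhs)
    fields, adjoints = sol[:, :m].T.copy(), sol[:, m:].T.copy()
    amp = np.empty((m, m - 1))
    pha = np.empty((m, m - 1))
    for i in range(m):
        order = [(i + k) % m for k in range(1, m)]
        vals = fields[i, dets[order]]
        amp[i] = np.abs(vals)
        pha[i] = np.angle(vals)
    return InverseState(mu_a, mu_s, fields, adjoints, _measurement_vector(amp, pha))


def compute_jacobian(
    state: InverseState, mesh: Mesh, acq: AcquisitionConfig
) -> np.ndarray:
    """Adjoint assembly of d(log-amp, phase)/d(nodal mu_a, mu_s').

    Rows: m*(m-1) log-amplitude rows then m*(m-1) phase rows, in the same
    (source, detector-offset) order as ``sample_boundary``.  Columns:
    n_nodes mu_a entries then n_nodes mu_s' entries.  Uses reciprocity: the
    detector adjoint field is the forward solution of a unit load at the
    detector node, so  dPhi_sd/dp_n = -Phi_s^T (dK/dp_n) Phi_d.
    """
    if state.fields is None or state.adjoints is None:
        raise ValueError("state lacks forward/adjoint fields; solve first")
    m = acq.n_sources
    n = m - 1
    N = mesh.n_nodes
    area, grads = _element_geometry(mesh)
    elements = mesh.elements
    dets = detector_nodes(mesh, m)

    d_nodal = 1.0 / (3.0 * (state.mu_a + state.mu_s_prime))
    dD = -3.0 * d_nodal**2  # dD/dmu_a = dD/dmu_s'

    src_of = np.array([i for i in range(m) for _ in range(1, m)])
    det_of = np.array([(i + k) % m for i in range(m) for k in range(1, m)])
    u = state.fields[src_of][:, elements]  # (P, E, 3)
    v = state.adjoints[det_of][:, elements]

    # mass-sensitivity: sum_ij u_i v_j int(phi_n phi_i phi_j)
    t_mass = np.einsum("nij,pei,pej->pen", _C3, u, v) * area[None, :, None]
    # stiffness-sensitivity: (A/3) grad(u).grad(v), equal share per vertex
    gu = np.einsum("eci,pei->pec", grads, u)
    gv = np.einsum("eci,pei->pec", grads, v)
    t_stiff = (np.einsum("pec,pec->pe", gu, gv) * (area / 3.0))[:, :, None]
    t_stiff = np.broadcast_to(t_stiff, t_mass.shape)

    P = src_of.shape[0]
    flat = np.tile(elements.ravel(), 1)
    sens_mass = np.zeros((P, N), dtype=complex)
    sens_stiff = np.zeros((P, N), dtype=complex)
    for p in range(P):
        np.add.at(sens_mass[p], flat, t_mass[p].ravel())
        np.add.at(sens_stiff[p], flat, t_stiff[p].ravel())

    phi_det = state.fields[src_of, dets[det_of]]
    # complex derivative of log(Phi_sd)
    g_mu_a = -(sens_mass + dD[None, :] * sens_stiff) / phi_det[:, None]
    g_mu_s = -(dD[None, :] * sens_stiff) / phi_det[:, None]

    J = np.empty((2 * m * n, 2 * N))
    J[: m * n, :N] = g_mu_a.real
    J[: m * n, N:] = g_mu_s.real
    J[m * n :, :N] = g_mu_a.imag
    J[m * n :, N:] = g_mu_s.imag
    return J


def tr_update(
    J: np.ndarray,
    residual: np.ndarray,
    lam: float,
    L: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the Tikhonov-regularized linear step via a stacked lstsq.

    Equivalent to  (J^T J + lam^2 L^T L)^{-1} J^T r  but numerically stable.
    """
    if not np.all(np.isfinite(residual)):
        raise FloatingPointError("non-finite residual")
    n_cols = J.shape[1]
    Lm = np.eye(n_cols) if L is None else L
    A = np.vstack([J, lam * Lm])
    b = np.concatenate([residual, np.zeros(Lm.shape[0])])
    dx, *_ = np.linalg.lstsq(A, b, rcond=None)
    return dx


def default_lambda(J: np.ndarray) -> float:
    """lambda = 0.1 * sqrt(max diag(J^T J))."""
    return 0.1 * np.sqrt((J * J).sum(axis=0).max())


class TikhonovNewton:
    """Damped Gauss-Newton reconstruction with Tikhonov regularization.

    Parameters
    ----------
    lam : float, optional
        Regularization weight; default ``0.1*sqrt(max diag(J^T J))`` from
        the first-iteration Jacobian.
    max_iter : int
        Newton iteration budget (default 10).
    tol : float
        Stop when the relative objective drop falls below this (1e-4).

    Attributes set by :meth:`reconstruct`
    -------------------------------------
    mu_a_, mu_s_prime_ : nodal estimates
    objective_history_ : data-misfit value per accepted iterate
    status_ : ``"converged" | "max_iter" | "stalled"``
    """

    def __init__(self, lam: float | None = None, max_iter: int = 10, tol: float = 1e-4):
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"lam": self.lam, "max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "TikhonovNewton":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def reconstruct(
        self,
        data: BoundaryData,
        mesh: Mesh,
        acq: AcquisitionConfig,
        background: OpticalProperties,
        frequency_mhz: float,
    ) -> PropertyImage:
        """Invert one phantom's boundary data starting from its background."""
        y_meas = measurements_from_data(data)
        omega_over_c = 2.0 * np.pi * frequency_mhz * 1e-3 / acq.light_speed
        N = mesh.n_nodes
        mu_a = np.full(N, background.mu_a)
        mu_s = np.full(N, background.mu_s_prime)

        state = _solve_state(mesh, acq, mu_a, mu_s, omega_over_c, background.mu_s_prime)
        residual = y_meas - state.modeled
        obj = float(residual @ residual)
        history = [obj]
        status = "max_iter"
        lam = self.lam

        for _ in range(self.max_iter):
            J = compute_jacobian(state, mesh, acq)
            if lam is None:
                lam = default_lambda(J)
            dx = tr_update(J, residual, lam)
            step = 1.0
            accepted = False
            obj_try = obj
            for _halve in range(11):
                mu_a_try = np.clip(mu_a + step * dx[:N], 1e-4, None)
                mu_s_try = np.clip(mu_s + step * dx[N:], 1e-3, None)
                trial = _solve_state(
                    mesh, acq, mu_a_try, mu_s_try, omega_over_c, background.mu_s_prime
                )
                r_try = y_meas - trial.modeled
                obj_try = float(r_try @ r_try)
                if obj_try < obj:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                status = "stalled"
                break
            rel_drop = (obj - obj_try) / obj if obj > 0 else 0.0
            mu_a, mu_s, state, residual, obj = mu_a_try, mu_s_try, trial, r_try, obj_try
            history.append(obj)
            if rel_drop < self.tol:
                status = "converged"
                break

        self.mu_a_ = mu_a
        self.mu_s_prime_ = mu_s
        self.objective_history_ = history
        self.status_ = status
        self.lam_ = lam
        return nodal_to_image(mesh, mu_a, mu_s)


def nodal_to_image(
    mesh: Mesh, mu_a: np.ndarray, mu_s: np.ndarray, grid: int = GRID
) -> PropertyImage:
    """Barycentric interpolation of nodal values onto the 64x64 raster."""
    R = mesh.radius
    px = 2.0 * R / grid
    coords = -R + (np.arange(grid) + 0.5) * px
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    mask = X**2 + Y**2 <= R**2
    pts = np.column_stack([X.ravel(), Y.ravel()])
    out = []
    for vals in (mu_a, mu_s):
        interp = LinearNDInterpolator(mesh.nodes, vals, fill_value=np.nan)
        img = interp(pts).reshape(grid, grid)
        # disk pixels just outside the boundary polygon: pull radially inward
        hole = mask & ~np.isfinite(img)
        if hole.any():
            r = np.hypot(X[hole], Y[hole])
            shrink = (R * (1.0 - 1e-9)) / np.maximum(r, 1e-12)
            img[hole] = interp(np.column_stack([X[hole] * shrink, Y[hole] * shrink]))
        img = np.where(mask, img, 0.0)
        out.append(np.nan_to_num(img, nan=float(np.nanmean(vals))))
    return PropertyImage(out[0], out[1], px, mask)
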