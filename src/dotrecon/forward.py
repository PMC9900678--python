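"""Frequency-domain diffusion forward model on P1 triangle meshes.

Solves ``-div(D grad Phi) + (mu_a - i w/c) Phi = S0`` with the Robin
condition ``Phi + 2 A D dPhi/dn = 0`` on the phantom rim, where
``D = 1/(3(mu_a + mu_s'))``.  Sources are isotropic point loads placed one
transport length (``1/mu_s'`` of the background) inside the rim; detectors
read the nodal fluence at the other rim positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import Mesh, GeometryError
from .optics import OpticalProperties
from .phantoms import PhantomSpec

C_VACUUM_MM_PER_NS = 299.792458


class DegenerateChannelError(ValueError):
    """A boundary-data channel is constant and cannot be min-max normalized."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Source-detector layout and physical constants of the acquisition.

    ``n_sources`` positions are equally spaced on the rim; each source is
    read at the remaining ``n_sources - 1`` positions, so one acquisition
    yields ``m*(m-1)`` amplitude and as many phase observations.
    """

    n_sources: int = 16
    refractive_index: float = 1.4
    boundary_coefficient: float = 1.0  # A in  Phi + 2 A D dPhi/dn = 0
    noise_level: float = 0.15
    frequency_mhz: float | None = None  # None: use the phantom's own frequency

    def __post_init__(self) -> None:
        if self.n_sources < 4:
            raise ValueError("need at least 4 source positions")
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")

    @property
    def n_detectors(self) -> int:
        """Detectors per source, always ``n_sources - 1``."""
        return self.n_sources - 1

    @property
    def light_speed(self) -> float:
        """Speed of light in tissue, mm/ns."""
        return C_VACUUM_MM_PER_NS / self.refractive_index


@dataclass
class BoundaryData:
    """Amplitude and phase readings, shape (m, m-1).

    Row ``i`` holds the detectors of source ``i`` ordered by increasing
    counter-clockwise angular offset from the source position.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    noisy: bool = False
    normalized: bool = False
    norm_stats: dict | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    def stack(self) -> np.ndarray:
        """(2, m, n) array: channel 0 amplitude, channel 1 phase."""
        return np.stack([self.amplitude, self.phase])


# ---------------------------------------------------------------------------
# assembly


def nodal_properties(
    mesh: Mesh, props_per_region: Mapping[int, OpticalProperties]
) -> tuple[np.ndarray, np.ndarray]:
    """Spread region properties to nodes (inclusion labels win on shared nodes)."""
    regions = set(np.unique(mesh.regions).tolist())
    missing = regions - set(props_per_region)
    if missing:
        raise KeyError(f"no optical properties assigned to region(s) {sorted(missing)}")
    node_region = np.zeros(mesh.n_nodes, dtype=np.int64)
    for k in sorted(regions):
        if k == 0:
            continue
        nodes_k = np.unique(mesh.elements[mesh.regions == k])
        node_region[nodes_k] = k
    mu_a = np.empty(mesh.n_nodes)
    mu_s = np.empty(mesh.n_nodes)
    for k in regions:
        sel = node_region == k
        mu_a[sel] = props_per_region[k].mu_a
        mu_s[sel] = props_per_region[k].mu_s_prime
    return mu_a, mu_s


def _element_geometry(mesh: Mesh):
    """Per-element areas and P1 shape-function gradients, shape (E, 2, 3)."""
    p = mesh.nodes[mesh.elements]  # (E, 3, 2)
    x, y = p[..., 0], p[..., 1]
    area = mesh.element_areas()
    # grad phi_i = (b_i, c_i) / (2A)
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    grads = np.stack([b, c], axis=1) / (2.0 * area[:, None, None])
    return area, grads


def _linear_coeff_mass(area: np.ndarray, q: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """3x3 element mass blocks for a P1-interpolated coefficient q (may be complex).

    Exact integrals of q(x) phi_i phi_j with q linear on the element:
    off-diagonal A*((q_i+q_j)/30 + q_k/60), diagonal A*(q_i/10 + (q_j+q_k)/30).
    """
    qe = q[elements]  # (E, 3)
    E = area.shape[0]
    M = np.empty((E, 3, 3), dtype=qe.dtype)
    for i in range(3):
        for j in range(3):
            if i == j:
                others = [k for k in range(3) if k != i]
                M[:, i, i] = qe[:, i] / 10.0 + qe[:, others].sum(axis=1) / 30.0
            else:
                k = 3 - i - j
                M[:, i, j] = (qe[:, i] + qe[:, j]) / 30.0 + qe[:, k] / 60.0
    return M * area[:, None, None]


def _stiffness_blocks(area: np.ndarray, grads: np.ndarray, d: np.ndarray, elements) -> np.ndarray:
    """Element stiffness with linearly interpolated diffusion coefficient."""
    d_mean = d[elements].mean(axis=1)
    gg = np.einsum("eci,ecj->eij", grads, grads)  # (E, 3, 3)
    return gg * (d_mean * area)[:, None, None]


def _scatter(blocks: np.ndarray, elements: np.ndarray, n_nodes: int) -> sp.csr_matrix:
    rows = np.repeat(elements, 3, axis=1).ravel()
    cols = np.tile(elements, (1, 3)).ravel()
    K = sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=(n_nodes, n_nodes))
    return K.tocsr()


def boundary_edge_matrix(mesh: Mesh) -> sp.csr_matrix:
    """Rim mass matrix  integral(phi_i phi_j) over the boundary polygon."""
    rim = mesh.boundary_nodes
    nxt = np.roll(rim, -1)
    length = np.hypot(*(mesh.nodes[nxt] - mesh.nodes[rim]).T)
    rows, cols, vals = [], [], []
    for a, b, L in zip(rim, nxt, length):
        rows += [a, b, a, b]
        cols += [a, b, b, a]
        vals += [L / 3.0, L / 3.0, L / 6.0, L / 6.0]
    return sp.coo_matrix((vals, (rows, cols)), shape=(mesh.n_nodes,) * 2).tocsr()


def assemble_from_nodal(
    mesh: Mesh,
    mu_a: np.ndarray,
    mu_s_prime: np.ndarray,
    omega_over_c: float,
    boundary_coefficient: float = 1.0,
) -> sp.csc_matrix:
    """Assemble the complex FEM operator from nodal property vectors."""
    if np.any(mu_a <= 0) or np.any(mu_s_prime <= 0):
        raise ValueError("optical properties must be positive everywhere")
    area, grads = _element_geometry(mesh)
    d = 1.0 / (3.0 * (mu_a + mu_s_prime))
    S = _stiffness_blocks(area, grads, d, mesh.elements)
    q = mu_a.astype(complex) - 1j * omega_over_c
    M = _linear_coeff_mass(area, q, mesh.elements)
    K = _scatter(S.astype(complex) + M, mesh.elements, mesh.n_nodes)
    K = K + boundary_edge_matrix(mesh) / (2.0 * boundary_coefficient)
    return K.tocsc()


@dataclass
class ForwardSystem:
    """Assembled operator plus the geometry needed to place sources/detectors."""

    matrix: sp.csc_matrix
    mesh: Mesh
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    omega_over_c: float
    background_mu_s: float
    _lu: object = field(default=None, repr=False)

    def lu(self):
        if self._lu is None:
            self._lu = splu(self.matrix)
        return self._lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self.lu().solve(rhs.astype(complex))


def assemble_system(
    mesh: Mesh,
    props_per_region: Mapping[int, OpticalProperties],
    acq: AcquisitionConfig,
    frequency_mhz: float = 0.0,
) -> ForwardSystem:
    """Assemble the frequency-domain diffusion operator for one phantom.

    ``frequency_mhz`` may be overridden by ``acq.frequency_mhz`` when set.
    """
    f = acq.frequency_mhz if acq.frequency_mhz is not None else frequency_mhz
    if f < 0:
        raise ValueError("modulation frequency must be >= 0")
    omega = 2.0 * np.pi * f * 1e-3  # rad/ns
    mu_a, mu_s = nodal_properties(mesh, props_per_region)
    K = assemble_from_nodal(mesh, mu_a, mu_s, omega / acq.light_speed, acq.boundary_coefficient)
    return ForwardSystem(
        K, mesh, mu_a, mu_s, omega / acq.light_speed, props_per_region[0].mu_s_prime
    )


# ---------------------------------------------------------------------------
# sources / detectors


def rim_angles(m: int) -> np.ndarray:
    """Equally spaced source/detector position angles, CCW from 0."""
    return 2.0 * np.pi * np.arange(m) / m


def detector_nodes(mesh: Mesh, m: int) -> np.ndarray:
    """Nearest rim node to each of the m position angles.

    Raises :class:`GeometryError` when the closest rim node is further than
    half the angular spacing from the requested angle.
    """
    rim = mesh.boundary_nodes
    ang = np.arctan2(mesh.nodes[rim, 1], mesh.nodes[rim, 0]) % (2.0 * np.pi)
    targets = rim_angles(m)
    diff = np.abs(ang[None, :] - targets[:, None])
    diff = np.minimum(diff, 2.0 * np.pi - diff)
    best = diff.argmin(axis=1)
    if np.any(diff[np.arange(m), best] > np.pi / m):
        raise GeometryError("mesh rim too coarse for the requested detector layout")
    return rim[best]


def source_nodes(mesh: Mesh, m: int, background_mu_s: float) -> np.ndarray:
    """Node nearest to one transport length radially inside each rim position."""
    depth = 1.0 / background_mu_s
    r_src = max(mesh.radius - depth, 0.25 * mesh.radius)
    targets = r_src * np.column_stack([np.cos(rim_angles(m)), np.sin(rim_angles(m))])
    d2 = ((mesh.nodes[None, :, :] - targets[:, None, :]) ** 2).sum(-1)
    return d2.argmin(axis=1)


def solve_forward(system: ForwardSystem, source_index: int, acq: AcquisitionConfig) -> np.ndarray:
    """Complex nodal fluence for a unit point source at one rim position."""
    m = acq.n_sources
    if not (0 <= source_index < m):
        raise IndexError(f"source_index {source_index} outside [0, {m})")
    src = source_nodes(system.mesh, m, system.background_mu_s)[source_index]
    rhs = np.zeros(system.mesh.n_nodes, dtype=complex)
    rhs[src] = 1.0
    phi = system.solve(rhs)
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("forward solve produced non-finite fluence")
    return phi


def solve_all_sources(system: ForwardSystem, acq: AcquisitionConfig) -> np.ndarray:
    """Fields for all m sources, shape (m, n_nodes); one factorization reused."""
    m = acq.n_sources
    srcs = source_nodes(system.mesh, m, system.background_mu_s)
    rhs = np.zeros((system.mesh.n_nodes, m), dtype=complex)
    rhs[srcs, np.arange(m)] = 1.0
    phi = system.lu().solve(rhs)
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("forward solve produced non-finite fluence")
    return phi.T


def sample_boundary(fields: np.ndarray, mesh: Mesh, acq: AcquisitionConfig) -> BoundaryData:
    """Read amplitude/phase at the m-1 rim positions of every source.

    Row ``i`` lists detectors by increasing CCW angular offset from source
    ``i``; the source's own position is excluded.
    """
    m = acq.n_sources
    if fields.shape[0] != m:
        raise ValueError(f"expected {m} fields, got {fields.shape[0]}")
    det = detector_nodes(mesh, m)
    amp = np.empty((m, m - 1))
    pha = np.empty((m, m - 1))
    for i in range(m):
        order = [(i + k) % m for k in range(1, m)]
        vals = fields[i, det[order]]
        amp[i] = np.abs(vals)
        pha[i] = np.angle(vals)
    return BoundaryData(amp, pha)


# ---------------------------------------------------------------------------
# noise and normalization


def add_noise(data: BoundaryData, level: float, seed: int) -> BoundaryData:
    """Measurement noise: multiplicative on amplitude, additive on phase.

    Amplitude entries are scaled by ``1 + eps`` with ``eps ~ N(0, level^2)``;
    phase entries are shifted by ``N(0, (level * std(phase))^2)``.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if data.normalized:
        raise ValueError("noise must be added before normalization")
    if level == 0:
        return replace(data, amplitude=data.amplitude.copy(), phase=data.phase.copy())
    rng = np.random.default_rng(seed)
    amp = data.amplitude * (1.0 + rng.normal(0.0, level, data.amplitude.shape))
    pha = data.phase + rng.normal(0.0, level * data.phase.std(), data.phase.shape)
    return BoundaryData(amp, pha, noisy=True)


def channel_stats(datas: Sequence[BoundaryData]) -> dict:
    """Per-channel min/max over a collection (typically the training split)."""
    amp = np.stack([d.amplitude for d in datas])
    pha = np.stack([d.phase for d in datas])
    stats = {
        "amplitude": (float(amp.min()), float(amp.max())),
        "phase": (float(pha.min()), float(pha.max())),
    }
    for name, (lo, hi) in stats.items():
        if hi == lo:
            raise DegenerateChannelError(f"{name} channel is constant (min == max)")
    return stats


def normalize_minmax(data: BoundaryData, stats: dict | None = None) -> BoundaryData:
    """Min-max map each channel to [0, 1].

    With precomputed ``stats`` (training-split min/max) the same affine map
    is applied and the result clipped to [0, 1]; without, the data's own
    range is used and recorded.
    """
    if data.amplitude.size == 0:
        raise ValueError("empty boundary data")
    if stats is None:
        stats = channel_stats([data])
        clip = False
    else:
        clip = True
    out = {}
    for name, arr in (("amplitude", data.amplitude), ("phase", data.phase)):
        lo, hi = stats[name]
        if hi == lo:
            raise DegenerateChannelError(f"{name} channel stats degenerate (min == max)")
        x = (arr - lo) / (hi - lo)
        out[name] = np.clip(x, 0.0, 1.0) if clip else x
    return BoundaryData(
        out["amplitude"], out["phase"], noisy=data.noisy, normalized=True, norm_stats=stats
    )


# ---------------------------------------------------------------------------
# convenience pipeline


def simulate_boundary_data(
    spec: PhantomSpec,
    acq: AcquisitionConfig,
    target_edge_length: float | None = None,
    noise_seed: int | None = None,
) -> tuple[BoundaryData, Mesh]:
    """Mesh, solve all sources, sample the rim, optionally add noise."""
    from .mesh import build_mesh

    mesh = build_mesh(spec, target_edge_length, layout_m=acq.n_sources)
    props = {0: spec.background}
    props.update({k + 1: inc.props for k, inc in enumerate(spec.inclusions)})
    system = assemble_system(mesh, props, acq, spec.frequency_mhz)
    fields = solve_all_sources(system, acq)
    data = sample_boundary(fields, mesh, acq)
    if noise_seed is not None and acq.noise_level > 0:
        data = add_noise(data, acq.noise_level, noise_seed)
    return data, mesh
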