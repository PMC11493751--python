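"""Miniature finite-strain FE homogenization with embedded fibers.

The extracellular matrix is discretized by a structured grid of 8-node
hexahedra over the periodic cube; fiber axes are discretized into embedded
finite-strain truss elements whose nodes are kinematically tied to the host
displacement field by trilinear interpolation (embedded element technique).
The truss material is the stiffness-redundancy corrected Ogden rod
(mu_f* = mu_f - mu_m) with cross-section area pi d^2/4, so matrix energy
integrated over the whole cube plus corrected fiber energy reproduces the
true two-phase energy.

Periodic boundary conditions are imposed exactly by construction: the total
displacement is split as u = (F_macro - I) x + u*, and the periodic
fluctuation u* is shared between every set of periodically identified nodes
(opposite faces, edges and corners carry one fluctuation unknown).  One
node's fluctuation is pinned to remove the rigid translation that the
difference constraints leave free.

Each load step solves the discrete equilibrium (zero body force,
quasi-static) by Newton iteration; element tangents come from finite
differencing the analytic internal-force vectors, the truss tangent is
analytic.  Macroscopic output follows Hill-Mandel volume averaging: the
homogenized first Piola-Kirchhoff stress is the volume average of the matrix
PK1 plus the corrected-fiber rod contributions, and the homogenized Cauchy
stress is the deformed-volume average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, MeshError, ParameterError
from .materials import (
    ConstituentSet,
    OgdenParams,
    _pk1_batch,
    cauchy_from_pk1,
    corrected_fiber_params,
    DEFAULT_BULK_RATIO,
)
from .rve import RveGeometry

__all__ = [
    "HexMesh",
    "EmbeddedFiberMesh",
    "MacroDeformation",
    "SolverConfig",
    "FieldSolution",
    "HomogenizedResponse",
    "build_host_mesh",
    "embed_fibers",
    "assemble_pbc",
    "solve_quasistatic",
    "homogenize_stress",
    "localized_metrics",
    "hill_mandel_gap",
    "face_traction_asymmetry",
]

_GP = 1.0 / math.sqrt(3.0)
# local node coordinates, VTK hexahedron ordering
_XI_NODES = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)


def _shape_fn(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions at reference point(s) xi (..., 3) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    return np.prod(1.0 + xi[..., None, :] * _XI_NODES, axis=-1) / 8.0


def _shape_grad(xi: np.ndarray) -> np.ndarray:
    """d N_a / d xi at one reference point -> (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        na = _XI_NODES[a]
        for j in range(3):
            term = na[j] / 8.0
            for k in range(3):
                if k != j:
                    term *= 1.0 + xi[k] * na[k]
            g[a, j] = term
    return g


@dataclass
class HexMesh:
    """Structured periodic hexahedral grid over the cube [0, edge]^3."""

    edge: float
    n: int
    nodes: np.ndarray  # (Nn, 3)
    elems: np.ndarray  # (Ne, 8)
    node_class: np.ndarray  # (Nn,) periodic-fluctuation class per node

    @property
    def h(self) -> float:
        return self.edge / self.n

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_classes(self) -> int:
        return self.n**3

    def boundary_pairs(self, direction: int) -> list[tuple[int, int]]:
        """(max-face node, min-face node) pairs for one periodic direction."""
        n = self.n
        pairs = []
        for idx in range(self.n_nodes):
            ijk = self._ijk(idx)
            if ijk[direction] == n:
                partner = list(ijk)
                partner[direction] = 0
                pairs.append((idx, self._nid(*partner)))
        return pairs

    def _nid(self, i: int, j: int, k: int) -> int:
        m = self.n + 1
        return (i * m + j) * m + k

    def _ijk(self, nid: int) -> tuple[int, int, int]:
        m = self.n + 1
        return nid // (m * m), (nid // m) % m, nid % m

    def element_volumes(self) -> np.ndarray:
        return np.full(len(self.elems), self.h**3)


def build_host_mesh(edge: float, n_per_side: int) -> HexMesh:
    """Structured n^3 hex grid with periodic node classes precomputed."""
    if n_per_side < 1:
        raise ParameterError("n_per_side must be >= 1")
    n = int(n_per_side)
    m = n + 1
    axis = np.linspace(0.0, edge, m)
    I, J, K = np.meshgrid(np.arange(m), np.arange(m), np.arange(m), indexing="ij")
    nodes = np.stack([axis[I], axis[J], axis[K]], axis=-1).reshape(-1, 3)
    node_class = (
        ((I % n) * n + (J % n)) * n + (K % n)
    ).reshape(-1)

    elems = np.empty((n**3, 8), dtype=int)
    e = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                nid = lambda a, b, c: (a * m + b) * m + c
                elems[e] = [
                    nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ]
                e += 1
    return HexMesh(edge=float(edge), n=n, nodes=nodes, elems=elems, node_class=node_class)


# ---------------------------------------------------------------------------
# embedded fibers


@dataclass
class EmbeddedFiberMesh:
    """Fiber axes discretized into tied nodes and finite-strain truss elements."""

    positions: np.ndarray  # (Nf, 3) fiber node positions (wrapped into cube)
    host_nodes: np.ndarray  # (Nf, 8) host node ids per fiber node
    weights: np.ndarray  # (Nf, 8) trilinear interpolation weights
    conn: np.ndarray  # (Nt, 2) truss connectivity into fiber nodes
    ref_vec: np.ndarray  # (Nt, 3) unwrapped reference axis vector
    length0: np.ndarray  # (Nt,)
    area: np.ndarray  # (Nt,) cross-section area pi d^2/4
    fiber_id: np.ndarray  # (Nt,)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_trusses(self) -> int:
        return len(self.conn)


def _locate(mesh: HexMesh, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Host element node ids and trilinear weights for points in the cube."""
    h, n = mesh.h, mesh.n
    tol = 1e-9 * mesh.edge
    if np.any(pos < -tol) or np.any(pos > mesh.edge + tol):
        raise MeshError("fiber node lies outside the host cube")
    cell = np.clip(np.floor(pos / h).astype(int), 0, n - 1)
    xi = 2.0 * (pos / h - cell) - 1.0  # inverse trilinear map (regular grid)
    m = n + 1
    i, j, k = cell[:, 0], cell[:, 1], cell[:, 2]
    corner = (i * m + j) * m + k
    offs = np.array([
        0, m * m, m * m + m, m,
        1, m * m + 1, m * m + m + 1, m + 1,
    ])
    nodes = corner[:, None] + offs[None, :]
    w = _shape_fn(xi)
    return nodes, w


def embed_fibers(
    mesh: HexMesh, geometry: RveGeometry, resolution: float = 2.0
) -> EmbeddedFiberMesh:
    """Discretize each fiber axis into truss elements tied to the host mesh.

    ``resolution`` sets the target number of truss subdivisions per host
    element size h (node spacing ~ h / resolution).
    """
    spacing = mesh.h / float(resolution)
    positions, host_nodes, weights = [], [], []
    conn, ref_vec, length0, area, fiber_id = [], [], [], [], []
    node_count = 0
    for fi, f in enumerate(geometry.fibers):
        A = math.pi * f.diameter**2 / 4.0
        for a, b in f.segments:
            a = np.asarray(a)
            b = np.asarray(b)
            seg = b - a
            L = float(np.linalg.norm(seg))
            if L < 1e-12:
                continue
            ndiv = max(1, int(math.ceil(L / spacing)))
            t = np.linspace(0.0, 1.0, ndiv + 1)
            pts = a[None, :] + t[:, None] * seg[None, :]
            base = node_count
            positions.append(pts)
            node_count += len(pts)
            for d in range(ndiv):
                conn.append((base + d, base + d + 1))
                ref_vec.append(seg / ndiv)
                length0.append(L / ndiv)
                area.append(A)
                fiber_id.append(fi)
    if node_count == 0:
        z3 = np.zeros((0, 3))
        return EmbeddedFiberMesh(
            z3, np.zeros((0, 8), dtype=int), np.zeros((0, 8)),
            np.zeros((0, 2), dtype=int), z3.copy(), np.zeros(0), np.zeros(0),
            np.zeros(0, dtype=int),
        )
    pos = np.vstack(positions)
    pos_wrapped = np.clip(pos, 0.0, mesh.edge)  # segment points are in-cube
    hn, w = _locate(mesh, pos_wrapped)
    return EmbeddedFiberMesh(
        positions=pos,
        host_nodes=hn,
        weights=w,
        conn=np.asarray(conn, dtype=int),
        ref_vec=np.asarray(ref_vec),
        length0=np.asarray(length0),
        area=np.asarray(area),
        fiber_id=np.asarray(fiber_id, dtype=int),
    )


# ---------------------------------------------------------------------------
# periodic constraints (explicit form, for inspection/tests)


@dataclass
class PbcConstraints:
    """Explicit slave-master difference constraints u_s - u_m = (F-I) dx."""

    pairs: list  # (slave_node, master_node, delta_x)
    pinned_node: int

    @property
    def n_constraints(self) -> int:
        return 3 * len(self.pairs)

    def residuals(self, u_full: np.ndarray, F_macro: np.ndarray, nodes: np.ndarray) -> np.ndarray:
        A = np.asarray(F_macro) - np.eye(3)
        out = np.empty((len(self.pairs), 3))
        for r, (s, m, dx) in enumerate(self.pairs):
            out[r] = u_full[s] - u_full[m] - A @ dx
        return out


def assemble_pbc(mesh: HexMesh, macro: "MacroDeformation | None" = None) -> PbcConstraints:
    """One difference constraint per paired boundary DOF.

    Every boundary node whose periodic class representative is a different
    node is a slave; its master is the class representative (the node with
    all grid indices reduced modulo n).  The fluctuation of node 0 (grid
    origin) is pinned to remove rigid translation.
    """
    n, m = mesh.n, mesh.n + 1
    rep_node = {}
    for nid in range(mesh.n_nodes):
        i, j, k = mesh._ijk(nid)
        rep = mesh._nid(i % n, j % n, k % n)
        if rep != nid:
            rep_node[nid] = rep
    pairs = [
        (s, r, mesh.nodes[s] - mesh.nodes[r]) for s, r in sorted(rep_node.items())
    ]
    return PbcConstraints(pairs=pairs, pinned_node=0)


# ---------------------------------------------------------------------------
# macro loading, solver config


@dataclass
class MacroDeformation:
    """Macroscopic loading programme.

    mode 'uniaxial_stress': prescribe the axial stretch lambda and iterate
    the transverse stretch so the homogenized transverse nominal stresses
    vanish (tension-test control).  mode 'prescribed': impose the diagonal
    F = diag(lambda, lambda_t, lambda_t) with lambda_t fixed (defaults to
    the incompressible value lambda^-1/2), or a fully specified F_final.
    """

    stretch: float = 1.2
    n_steps: int = 10
    mode: str = "uniaxial_stress"
    lambda_transverse: float | None = None
    F_final: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("uniaxial_stress", "prescribed"):
            raise ParameterError(f"unknown loading mode {self.mode!r}")
        if self.stretch <= 0.0:
            raise ParameterError("macroscopic stretch must be positive")

    def stretch_schedule(self) -> np.ndarray:
        return np.linspace(1.0, self.stretch, self.n_steps + 1)[1:]

    def F_at(self, lam: float, lam_t: float | None = None) -> np.ndarray:
        if self.F_final is not None:
            # interpolate linearly between I and F_final by load fraction
            frac = (lam - 1.0) / (self.stretch - 1.0) if self.stretch != 1.0 else 1.0
            return np.eye(3) + frac * (np.asarray(self.F_final) - np.eye(3))
        if lam_t is None:
            lam_t = self.lambda_transverse if self.lambda_transverse is not None else lam**-0.5
        return np.diag([lam, lam_t, lam_t])


@dataclass
class SolverConfig:
    newton_tol: float = 1e-8  # relative residual
    newton_abs_tol: float = 1e-12
    max_newton: int = 30
    min_step_fraction: float = 1.0 / 64.0
    bulk_ratio: float = DEFAULT_BULK_RATIO
    transverse_tol: float = 1e-4  # |P22+P33| relative to max(|P11|, mu)
    max_transverse_iter: int = 40
    fd_step: float = 1e-7


@dataclass
class StepResult:
    stretch: float
    lambda_t: float
    F_macro: np.ndarray
    fluct: np.ndarray  # (Nc, 3)
    P_bar: np.ndarray
    sigma_bar: np.ndarray
    newton_iters: int
    residual_norm: float
    converged: bool


@dataclass
class FieldSolution:
    mesh: HexMesh
    fibers: EmbeddedFiberMesh | None
    constituents: ConstituentSet
    matrix_params: OgdenParams  # penalized ECM used by the solver
    fiber_params: OgdenParams  # corrected rod
    macro: MacroDeformation
    config: SolverConfig
    steps: list[StepResult] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.steps)

    @property
    def final(self) -> StepResult:
        return self.steps[-1]

    def full_displacement(self, step: StepResult | None = None) -> np.ndarray:
        step = step or self.final
        A = step.F_macro - np.eye(3)
        return self.mesh.nodes @ A.T + step.fluct[self.mesh.node_class]

    def response(self) -> "HomogenizedResponse":
        return homogenize_stress(self)


@dataclass
class HomogenizedResponse:
    """Macroscopic stretch vs nominal stress curve plus localized metrics."""

    stretch: np.ndarray
    nominal_stress: np.ndarray  # P11, Pa
    cauchy_stress: np.ndarray  # sigma11, Pa
    sigma_max_over_avg: float | None = None
    hill_mandel_gap: float | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"stretch": self.stretch, "nominal_stress_Pa": self.nominal_stress}
        )


# ---------------------------------------------------------------------------
# assembly kernels


class _System:
    """Precomputed arrays for one (mesh, fibers, materials) combination."""

    def __init__(self, mesh, fibers, matrix_params, fiber_params, fd_step):
        self.mesh = mesh
        self.fibers = fibers if (fibers is not None and fibers.n_trusses) else None
        self.mp = matrix_params
        self.fp = fiber_params
        self.fd_step = fd_step

        h = mesh.h
        gp = np.array(
            [[sx * _GP, sy * _GP, sz * _GP] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        self.G = np.stack([_shape_grad(x) for x in gp]) * (2.0 / h)  # (8q, 8a, 3)
        self.wq = (h / 2.0) ** 3  # unit gauss weights
        self.Xe = mesh.nodes[mesh.elems]  # (Ne, 8, 3)

        nc = mesh.n_classes
        self.nc = nc
        # map classes -> equation ids, pinned class removed
        self.pinned_class = int(mesh.node_class[0])
        eq = np.full(nc, -1, dtype=int)
        free = [c for c in range(nc) if c != self.pinned_class]
        eq[free] = np.arange(len(free))
        self.class_eq = eq
        self.n_eq = 3 * len(free)

        ec = mesh.node_class[mesh.elems]  # (Ne, 8)
        self.elem_class = ec
        # 24 dof ids per element (class*3 + comp), -1 where pinned
        dof = np.where(
            eq[ec][..., None] >= 0, eq[ec][..., None] * 3 + np.arange(3), -1
        )
        self.elem_dof = dof.reshape(len(mesh.elems), 24)
        rows = np.repeat(self.elem_dof[:, :, None], 24, axis=2)
        cols = np.repeat(self.elem_dof[:, None, :], 24, axis=1)
        keep = (rows >= 0) & (cols >= 0)
        self._krows = rows[keep]
        self._kcols = cols[keep]
        self._kkeep = keep

        if self.fibers is not None:
            fb = self.fibers
            # signed interpolation weights of each truss onto 16 host nodes
            n1 = fb.conn[:, 0]
            n2 = fb.conn[:, 1]
            self.t_hosts = np.concatenate(
                [fb.host_nodes[n2], fb.host_nodes[n1]], axis=1
            )  # (Nt, 16)
            self.t_sw = np.concatenate([fb.weights[n2], -fb.weights[n1]], axis=1)
            tc = mesh.node_class[self.t_hosts]
            self.t_class = tc
            tdof = np.where(eq[tc][..., None] >= 0, eq[tc][..., None] * 3 + np.arange(3), -1)
            self.t_dof = tdof  # (Nt, 16, 3)

    # -- matrix (hex) kernels ---------------------------------------------

    def _elem_forces(self, ue: np.ndarray) -> np.ndarray:
        """Internal force (Ne, 8, 3) from element displacements (Ne, 8, 3)."""
        F = np.eye(3) + np.einsum("eai,qaj->eqij", ue, self.G)
        P = _pk1_batch(self.mp, F.reshape(-1, 3, 3)).reshape(F.shape)
        return np.einsum("eqij,qaj->eai", P, self.G) * self.wq

    def _elem_F(self, ue: np.ndarray) -> np.ndarray:
        return np.eye(3) + np.einsum("eai,qaj->eqij", ue, self.G)

    def gather_u(self, Fbar: np.ndarray, s: np.ndarray) -> np.ndarray:
        A = Fbar - np.eye(3)
        return self.mesh.nodes @ A.T + s[self.mesh.node_class]

    def residual(self, Fbar: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Reduced residual (gradient of total energy wrt free fluctuations)."""
        u = self.gather_u(Fbar, s)
        fe = self._elem_forces(u[self.mesh.elems])
        R = np.zeros(self.n_eq + 1)  # last slot swallows pinned dofs
        dof = np.where(self.elem_dof >= 0, self.elem_dof, self.n_eq)
        np.add.at(R, dof.ravel(), fe.reshape(len(fe), 24).ravel())
        if self.fibers is not None:
            fv = self._truss_forces(Fbar, s)[0]  # (Nt, 3)
            contrib = np.einsum("tm,ti->tmi", self.t_sw, fv)
            tdof = np.where(self.t_dof >= 0, self.t_dof, self.n_eq)
            np.add.at(R, tdof.ravel(), contrib.ravel())
        return R[: self.n_eq]

    def full_internal_forces(self, Fbar: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Unreduced nodal internal forces (Nn, 3), fiber ties included."""
        u = self.gather_u(Fbar, s)
        fe = self._elem_forces(u[self.mesh.elems])
        R = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(R, self.mesh.elems.ravel(), fe.reshape(-1, 3))
        if self.fibers is not None:
            fv = self._truss_forces(Fbar, s)[0]
            contrib = np.einsum("tm,ti->tmi", self.t_sw, fv)
            np.add.at(R, self.t_hosts.ravel(), contrib.reshape(-1, 3))
        return R

    # -- fibers -------------------------------------------------------------

    def _truss_state(self, Fbar: np.ndarray, s: np.ndarray):
        fb = self.fibers
        dv_fluct = np.einsum("tm,tmi->ti", self.t_sw, s[self.t_class])
        v = fb.ref_vec @ Fbar.T + dv_fluct  # current axis vectors
        ell = np.linalg.norm(v, axis=1)
        lam = ell / fb.length0
        vhat = v / ell[:, None]
        return v, ell, lam, vhat

    def _rod_stress(self, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, a = self.fp.mu, self.fp.alpha
        P = (2.0 * mu / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
        dP = (2.0 * mu / a) * (
            (a - 1.0) * lam ** (a - 2.0) + (a / 2.0 + 1.0) * lam ** (-a / 2.0 - 2.0)
        )
        return P, dP

    def _truss_forces(self, Fbar: np.ndarray, s: np.ndarray):
        v, ell, lam, vhat = self._truss_state(Fbar, s)
        P, dP = self._rod_stress(lam)
        fv = (self.fibers.area * P)[:, None] * vhat  # (Nt, 3)
        return fv, (v, ell, lam, vhat, P, dP)

    def _truss_tangent_blocks(self, state):
        v, ell, lam, vhat, P, dP = state
        fb = self.fibers
        eye = np.eye(3)
        nn = np.einsum("ti,tj->tij", vhat, vhat)
        k = (
            (fb.area * dP / fb.length0)[:, None, None] * nn
            + (fb.area * P / ell)[:, None, None] * (eye - nn)
        )
        return k  # (Nt, 3, 3) in axis-vector space

    # -- tangent -------------------------------------------------------------

    def tangent(self, Fbar: np.ndarray, s: np.ndarray) -> sp.csr_matrix:
        u = self.gather_u(Fbar, s)
        ue = u[self.mesh.elems]
        f0 = self._elem_forces(ue).reshape(len(ue), 24)
        hstep = self.fd_step * max(self.mesh.h, 1.0)
        Ke = np.empty((len(ue), 24, 24))
        for j in range(24):
            up = ue.copy().reshape(len(ue), 24)
            up[:, j] += hstep
            fj = self._elem_forces(up.reshape(-1, 8, 3)).reshape(len(ue), 24)
            Ke[:, :, j] = (fj - f0) / hstep
        Ke = 0.5 * (Ke + Ke.transpose(0, 2, 1))
        data = Ke[self._kkeep]
        K = sp.coo_matrix(
            (data, (self._krows, self._kcols)), shape=(self.n_eq, self.n_eq)
        ).tocsr()
        if self.fibers is not None:
            _, state = self._truss_forces(Fbar, s)
            kv = self._truss_tangent_blocks(state)
            # expand to signed-weight host dof blocks
            blocks = np.einsum("tm,tn,tij->tminj", self.t_sw, self.t_sw, kv)
            tdof = self.t_dof  # (Nt, 16, 3)
            rows = np.repeat(tdof[:, :, :, None, None], 16, axis=3)
            rows = np.repeat(rows, 3, axis=4)
            cols = np.repeat(tdof[:, None, None, :, :], 16, axis=1)
            cols = np.repeat(cols, 3, axis=2)
            keep = (rows >= 0) & (cols >= 0)
            K = K + sp.coo_matrix(
                (blocks[keep], (rows[keep], cols[keep])), shape=(self.n_eq, self.n_eq)
            ).tocsr()
        return K

    # -- homogenized quantities ----------------------------------------------

    def averages(self, Fbar: np.ndarray, s: np.ndarray):
        """(P_bar, sigma_bar, von-Mises values + weights) at one state."""
        V0 = self.mesh.edge**3
        u = self.gather_u(Fbar, s)
        F = self._elem_F(u[self.mesh.elems])
        Fq = F.reshape(-1, 3, 3)
        Pq = _pk1_batch(self.mp, Fq)
        Jq = np.linalg.det(Fq)
        sq = cauchy_from_pk1(Pq, Fq)
        P_bar = Pq.sum(axis=0) * self.wq / V0
        sig_sum = (sq * (Jq * self.wq)[:, None, None]).sum(axis=0)
        Vcur = float(np.sum(Jq) * self.wq)

        dev = sq - np.trace(sq, axis1=1, axis2=2)[:, None, None] / 3.0 * np.eye(3)
        vm = np.sqrt(1.5 * np.einsum("qij,qij->q", dev, dev))
        vm_w = np.full(len(vm), self.wq * 1.0)  # reference weights for averaging
        vm_vals = [vm]
        vm_wts = [Jq * self.wq]

        if self.fibers is not None:
            fb = self.fibers
            v, ell, lam, vhat, Pax, _ = self._truss_forces(Fbar, s)[1]
            vol0 = fb.area * fb.length0
            P_bar = P_bar + np.einsum(
                "t,ti,tj->ij", Pax * vol0, vhat, fb.ref_vec / fb.length0[:, None]
            ) / V0
            sig_ax = Pax * lam  # incompressible rod true stress
            sig_sum = sig_sum + np.einsum("t,ti,tj->ij", sig_ax * vol0, vhat, vhat)
            vm_vals.append(np.abs(sig_ax))
            vm_wts.append(vol0)
        sigma_bar = sig_sum / Vcur
        return P_bar, sigma_bar, np.concatenate(vm_vals), np.concatenate(vm_wts)


def _penalized(params: OgdenParams, bulk_ratio: float) -> OgdenParams:
    return params.with_bulk_ratio(bulk_ratio) if params.d_penalty == 0.0 else params


def _newton(system: _System, Fbar, s0, cfg: SolverConfig):
    s = s0.copy()
    scale = abs(system.mp.mu) * system.mesh.edge**2
    hist = []
    for it in range(cfg.max_newton):
        R = system.residual(Fbar, s)
        rn = float(np.linalg.norm(R))
        hist.append(rn)
        if rn <= cfg.newton_tol * scale or rn <= cfg.newton_abs_tol:
            return s, True, it, rn
        K = system.tangent(Fbar, s)
        try:
            ds = spla.spsolve(K.tocsc(), -R)
        except Exception:
            return s, False, it, rn
        if not np.all(np.isfinite(ds)):
            return s, False, it, rn
        upd = np.zeros_like(s)
        free = system.class_eq >= 0
        upd[free] = ds.reshape(-1, 3)
        s = s + upd
    R = system.residual(Fbar, s)
    rn = float(np.linalg.norm(R))
    return s, rn <= cfg.newton_tol * scale, cfg.max_newton, rn


def solve_quasistatic(
    mesh: HexMesh,
    fibers: EmbeddedFiberMesh | None,
    constituents: ConstituentSet,
    macro: MacroDeformation,
    config: SolverConfig | None = None,
) -> FieldSolution:
    """Incremental quasi-static solve under periodic boundary conditions.

    Newton divergence triggers load-step halving; ConvergenceError is raised
    below the minimum step fraction.
    """
    cfg = config or SolverConfig()
    mp = _penalized(constituents.ecm, cfg.bulk_ratio)
    fp = corrected_fiber_params(constituents.axon, constituents.ecm)
    system = _System(mesh, fibers, mp, fp, cfg.fd_step)
    sol = FieldSolution(
        mesh=mesh, fibers=fibers, constituents=constituents,
        matrix_params=mp, fiber_params=fp, macro=macro, config=cfg,
    )

    s = np.zeros((mesh.n_classes, 3))
    lam_prev, lam_t_prev = 1.0, 1.0
    targets = list(macro.stretch_schedule())
    i = 0
    while i < len(targets):
        lam = targets[i]
        frac = 1.0
        lam_lo = lam_prev
        while True:
            lam_try = lam_lo + frac * (lam - lam_lo)
            ok, s_new, lam_t, res = _solve_one_stretch(
                system, macro, lam_try, s, lam_prev, lam_t_prev, cfg
            )
            if ok:
                break
            frac *= 0.5
            if frac < cfg.min_step_fraction:
                raise ConvergenceError(
                    f"no convergence at stretch {lam_try:.5f}",
                    diagnostics={"stretch": lam_try, "residual": res},
                )
        s = s_new
        lam_prev, lam_t_prev = lam_try, lam_t
        Fbar = macro.F_at(lam_try, lam_t if macro.mode == "uniaxial_stress" else None)
        P_bar, sigma_bar, _, _ = system.averages(Fbar, s)
        sol.steps.append(
            StepResult(
                stretch=lam_try, lambda_t=lam_t, F_macro=Fbar, fluct=s.copy(),
                P_bar=P_bar, sigma_bar=sigma_bar, newton_iters=res[0],
                residual_norm=res[1], converged=True,
            )
        )
        if abs(lam_try - lam) < 1e-12:
            i += 1
    sol._system = system
    return sol


def _solve_one_stretch(system, macro, lam, s0, lam_prev, lam_t_prev, cfg):
    """Solve one load level; in uniaxial-stress mode iterate lambda_t."""
    if macro.mode == "prescribed":
        Fbar = macro.F_at(lam)
        s, conv, iters, rn = _newton(system, Fbar, s0, cfg)
        return conv, s, float(Fbar[1, 1]), (iters, rn)

    # uniaxial stress: secant on the transverse stretch
    mu_scale = abs(system.mp.mu)

    def g(lam_t, s_start):
        Fbar = macro.F_at(lam, lam_t)
        s, conv, iters, rn = _newton(system, Fbar, s_start, cfg)
        if not conv:
            return None, s, (iters, rn)
        P_bar, _, _, _ = system.averages(Fbar, s)
        return float(P_bar[1, 1] + P_bar[2, 2]), s, (iters, rn)

    # initial guesses: continue the previous transverse ratio
    ratio = lam_t_prev / lam_prev**-0.5 if lam_prev > 0 else 1.0
    x0 = ratio * lam**-0.5
    g0, s, info = g(x0, s0)
    if g0 is None:
        return False, s, x0, info
    tol = cfg.transverse_tol * max(abs(g0), mu_scale * 1e-3)

    def done(val, P11_scale):
        return abs(val) <= cfg.transverse_tol * max(abs(P11_scale), mu_scale * 1e-6)

    Fbar = macro.F_at(lam, x0)
    P_bar, _, _, _ = system.averages(Fbar, s)
    if done(g0, P_bar[0, 0]):
        return True, s, x0, info
    x1 = x0 * (1.0 - 1e-3 * np.sign(g0))
    g1, s, info = g(x1, s)
    if g1 is None:
        return False, s, x1, info
    for _ in range(cfg.max_transverse_iter):
        if done(g1, P_bar[0, 0]):
            return True, s, x1, info
        if g1 == g0:
            break
        x2 = x1 - g1 * (x1 - x0) / (g1 - g0)
        x2 = float(np.clip(x2, 0.3, 3.0))
        g2, s, info = g(x2, s)
        if g2 is None:
            return False, s, x2, info
        x0, g0, x1, g1 = x1, g1, x2, g2
        Fbar = macro.F_at(lam, x1)
        P_bar, _, _, _ = system.averages(Fbar, s)
    return done(g1, P_bar[0, 0]), s, x1, info


# ---------------------------------------------------------------------------
# post-processing


def homogenize_stress(solution: FieldSolution) -> HomogenizedResponse:
    """Hill-Mandel volume averages along the whole load path."""
    if not solution.converged:
        raise ConvergenceError("refusing to homogenize an unconverged solution")
    system = _get_system(solution)
    stretches = [1.0]
    P11 = [0.0]
    s11 = [0.0]
    for st in solution.steps:
        stretches.append(st.stretch)
        P11.append(float(st.P_bar[0, 0]))
        s11.append(float(st.sigma_bar[0, 0]))
    ratio = localized_metrics(solution)["sigma_max_over_avg"]
    return HomogenizedResponse(
        stretch=np.array(stretches),
        nominal_stress=np.array(P11),
        cauchy_stress=np.array(s11),
        sigma_max_over_avg=ratio,
    )


def localized_metrics(solution: FieldSolution, step: StepResult | None = None) -> dict:
    """Max/mean von-Mises equivalent Cauchy stress over quadrature points
    (matrix) and fiber segments (axial)."""
    system = _get_system(solution)
    st = step or solution.final
    _, _, vm, w = system.averages(st.F_macro, st.fluct)
    avg = float(np.sum(vm * w) / np.sum(w))
    mx = float(vm.max())
    return {
        "sigma_max": mx,
        "sigma_avg": avg,
        "sigma_max_over_avg": mx / avg if avg > 0 else math.inf,
    }


def hill_mandel_gap(solution: FieldSolution, rng_seed: int = 0) -> float:
    """Relative gap between <P : dF> and P_bar : dF_bar for a random virtual
    macro increment combined with a random periodic fluctuation variation."""
    system = _get_system(solution)
    st = solution.final
    rng = np.random.default_rng(rng_seed)
    dF = rng.normal(scale=1e-3, size=(3, 3))
    ds = rng.normal(scale=1e-3 * system.mesh.h, size=(system.nc, 3))
    ds[system.pinned_class] = 0.0

    V0 = system.mesh.edge**3
    u = system.gather_u(st.F_macro, st.fluct)
    du = system.mesh.nodes @ dF.T + ds[system.mesh.node_class]
    Fq = system._elem_F(u[system.mesh.elems]).reshape(-1, 3, 3)
    dFq = np.einsum("eai,qaj->eqij", du[system.mesh.elems], system.G).reshape(-1, 3, 3)
    Pq = _pk1_batch(system.mp, Fq)
    lhs = float(np.einsum("qij,qij->", Pq, dFq) * system.wq / V0)
    P_bar, _, _, _ = system.averages(st.F_macro, st.fluct)
    if system.fibers is not None:
        fb = system.fibers
        _, (v, ell, lam, vhat, Pax, _) = system._truss_forces(st.F_macro, st.fluct)
        dv = fb.ref_vec @ dF.T + np.einsum("tm,tmi->ti", system.t_sw, ds[system.t_class])
        dlam = np.einsum("ti,ti->t", vhat, dv) / fb.length0
        lhs += float(np.sum(fb.area * fb.length0 * Pax * dlam) / V0)
    rhs = float(np.einsum("ij,ij->", P_bar, dF))
    scale = np.linalg.norm(P_bar) * np.linalg.norm(dF)
    return abs(lhs - rhs) / max(scale, 1e-30)


def face_traction_asymmetry(solution: FieldSolution) -> dict:
    """Post-hoc check of traction antisymmetry t+ = -t- on opposite faces.

    Returns per-direction averaged face tractions and the worst relative
    asymmetry ||t+ + t-|| / max ||t||.
    """
    system = _get_system(solution)
    st = solution.final
    f = system.full_internal_forces(st.F_macro, st.fluct)
    mesh = system.mesh
    area = mesh.edge**2
    out = {"directions": []}
    worst = 0.0
    for d in range(3):
        plus = np.isclose(mesh.nodes[:, d], mesh.edge)
        minus = np.isclose(mesh.nodes[:, d], 0.0)
        tp = f[plus].sum(axis=0) / area
        tm = f[minus].sum(axis=0) / area
        denom = max(np.linalg.norm(tp), np.linalg.norm(tm), 1e-30)
        rel = float(np.linalg.norm(tp + tm) / denom)
        worst = max(worst, rel)
        out["directions"].append({"axis": d, "t_plus": tp, "t_minus": tm, "rel_asymmetry": rel})
    out["worst_rel_asymmetry"] = worst
    return out


def _get_system(solution: FieldSolution) -> _System:
    system = getattr(solution, "_system", None)
    if system is None:
        system = _System(
            solution.mesh, solution.fibers, solution.matrix_params,
            solution.fiber_params, solution.config.fd_step,
        )
        solution._system = system
    return system
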