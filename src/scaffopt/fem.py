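"""Quasi-static Biot poroelastic compression of the two-phase voxel domain.

The scaffold (stiff polymer) and the granulation tissue filling its pores are
both modeled as saturated poroelastic media.  Unknowns are the solid
displacement ``u`` and the pore pressure ``p`` on a structured grid of
trilinear (Q1/Q1) hexahedral voxel elements with Brezzi-Pitkaranta pressure
stabilization; time integration is backward Euler.

Units: mm - N - MPa - s internally.  Permeability is supplied in SI
(m^4 N^-1 s^-1, i.e. hydraulic mobility including viscosity) and converted to
mm^4 N^-1 s^-1 (x 1e12) on load.  Interstitial fluid (Darcy) velocities are
reported in um/s, the unit of the mechanoregulation constant ``b``.

Boundary conditions (the confined-compression setup used throughout):

* bottom face clamped (u = 0);
* top face loaded through a rigid frictionless plate: all top-face vertical
  displacements are tied to one master degree of freedom, to which the total
  force ``F = p * A_top`` is applied (ramped linearly over ``ramp_time``);
* lateral faces: symmetry (zero normal displacement, zero fluid flux);
* drainage: top face at prescribed pore pressure (default 0), all other
  faces impermeable.  Optionally the bottom face may also be drained, which
  together with distinct top/bottom pressures realizes steady Darcy flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import GRANULATION, SCAFFOLD, VoxelModel

__all__ = [
    "MaterialProperties",
    "SCAFFOLD_PLA",
    "GRANULATION_TISSUE",
    "LoadCase",
    "BoundaryConditions",
    "ElementStates",
    "BiotSystem",
    "BiotSolution",
    "assemble_biot",
    "solve_compression",
    "element_fluid_velocity",
    "hex_stiffness",
    "hex_element_matrices",
]

_K_UNIT_SCALE = 1.0e12  # m^4/(N s) -> mm^4/(N s)


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic poroelastic material.

    Parameters
    ----------
    E_MPa, nu
        Drained Young's modulus (MPa) and Poisson's ratio.
    k_m4_Ns
        Permeability (hydraulic mobility) in m^4 N^-1 s^-1: Darcy flux is
        ``q = -k grad p``.
    n_poro
        Porosity (fluid volume fraction) of the medium itself.
    K_grain_MPa, K_fluid_MPa
        Bulk moduli of the solid grains and of the pore fluid, MPa.  These
        set the Biot coefficient ``alpha = 1 - K_drained / K_grain`` and the
        storage ``1/M = (alpha - n) / K_grain + n / K_fluid``.
    """

    E_MPa: float
    nu: float
    k_m4_Ns: float
    n_poro: float
    K_grain_MPa: float
    K_fluid_MPa: float

    def __post_init__(self) -> None:
        if self.E_MPa <= 0:
            raise ValueError("E must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must be in [0, 0.5)")
        if self.k_m4_Ns <= 0:
            raise ValueError("permeability must be positive")
        if not 0 < self.n_poro < 1:
            raise ValueError("porosity must be in (0, 1)")
        if self.K_grain_MPa <= 0 or self.K_fluid_MPa <= 0:
            raise ValueError("bulk moduli must be positive")

    @property
    def G(self) -> float:
        return self.E_MPa / (2.0 * (1.0 + self.nu))

    @property
    def lam(self) -> float:
        return self.E_MPa * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))

    @property
    def K_drained(self) -> float:
        return self.E_MPa / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def M_constrained(self) -> float:
        """Confined (oedometer) modulus lambda + 2G, MPa."""
        return self.lam + 2.0 * self.G

    @property
    def alpha(self) -> float:
        """Biot effective-stress coefficient; -> 1 as K_grain -> infinity."""
        return 1.0 - self.K_drained / self.K_grain_MPa

    @property
    def inv_M_biot(self) -> float:
        """Specific storage 1/M (1/MPa)."""
        return (
            (self.alpha - self.n_poro) / self.K_grain_MPa
            + self.n_poro / self.K_fluid_MPa
        )

    @property
    def k_mm(self) -> float:
        """Permeability in mm^4 N^-1 s^-1."""
        return self.k_m4_Ns * _K_UNIT_SCALE


#: PLA scaffold strands (drained stiffness of the printed polymer).
SCAFFOLD_PLA = MaterialProperties(
    E_MPa=2300.0, nu=0.3, k_m4_Ns=1e-14, n_poro=0.5,
    K_grain_MPa=13920.0, K_fluid_MPa=2300.0,
)

#: Early granulation tissue filling the scaffold pores.
GRANULATION_TISSUE = MaterialProperties(
    E_MPa=0.2, nu=0.167, k_m4_Ns=1e-14, n_poro=0.8,
    K_grain_MPa=2300.0, K_fluid_MPa=2300.0,
)


@dataclass(frozen=True)
class LoadCase:
    """Compressive plate load ramped linearly over ``ramp_time_s``.

    ``p_MPa`` is the force per unit loaded (top-face) area.  The total force
    on the sub-volume is ``F = p * A_top``; the per-element stimulus is
    evaluated at ``eval_time_s``.
    """

    p_MPa: float
    ramp_time_s: float = 1.0
    eval_time_s: float = 1.0
    dt_s: float = 0.05

    def __post_init__(self) -> None:
        if self.p_MPa < 0:
            raise ValueError("load p must be non-negative")
        if not self.eval_time_s >= self.ramp_time_s > 0:
            raise ValueError("need eval_time >= ramp_time > 0")
        if self.dt_s <= 0:
            raise ValueError("dt must be positive")

    def force_N(self, area_mm2: float) -> float:
        return self.p_MPa * area_mm2

    def force_at(self, t: float, area_mm2: float) -> float:
        return self.force_N(area_mm2) * min(t / self.ramp_time_s, 1.0)


@dataclass(frozen=True)
class BoundaryConditions:
    """Drainage and support options for the confined-compression setup."""

    drained_top: bool = True
    drained_bottom: bool = False
    p_top_MPa: float = 0.0
    p_bottom_MPa: float = 0.0
    clamp_bottom: bool = True  # if False, bottom only vertically supported


# ----------------------------------------------------------------------------
# reference hexahedron (cube of edge h), trilinear shape functions
# ----------------------------------------------------------------------------

# local node coordinates in {-1, 1}^3, VTK hexahedron ordering
_XI = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)


def _shape(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape values N_a(xi), shape (8,)."""
    return np.prod(1.0 + _XI * xi, axis=1) / 8.0


def _dshape_dx(xi: np.ndarray, h: float) -> np.ndarray:
    """Physical gradients dN_a/dx_i for a cube of edge h, shape (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        for i in range(3):
            term = _XI[a, i] / 8.0
            for j in range(3):
                if j != i:
                    term *= 1.0 + _XI[a, j] * xi[j]
            g[a, i] = term
    return g * (2.0 / h)  # dxi/dx = 2/h


def _gauss_points() -> tuple[np.ndarray, float]:
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([[sx * g, sy * g, sz * g]
                    for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    return pts, 1.0  # unit weights in reference coords


def _elastic_C(E: float, nu: float) -> np.ndarray:
    """Isotropic stiffness, Voigt order (xx, yy, zz, xy, yz, xz), engineering shear."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    G = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * G
    C[np.arange(3, 6), np.arange(3, 6)] = G
    return C


def _B_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6 x 24) from nodal gradients (8 x 3)."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def hex_stiffness(h: float, E: float, nu: float) -> np.ndarray:
    """24 x 24 stiffness of a cubic trilinear hexahedron of edge ``h`` (mm)."""
    C = _elastic_C(E, nu)
    pts, w = _gauss_points()
    dV = (h / 2.0) ** 3 * w
    K = np.zeros((24, 24))
    for xi in pts:
        B = _B_matrix(_dshape_dx(xi, h))
        K += B.T @ C @ B * dV
    return K


def hex_element_matrices(h: float, mat: MaterialProperties) -> dict[str, np.ndarray]:
    """All element matrices for one phase on a cubic voxel of edge ``h``.

    Returns ``K`` (24x24 stiffness), ``Q`` (24x8 coupling, alpha included),
    ``S`` (8x8 storage, 1/M included), ``H`` (8x8 Darcy, k included) and
    ``Lstab`` (8x8 pressure-Laplacian stabilization, tau included,
    tau = h^2 / (4 (lambda + 2G)) ).
    """
    C = _elastic_C(mat.E_MPa, mat.nu)
    pts, w = _gauss_points()
    dV = (h / 2.0) ** 3 * w
    K = np.zeros((24, 24))
    Q = np.zeros((24, 8))
    S = np.zeros((8, 8))
    H = np.zeros((8, 8))
    L = np.zeros((8, 8))
    for xi in pts:
        N = _shape(xi)
        g = _dshape_dx(xi, h)
        B = _B_matrix(g)
        K += B.T @ C @ B * dV
        # coupling: alpha * dN_a/dx_i * N_b
        Q += mat.alpha * np.einsum("ai,b->aib", g, N).reshape(24, 8) * dV
        S += mat.inv_M_biot * np.outer(N, N) * dV
        H += mat.k_mm * (g @ g.T) * dV
        L += (g @ g.T) * dV
    tau = h**2 / (4.0 * mat.M_constrained)
    return {"K": K, "Q": Q, "S": S, "H": H, "Lstab": tau * L}


# ----------------------------------------------------------------------------
# global assembly
# ----------------------------------------------------------------------------


@dataclass
class BiotSystem:
    """Assembled coupled displacement / pore-pressure system on the voxel grid."""

    model: VoxelModel
    K: sp.csr_matrix          # (3nn x 3nn) elasticity block
    Q: sp.csr_matrix          # (3nn x nn) pressure coupling
    S: sp.csr_matrix          # (nn x nn) storage
    H: sp.csr_matrix          # (nn x nn) Darcy conductance
    Lstab: sp.csr_matrix      # (nn x nn) pressure stabilization
    conn: np.ndarray          # (ne, 8) element -> node connectivity
    phase: np.ndarray         # (ne,) element phase label
    k_mm_phase: np.ndarray    # (ne,) element permeability, mm^4/(N s)
    grid_nodes: tuple[int, int, int]

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.grid_nodes
        return nx * ny * nz

    @property
    def n_elements(self) -> int:
        return self.conn.shape[0]


def _node_ids(nnx: int, nny: int, nnz: int) -> np.ndarray:
    return np.arange(nnx * nny * nnz).reshape(nnx, nny, nnz)


def _connectivity(shape: tuple[int, int, int]) -> np.ndarray:
    """(ne, 8) node indices per voxel in VTK hexahedron order."""
    nx, ny, nz = shape
    nid = _node_ids(nx + 1, ny + 1, nz + 1)
    i, j, k = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ]
    return np.stack([nid[i + di, j + dj, k + dk] for di, dj, dk in corners], axis=1)


def _scatter(conn_dofs: np.ndarray, elem_mats: np.ndarray, n: int, m_dofs: np.ndarray,
             ncols: int) -> sp.csr_matrix:
    """Assemble per-element dense blocks into a global sparse matrix."""
    ne, nr = conn_dofs.shape
    nc = m_dofs.shape[1]
    rows = np.repeat(conn_dofs, nc, axis=1).ravel()
    cols = np.tile(m_dofs, (1, nr)).ravel()
    return sp.coo_matrix((elem_mats.ravel(), (rows, cols)), shape=(n, ncols)).tocsr()


def assemble_biot(
    model: VoxelModel,
    mat_scaffold: MaterialProperties = SCAFFOLD_PLA,
    mat_granulation: MaterialProperties = GRANULATION_TISSUE,
) -> BiotSystem:
    """Assemble the coupled Biot system for the two-phase voxel model.

    Every voxel is a geometrically identical cube, so exactly two sets of
    element matrices (one per phase) are computed and scattered.
    """
    nx, ny, nz = model.shape
    h = model.voxel_mm
    conn = _connectivity(model.shape)
    phase = model.labels.ravel()
    ne = conn.shape[0]
    nn = (nx + 1) * (ny + 1) * (nz + 1)

    mats = {
        SCAFFOLD: hex_element_matrices(h, mat_scaffold),
        GRANULATION: hex_element_matrices(h, mat_granulation),
    }

    udofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
    pdofs = conn

    def per_elem(name: str, shape: tuple[int, int]) -> np.ndarray:
        out = np.empty((ne,) + shape)
        for ph, m in mats.items():
            out[phase == ph] = m[name]
        return out

    K = _scatter(udofs, per_elem("K", (24, 24)), 3 * nn, udofs, 3 * nn)
    Q = _scatter(udofs, per_elem("Q", (24, 8)), 3 * nn, pdofs, nn)
    S = _scatter(pdofs, per_elem("S", (8, 8)), nn, pdofs, nn)
    H = _scatter(pdofs, per_elem("H", (8, 8)), nn, pdofs, nn)
    L = _scatter(pdofs, per_elem("Lstab", (8, 8)), nn, pdofs, nn)

    k_phase = np.where(
        phase == SCAFFOLD, mat_scaffold.k_mm, mat_granulation.k_mm
    )
    return BiotSystem(
        model=model, K=K, Q=Q, S=S, H=H, Lstab=L,
        conn=conn, phase=phase.copy(), k_mm_phase=k_phase,
        grid_nodes=(nx + 1, ny + 1, nz + 1),
    )


# ----------------------------------------------------------------------------
# solve
# ----------------------------------------------------------------------------


@dataclass
class ElementStates:
    """Per-element output of a solve: volumes, principal strains, fluid speed.

    Struct-of-arrays container; index ``i`` is the element in raveled voxel
    order.  ``eps_I >= eps_II >= eps_III`` are the principal strains of the
    centroid strain tensor; ``v_um_s`` is the Darcy-flux magnitude in um/s.
    """

    volume_mm3: np.ndarray
    eps_I: np.ndarray
    eps_II: np.ndarray
    eps_III: np.ndarray
    v_um_s: np.ndarray
    phase: np.ndarray

    def __len__(self) -> int:
        return self.volume_mm3.size

    def granulation_only(self) -> "ElementStates":
        m = self.phase == GRANULATION
        return ElementStates(
            self.volume_mm3[m], self.eps_I[m], self.eps_II[m],
            self.eps_III[m], self.v_um_s[m], self.phase[m],
        )


@dataclass
class BiotSolution:
    """Full solution of a compression solve."""

    system: BiotSystem
    u: np.ndarray                  # (3nn,) displacements at eval_time, mm
    p: np.ndarray                  # (nn,) pore pressure at eval_time, MPa
    times: np.ndarray              # time grid, s
    plate_disp_mm: np.ndarray      # plate settlement history (negative down)
    p_history: np.ndarray | None   # (nsteps+1, nn) if recorded
    applied_force_N: float
    reaction_bottom_N: float
    states: ElementStates

    def settlement_mm(self) -> float:
        """Downward plate displacement magnitude at eval_time."""
        return float(-self.plate_disp_mm[-1])


def _strain_ops(h: float) -> tuple[np.ndarray, np.ndarray]:
    """Centroid B (6 x 24) and pressure gradient operator (3 x 8)."""
    g = _dshape_dx(np.zeros(3), h)
    return _B_matrix(g), g.T


def _principal_strains(eps_voigt: np.ndarray) -> np.ndarray:
    """Sorted (descending) principal strains from Voigt strains (ne, 6)."""
    ne = eps_voigt.shape[0]
    T = np.zeros((ne, 3, 3))
    T[:, 0, 0] = eps_voigt[:, 0]
    T[:, 1, 1] = eps_voigt[:, 1]
    T[:, 2, 2] = eps_voigt[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = eps_voigt[:, 3] / 2.0
    T[:, 1, 2] = T[:, 2, 1] = eps_voigt[:, 4] / 2.0
    T[:, 0, 2] = T[:, 2, 0] = eps_voigt[:, 5] / 2.0
    return np.linalg.eigvalsh(T)[:, ::-1]  # eigvalsh ascending -> flip


def solve_compression(
    system: BiotSystem,
    load: LoadCase,
    bcs: BoundaryConditions = BoundaryConditions(),
    times: np.ndarray | None = None,
    record_pressure_history: bool = False,
    solver_tol: float = 5e-3,
) -> BiotSolution:
    """Time-step the Biot system under rigid-plate compression.

    Parameters
    ----------
    times
        Optional explicit time grid (strictly increasing, ending at
        ``load.eval_time_s``); default is uniform steps of ``load.dt_s``.
    record_pressure_history
        Keep the nodal pressure at every step (for consolidation studies).
    solver_tol
        Relative tolerance on the bottom-reaction balance check.

    Returns per-element principal strains and Darcy-velocity magnitudes at
    ``eval_time`` together with the settlement history.
    """
    nnx, nny, nnz = system.grid_nodes
    nn = system.n_nodes
    ndof = 4 * nn  # 3 displacements + 1 pressure per node
    h = system.model.voxel_mm
    nid = _node_ids(nnx, nny, nnz)

    if times is None:
        nsteps = max(1, int(round(load.eval_time_s / load.dt_s)))
        times = np.linspace(0.0, load.eval_time_s, nsteps + 1)[1:]
    else:
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing and nonempty")
        if not np.isclose(times[-1], load.eval_time_s):
            raise ValueError("times must end at load.eval_time_s")

    # --- dof bookkeeping: full ordering [ux uy uz]*nn then p*nn
    def udof(nodes: np.ndarray, comp: int) -> np.ndarray:
        return 3 * nodes.ravel() + comp

    pdof_off = 3 * nn

    bottom = nid[:, :, 0]
    top = nid[:, :, -1]
    xfaces = np.concatenate([nid[0].ravel(), nid[-1].ravel()])
    yfaces = np.concatenate([nid[:, 0].ravel(), nid[:, -1].ravel()])

    fixed: dict[int, float] = {}
    if bcs.clamp_bottom:
        for c in range(3):
            for d in udof(bottom, c):
                fixed[d] = 0.0
    else:
        for d in udof(bottom, 2):
            fixed[d] = 0.0
    for d in udof(xfaces, 0):  # symmetry: zero normal displacement
        fixed.setdefault(d, 0.0)
    for d in udof(yfaces, 1):
        fixed.setdefault(d, 0.0)
    if bcs.drained_top:
        for nd in top.ravel():
            fixed[pdof_off + nd] = bcs.p_top_MPa
    if bcs.drained_bottom:
        for nd in bottom.ravel():
            fixed[pdof_off + nd] = bcs.p_bottom_MPa

    # rigid frictionless plate: every free top-face uz dof shares one plate
    # displacement U.  Rather than a master-slave tie (whose master row is
    # dense and ruins the sparse ordering) the plate is a bordered scalar:
    #   [ A_ff  a ] [y]   [b_f]          a   = A_f,plate (columns summed)
    #   [ a^T  amm] [U] = [b_m - F(t)],  amm = sum of the plate block
    plate = np.array(sorted(set(udof(top, 2)) - set(fixed)), dtype=np.int64)
    if plate.size == 0:
        raise ValueError("no free top-face vertical dof to load")

    free_mask = np.ones(ndof, dtype=bool)
    free_mask[list(fixed)] = False
    free_mask[plate] = False
    free = np.where(free_mask)[0]

    x_pres = np.zeros(ndof)
    for d, v in fixed.items():
        x_pres[d] = v
    has_lift = any(v != 0.0 for v in fixed.values())

    # --- monolithic symmetric operator
    #   [ K  -Q ] [u]   [f]
    #   [-Q' -C ] [p] = [-Q' u_n - (S + Lstab) p_n],  C = S + dt H + Lstab
    dts = np.diff(np.concatenate([[0.0], times]))
    Sg = (system.S + system.Lstab).tocsr()

    def build_A(dt: float) -> sp.csr_matrix:
        C = (Sg + dt * system.H).tocsr()
        return sp.bmat(
            [[system.K, -system.Q], [-system.Q.T, -C]], format="csr"
        )

    def factor(A_full: sp.csr_matrix):
        Aff = A_full[free][:, free].tocsc()
        a = np.asarray(A_full[free][:, plate].sum(axis=1)).ravel()
        amm = float(A_full[plate][:, plate].sum())
        lu = spla.splu(Aff)
        w2 = lu.solve(a)
        lift = A_full @ x_pres if has_lift else None
        return lu, a, amm, w2, lift

    current_dt = dts[0]
    A_full = build_A(current_dt)
    lu, a_col, amm, w2, lift = factor(A_full)

    area = ((nnx - 1) * h) * ((nny - 1) * h)

    u = np.zeros(3 * nn)
    p = np.zeros(nn)
    plate_hist = [0.0]
    p_hist = [p.copy()] if record_pressure_history else None

    b_full = np.zeros(ndof)

    for t, dt in zip(times, dts):
        if not np.isclose(dt, current_dt):
            current_dt = dt
            A_full = build_A(dt)
            lu, a_col, amm, w2, lift = factor(A_full)
        rhs_p = -(system.Q.T @ u) - (Sg @ p)
        b_full[:3 * nn] = 0.0
        b_full[3 * nn:] = rhs_p
        if lift is not None:
            b_full -= lift
        bf = b_full[free]
        bm = float(b_full[plate].sum()) - load.force_at(t, area)  # downward
        w1 = lu.solve(bf)
        U = (bm - a_col @ w1) / (amm - a_col @ w2)
        y = w1 - U * w2
        x = x_pres.copy()
        x[free] = y
        x[plate] = U
        u, p = x[:3 * nn], x[3 * nn:]
        plate_hist.append(float(U))
        if p_hist is not None:
            p_hist.append(p.copy())

    # --- bottom reaction check from unconstrained momentum rows
    resid_u = system.K @ u - system.Q @ p
    bottom_uz = udof(bottom, 2)
    reaction = float(np.sum(resid_u[bottom_uz]))
    F_applied = load.force_at(times[-1], area)
    if abs(abs(reaction) - F_applied) > max(solver_tol * F_applied, 1e-12):
        raise RuntimeError(
            f"load-reaction imbalance: bottom reaction {reaction:.6g} N vs "
            f"applied {F_applied:.6g} N"
        )

    states = _element_states(system, u, p)
    return BiotSolution(
        system=system, u=u, p=p,
        times=np.concatenate([[0.0], times]),
        plate_disp_mm=np.array(plate_hist),
        p_history=np.array(p_hist) if p_hist is not None else None,
        applied_force_N=F_applied,
        reaction_bottom_N=reaction,
        states=states,
    )


def _element_states(system: BiotSystem, u: np.ndarray, p: np.ndarray) -> ElementStates:
    h = system.model.voxel_mm
    B0, Gp = _strain_ops(h)
    conn = system.conn
    ne = conn.shape[0]

    udofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
    ue = u[udofs]                      # (ne, 24)
    eps = ue @ B0.T                    # (ne, 6) Voigt, engineering shear
    principal = _principal_strains(eps)

    pe = p[conn]                       # (ne, 8)
    grad_p = pe @ Gp.T                 # (ne, 3), MPa/mm
    v_mm_s = system.k_mm_phase * np.linalg.norm(grad_p, axis=1)
    return ElementStates(
        volume_mm3=np.full(ne, h**3),
        eps_I=principal[:, 0],
        eps_II=principal[:, 1],
        eps_III=principal[:, 2],
        v_um_s=v_mm_s * 1e3,
        phase=system.phase.copy(),
    )


def element_fluid_velocity(solution: BiotSolution, element: int) -> float:
    """Darcy-flux magnitude at one element centroid, um/s."""
    return float(solution.states.v_um_s[element])


def export_solution_vtk(solution: BiotSolution, path) -> None:
    """Write per-element strain/velocity/phase fields for inspection."""
    from . import vtkio

    shape = solution.system.model.shape
    st = solution.states
    fields = {
        "phase": st.phase.reshape(shape).astype(np.int64),
        "eps_I": st.eps_I.reshape(shape),
        "eps_II": st.eps_II.reshape(shape),
        "eps_III": st.eps_III.reshape(shape),
        "v_um_s": st.v_um_s.reshape(shape),
    }
    vtkio.write_structured_points(
        path, fields, spacing=solution.system.model.voxel_mm
    )
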