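"""Geometrically nonlinear quasi-static solver for discrete fiber networks.

Uniaxial tension of a random fiber network is simulated with a corotational
(exact nonlinear) truss element per fiber segment plus a discrete angular
spring at every interior fiber joint.  The axial law is tension-dominant:
with the effective bending radius the Euler buckling load of a segment is
four orders of magnitude below EA, so compressed segments buckle essentially
immediately; the law keeps a small configurable fraction of EA in
compression (smoothly blended) instead of resolving the buckled shapes.  The angular-spring stiffness derives
from an effective bending radius ``r_eff`` much smaller than the physical
radius, while the axial stiffness E*A is preserved (the elastic modulus is
scaled by (r_phys/r_eff)^2) - the network therefore behaves like a stable
truss whose bending contribution is negligible by design, mirroring the
behaviour of hinge-poor collagen networks whose joints have coordination 2.

Transverse (y) kinematics are governed by a single auxiliary degree of
freedom, the pivot: every boundary node obeys

    u_y = ((y - Ly/2) / (Ly/2)) * u_pivot

(+/- u_pivot on the two lateral faces, linear ramp on the loaded/fixed
faces), and the pivot is tied through a linear spring of stiffness K to a
driven node following the affine incompressible transverse motion
u_aff(lambda) = (lambda^(-1/2) - 1) * Ly/2.  K -> infinity enforces affine
transverse contraction; K -> 0 leaves the network free to contract.

The two lateral faces couple to the pivot bidirectionally (their transverse
forces balance the pivot spring).  The clamp (loaded/fixed) faces follow the
same ramp kinematically, but as a follower prescription: the grips supply
the transverse reaction there, so clamp-face forces do not load the pivot.
Without this split the stiff clamp constraint forces would dominate the
pivot equilibrium and no physical connector stiffness could steer the
response between the free and affine limits.

Fibers are generated in-plane (negligible polar angle), so out-of-plane
displacements carry no axial stiffness; u_z is fixed at zero throughout.

Units: micrometres, microNewtons, MPa.  A connector stiffness quoted in N/m
is numerically identical in uN/um.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import FiberNetwork

__all__ = [
    "MaterialParams",
    "BoundarySpec",
    "SolverConfig",
    "SimulationResult",
    "SolverError",
    "assemble_model",
    "apply_boundary_conditions",
    "solve_uniaxial",
    "pk1_curve",
    "simulate_network",
    "StressStretchCurve",
]

_FACE_TOL = 1e-6


class SolverError(RuntimeError):
    """Raised on non-convergence; carries the last converged result."""

    def __init__(self, message, partial_result=None):
        super().__init__(message)
        self.partial_result = partial_result


@dataclasses.dataclass(frozen=True)
class MaterialParams:
    """Linear elastic fiber material with the equivalent-stiffness radius trick.

    ``E_fiber`` is the physical collagen modulus (MPa) acting on the physical
    cross-section pi*r_phys^2; bending/torsion use the reduced section r_eff
    with the modulus scaled so E*A is unchanged.
    """

    E_fiber: float
    r_phys: float = 5.0
    r_eff: float = 0.1
    incompressible: bool = True
    # Slender segments buckle under minute compression (the Euler load with
    # the effective bending section is ~1e-4 of EA), so the axial law keeps
    # only a small fraction of EA in compression, blended smoothly over a
    # transition strain for a well-posed tangent.
    compression_factor: float = 1e-3
    transition_strain: float = 2e-2

    def __post_init__(self):
        if self.E_fiber <= 0:
            raise ValueError("E_fiber must be positive")
        if self.r_eff > self.r_phys:
            raise ValueError("r_eff must not exceed r_phys")
        if not 0.0 < self.compression_factor <= 1.0:
            raise ValueError("compression_factor must lie in (0, 1]")
        if self.transition_strain <= 0:
            raise ValueError("transition_strain must be positive")

    @property
    def EA(self) -> float:
        return self.E_fiber * math.pi * self.r_phys**2

    @property
    def EI_eff(self) -> float:
        # E_eff * I(r_eff) with E_eff = E * (r_phys/r_eff)^2
        e_eff = self.E_fiber * (self.r_phys / self.r_eff) ** 2
        return e_eff * math.pi * self.r_eff**4 / 4.0


@dataclasses.dataclass(frozen=True)
class BoundarySpec:
    """Loading and transverse-coupling specification.

    ``u_circ``: total axial displacement of the loaded face (um).
    ``K``: axial connector (pivot) stiffness in N/m (== uN/um).
    """

    u_circ: float
    K: float

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("connector stiffness must be non-negative")


@dataclasses.dataclass(frozen=True)
class SolverConfig:
    n_increments: int = 50
    tol_rel: float = 1e-6
    tol_abs: float | None = None   # default: 1e-9 * mean(EA)
    max_iter: int = 40
    line_search: bool = True
    stabilization: float = 1e-6    # ground-spring factor x mean(EA/L0)
    max_cutbacks: int = 8

    def __post_init__(self):
        if self.n_increments < 1:
            raise ValueError("need at least one increment")
        if self.tol_rel <= 0:
            raise ValueError("tolerance must be positive")


@dataclasses.dataclass
class StressStretchCurve:
    """Paired (stretch, PK1 stress in MPa) samples with monotone stretch."""

    stretch: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.stretch.shape != self.stress.shape:
            raise ValueError("stretch/stress length mismatch")
        if np.any(np.diff(self.stretch) < 0):
            raise ValueError("stretch must be monotone increasing")

    def resample(self, stretch_axis) -> "StressStretchCurve":
        stretch_axis = np.asarray(stretch_axis, dtype=float)
        return StressStretchCurve(
            stretch_axis, np.interp(stretch_axis, self.stretch, self.stress)
        )


@dataclasses.dataclass
class SimulationResult:
    stretch: np.ndarray            # (T,)
    force: np.ndarray              # (T,) reaction on the loaded face (uN)
    pk1: np.ndarray                # (T,) F / (Ly*Lz) (MPa)
    displacements: np.ndarray      # (T, N, 3) nodal displacement snapshots
    seg_strain: np.ndarray         # (T, M) axial engineering strain
    seg_stress: np.ndarray         # (T, M) axial stress E*eps (MPa)
    pivot: np.ndarray              # (T,) pivot transverse displacement (um)
    network: FiberNetwork
    metadata: dict

    @property
    def transverse_stretch(self) -> np.ndarray:
        """Realized transverse stretch 1 + 2*u_pivot/Ly per increment."""
        return 1.0 + 2.0 * self.pivot / self.network.box.Ly


class MechModel:
    """Assembled (and optionally constrained) mechanical model."""

    def __init__(self, net: FiberNetwork, mat: MaterialParams):
        self.net = net
        self.mat = mat
        self.X = net.nodes[:, :2].copy()       # reference in-plane coords
        self.segments = net.segments
        d = self.X[self.segments[:, 1]] - self.X[self.segments[:, 0]]
        self.L0 = np.linalg.norm(d, axis=1)
        if np.any(self.L0 <= 0):
            raise ValueError("zero-length segment in network")
        self.EA = np.full(len(self.L0), mat.EA)

        # hinges: consecutive segment pairs within a fiber
        trip = []
        for fid in range(net.n_fibers):
            idx = net.fiber_node_indices(fid)
            for j in range(len(idx) - 2):
                trip.append((idx[j], idx[j + 1], idx[j + 2]))
        self.hinges = np.asarray(trip, dtype=np.int64).reshape(-1, 3)
        seg_len_mean = float(np.mean(self.L0))
        self.k_hinge = np.full(
            len(self.hinges), mat.EI_eff / max(seg_len_mean, 1e-12)
        )
        self.psi0 = self._hinge_angles(self.X)

        # sparse scatter patterns (built once)
        a, b = self.segments[:, 0], self.segments[:, 1]
        edofs = np.stack([2 * a, 2 * a + 1, 2 * b, 2 * b + 1], axis=1)
        self._t_rows = np.repeat(edofs, 4, axis=1).ravel()
        self._t_cols = np.tile(edofs, (1, 4)).ravel()
        if len(self.hinges):
            ha, hb, hc = self.hinges.T
            hdofs = np.stack(
                [2 * ha, 2 * ha + 1, 2 * hb, 2 * hb + 1, 2 * hc, 2 * hc + 1],
                axis=1,
            )
            self._h_rows = np.repeat(hdofs, 6, axis=1).ravel()
            self._h_cols = np.tile(hdofs, (1, 6)).ravel()
            self._hdofs = hdofs
        else:
            self._h_rows = self._h_cols = self._hdofs = None
        self._edofs = edofs

        self.constrained = False

    # ---------------- element kinematics ----------------

    def _hinge_angles(self, x):
        if len(self.hinges) == 0:
            return np.zeros(0)
        a, b, c = self.hinges.T
        u1 = x[b] - x[a]
        u2 = x[c] - x[b]
        phi1 = np.arctan2(u1[:, 1], u1[:, 0])
        phi2 = np.arctan2(u2[:, 1], u2[:, 0])
        return self._wrap(phi2 - phi1)

    @staticmethod
    def _wrap(psi):
        return (psi + math.pi) % (2.0 * math.pi) - math.pi

    def _truss_state(self, x):
        a, b = self.segments[:, 0], self.segments[:, 1]
        d = x[b] - x[a]
        l = np.linalg.norm(d, axis=1)
        n = d / l[:, None]
        eps = l / self.L0 - 1.0
        N, _ = self._axial_law(eps)
        return l, n, eps, N

    def _axial_law(self, eps):
        """Axial force N(eps) and tangent dN/deps of the tension-dominant law.

        Linear EA in tension; in compression the stiffness drops smoothly
        (quadratic blend over ``transition_strain``) to
        ``compression_factor * EA``, standing in for Euler buckling of the
        slender segments.
        """
        c = self.mat.compression_factor
        et = self.mat.transition_strain
        N_hat = np.where(eps >= 0.0, eps, 0.0)
        k_hat = np.where(eps >= 0.0, 1.0, 0.0)
        blend = (eps < 0.0) & (eps >= -et)
        if np.any(blend):
            e = eps[blend]
            k_hat[blend] = c + (1.0 - c) * (1.0 + e / et) ** 2
            N_hat[blend] = c * e + (1.0 - c) * (
                e + e**2 / et + e**3 / (3.0 * et**2)
            )
        deep = eps < -et
        if np.any(deep):
            e = eps[deep]
            n_et = -c * et - (1.0 - c) * et / 3.0
            N_hat[deep] = n_et + c * (e + et)
            k_hat[deep] = c
        return self.EA * N_hat, self.EA * k_hat

    def _axial_energy(self, eps):
        """Stored axial energy per segment (integral of the axial law)."""
        c = self.mat.compression_factor
        et = self.mat.transition_strain
        psi = np.where(eps >= 0.0, 0.5 * eps**2, 0.0)
        blend = (eps < 0.0) & (eps >= -et)
        if np.any(blend):
            e = eps[blend]
            psi[blend] = 0.5 * c * e**2 + (1.0 - c) * (
                0.5 * e**2 + e**3 / (3.0 * et) + e**4 / (12.0 * et**2)
            )
        deep = eps < -et
        if np.any(deep):
            e = eps[deep]
            n_et = -c * et - (1.0 - c) * et / 3.0
            psi_et = 0.5 * c * et**2 + 0.25 * (1.0 - c) * et**2
            psi[deep] = psi_et + n_et * (e + et) + 0.5 * c * (e + et) ** 2
        return self.EA * self.L0 * psi

    def strain_energy(self, x) -> float:
        a, b = self.segments[:, 0], self.segments[:, 1]
        d = x[b] - x[a]
        l = np.linalg.norm(d, axis=1)
        eps = l / self.L0 - 1.0
        e = float(np.sum(self._axial_energy(eps)))
        if len(self.hinges):
            dev = self._wrap(self._hinge_angles(x) - self.psi0)
            e += 0.5 * np.sum(self.k_hinge * dev**2)
        return float(e)

    def internal_forces(self, x) -> np.ndarray:
        """Full internal force vector (2N,) at deformed coords x (N,2)."""
        n_dof = 2 * self.X.shape[0]
        f = np.zeros(n_dof)
        l, n, eps, N = self._truss_state(x)
        fa = -N[:, None] * n
        a, b = self.segments[:, 0], self.segments[:, 1]
        np.add.at(f, 2 * a, fa[:, 0])
        np.add.at(f, 2 * a + 1, fa[:, 1])
        np.add.at(f, 2 * b, -fa[:, 0])
        np.add.at(f, 2 * b + 1, -fa[:, 1])
        if len(self.hinges):
            g6, dev = self._hinge_grad(x)
            mom = (self.k_hinge * dev)[:, None] * g6
            np.add.at(f, self._hdofs.ravel(), mom.ravel())
        return f

    def _hinge_grad(self, x):
        a, b, c = self.hinges.T
        u1 = x[b] - x[a]
        u2 = x[c] - x[b]
        l1sq = np.sum(u1**2, axis=1)
        l2sq = np.sum(u2**2, axis=1)
        ga = np.stack([-u1[:, 1], u1[:, 0]], axis=1) / l1sq[:, None]
        gc = np.stack([-u2[:, 1], u2[:, 0]], axis=1) / l2sq[:, None]
        gb = -ga - gc
        g6 = np.concatenate([ga, gb, gc], axis=1)  # (H, 6)
        dev = self._wrap(self._hinge_angles(x) - self.psi0)
        return g6, dev

    def tangent(self, x) -> sp.csr_matrix:
        """Full tangent stiffness (2N x 2N) at deformed coords x."""
        a, b = self.segments[:, 0], self.segments[:, 1]
        d = x[b] - x[a]
        l = np.linalg.norm(d, axis=1)
        n = d / l[:, None]
        eps = l / self.L0 - 1.0
        N, k_ax = self._axial_law(eps)
        eye = np.eye(2)
        nn = n[:, :, None] * n[:, None, :]
        ke = (k_ax / self.L0)[:, None, None] * nn + (N / l)[
            :, None, None
        ] * (eye[None] - nn)
        blocks = np.empty((len(self.L0), 4, 4))
        blocks[:, :2, :2] = ke
        blocks[:, :2, 2:] = -ke
        blocks[:, 2:, :2] = -ke
        blocks[:, 2:, 2:] = ke
        rows, cols, data = self._t_rows, self._t_cols, blocks.ravel()
        if len(self.hinges):
            g6, dev = self._hinge_grad(x)
            # Gauss-Newton hinge hessian k * g g^T (curvature term omitted;
            # hinge stiffness is negligible vs axial by construction)
            hb = self.k_hinge[:, None, None] * (
                g6[:, :, None] * g6[:, None, :]
            )
            rows = np.concatenate([rows, self._h_rows])
            cols = np.concatenate([cols, self._h_cols])
            data = np.concatenate([data, hb.ravel()])
        n_dof = 2 * self.X.shape[0]
        K = sp.coo_matrix((data, (rows, cols)), shape=(n_dof, n_dof))
        return K.tocsr()


def assemble_model(net: FiberNetwork, mat: MaterialParams) -> MechModel:
    """Build the element-level model (one truss per segment + joint hinges)."""
    return MechModel(net, mat)


def apply_boundary_conditions(model: MechModel, spec: BoundarySpec) -> MechModel:
    """Constrain the model for displacement-driven uniaxial tension.

    Loaded face (x = Lx): prescribed axial ramp to ``u_circ``; fixed face
    (x = 0): axial displacement zero.  Lateral faces (y = 0, Ly): u_y slaved
    bidirectionally to the pivot (coefficient -1 / +1); the pivot is tied by
    a spring K to a driven node following the affine transverse motion.
    Clamp faces: u_y follows the ramp ((y - Ly/2)/(Ly/2)) * u_pivot as an
    externally reacted (grip) boundary condition - the grip supplies the
    transverse reaction, so these forces do not load the pivot.

    Lateral-face nodes have free axial displacement.  Consequence: fibers
    that do not span both loading faces can translate axially force-free, so
    they are stretched only through the transverse contraction.  Tethering
    them to the macroscopic axial motion instead would make them taut, and
    their mN-scale transverse pulls would then either collapse the pivot or
    (if reacted externally) make the connector stiffness K inert; either way
    K could no longer steer the transverse kinematics between the free and
    affine limits, which is the defining role of the connector.  See
    docs/methods.md for the discussion.
    """
    box = model.net.box
    X3 = model.net.nodes
    on_x0 = np.abs(X3[:, 0]) < _FACE_TOL
    on_x1 = np.abs(X3[:, 0] - box.Lx) < _FACE_TOL
    on_y0 = np.abs(X3[:, 1]) < _FACE_TOL
    on_y1 = np.abs(X3[:, 1] - box.Ly) < _FACE_TOL
    on_x = on_x0 | on_x1
    if not (np.any(on_x0) and np.any(on_x1)):
        raise ValueError("no nodes on the loading faces")

    n_nodes = X3.shape[0]
    n_dof = 2 * n_nodes
    dof_free = np.ones(n_dof, dtype=bool)
    # axial prescriptions on the clamp faces
    clamp_nodes = np.where(on_x)[0]
    dof_free[2 * clamp_nodes] = False
    # clamp-face transverse ramp (follower prescription)
    dof_free[2 * clamp_nodes + 1] = False
    # lateral faces: u_y slaved to the pivot (bidirectional); u_x free
    slave_nodes = np.where((on_y0 | on_y1) & ~on_x)[0]
    dof_free[2 * slave_nodes + 1] = False

    free_dofs = np.where(dof_free)[0]
    n_free = len(free_dofs)
    pivot_col = n_free
    c_slave = (X3[slave_nodes, 1] - box.Ly / 2.0) / (box.Ly / 2.0)
    c_clamp = (X3[clamp_nodes, 1] - box.Ly / 2.0) / (box.Ly / 2.0)

    # constraint map: free dofs + lateral slaving; the clamp-face transverse
    # ramp is applied through the prescription vector (its value follows the
    # pivot via an outer fixed-point loop, but its reaction is taken by the
    # grips and never loads the pivot)
    rows = np.concatenate([free_dofs, 2 * slave_nodes + 1])
    cols = np.concatenate(
        [np.arange(n_free), np.full(len(slave_nodes), pivot_col)]
    )
    data = np.concatenate([np.ones(n_free), c_slave])
    T = sp.csr_matrix((data, (rows, cols)), shape=(n_dof, n_free + 1))

    model.T = T
    model.Tt = T.T.tocsr()
    model.free_dofs = free_dofs
    model.pivot_col = pivot_col
    model.loaded_nodes = np.where(on_x1)[0]
    model.fixed_nodes = np.where(on_x0)[0]
    model.clamp_nodes = clamp_nodes
    model.c_clamp = c_clamp
    model.slave_nodes = slave_nodes
    model.spec = spec
    model.constrained = True
    return model


def _affine_transverse(box, lam):
    """Affine incompressible displacement of the y = Ly boundary (negative)."""
    return (lam ** (-0.5) - 1.0) * box.Ly / 2.0


def solve_uniaxial(model: MechModel, cfg: SolverConfig | None = None) -> SimulationResult:
    """Incremental Newton solution of the constrained model.

    Each increment starts from an affine predictor; the corrector is a Newton
    iteration with backtracking line search on the total potential, with
    Levenberg regularization on indefinite tangents and adaptive step
    cutbacks on failure.
    """
    if not model.constrained:
        raise ValueError("apply_boundary_conditions before solving")
    if cfg is None:
        cfg = SolverConfig()
    box = model.net.box
    spec = model.spec
    n_nodes = model.X.shape[0]
    n_dof = 2 * n_nodes
    n_unknown = model.T.shape[1]

    ea_mean = float(np.mean(model.EA))
    k_stab = cfg.stabilization * float(np.mean(model.EA / model.L0))
    tol_abs = cfg.tol_abs if cfg.tol_abs is not None else 1e-9 * ea_mean

    def presc_vector(t, p_clamp):
        g = np.zeros(n_dof)
        g[2 * model.loaded_nodes] = t * spec.u_circ
        g[2 * model.clamp_nodes + 1] = model.c_clamp * p_clamp
        return g

    def lam_of(t):
        return 1.0 + t * spec.u_circ / box.Lx

    def deformed(q, g):
        u = model.T @ q + g
        return model.X + u.reshape(-1, 2), u

    I_unknown = sp.identity(n_unknown, format="csc")
    P_pivot = sp.csc_matrix(
        ([1.0], ([model.pivot_col], [model.pivot_col])),
        shape=(n_unknown, n_unknown),
    )

    def potential(q, g, t, q_stab):
        x, _ = deformed(q, g)
        e = model.strain_energy(x)
        d_aff = _affine_transverse(box, lam_of(t))
        e += 0.5 * spec.K * (q[model.pivot_col] - d_aff) ** 2
        e += 0.5 * k_stab * float(np.sum((q - q_stab) ** 2))
        return e

    def residual(q, g, t, q_stab):
        x, _ = deformed(q, g)
        f = model.internal_forces(x)
        r = model.Tt @ f
        d_aff = _affine_transverse(box, lam_of(t))
        r[model.pivot_col] += spec.K * (q[model.pivot_col] - d_aff)
        # force scale: the unprojected internal force vector keeps the
        # reaction dofs, so its norm measures the loading level even when the
        # projected residual has converged to zero
        f_scale = float(np.linalg.norm(f)) + spec.K * abs(
            q[model.pivot_col] - d_aff
        )
        r = r + k_stab * (q - q_stab)
        return r, f, f_scale

    # Inner solve at a frozen clamp-face prescription: the system is then
    # conservative and the corrector is a Levenberg-damped Newton iteration
    # globalized by an Armijo line search on the total potential.  The damping
    # mu persists across iterations: it grows when steps have to be cut back
    # (slack, nearly indefinite regime) and decays once full Newton steps are
    # accepted, recovering quadratic convergence near the solution.
    def newton(q0, t, q_stab, p_clamp):
        q = q0.copy()
        g = presc_vector(t, p_clamp)
        mu = 0.0
        for _it in range(cfg.max_iter):
            r, f, f_scale = residual(q, g, t, q_stab)
            tol = max(tol_abs, cfg.tol_rel * f_scale)
            if np.linalg.norm(r) <= tol:
                return q, True
            x, _ = deformed(q, g)
            H = model.Tt @ model.tangent(x) @ model.T
            H = (H + k_stab * I_unknown + spec.K * P_pivot).tocsc()
            diag_scale = max(float(np.abs(H.diagonal()).mean()), 1e-30)
            for _reg in range(16):
                try:
                    lu = spla.splu(H if mu == 0.0 else H + mu * I_unknown)
                    dq = lu.solve(-r)
                except RuntimeError:
                    dq = None
                if dq is not None and np.all(np.isfinite(dq)) and r @ dq < 0:
                    break
                mu = diag_scale * 1e-8 if mu == 0.0 else mu * 100.0
            else:
                return q, False
            if cfg.line_search:
                pi0 = potential(q, g, t, q_stab)
                slope = float(r @ dq)
                alpha = 1.0
                for _ls in range(10):
                    if (
                        potential(q + alpha * dq, g, t, q_stab)
                        <= pi0 + 1e-4 * alpha * slope
                    ):
                        break
                    alpha *= 0.5
                q = q + alpha * dq
                if alpha >= 1.0:
                    mu *= 0.25
                    if mu < diag_scale * 1e-12:
                        mu = 0.0
                elif alpha <= 0.25:
                    mu = diag_scale * 1e-6 if mu == 0.0 else mu * 10.0
            else:
                q = q + dq
        r, f, f_scale = residual(q, g, t, q_stab)
        return q, np.linalg.norm(r) <= max(tol_abs, cfg.tol_rel * f_scale)

    # Outer fixed point: the clamp-face ramp value must equal the pivot
    # displacement at equilibrium.  Aitken-relaxed iteration on p.
    p_tol = 1e-7 * box.Ly
    max_outer = 30

    def solve_step(q0, t, q_stab):
        q = q0.copy()
        p_bar = float(q[model.pivot_col])
        omega = 1.0
        delta_prev = None
        for _outer in range(max_outer):
            q_new, ok = newton(q, t, q_stab, p_bar)
            if not ok:
                return q0, False
            q = q_new
            p_new = float(q[model.pivot_col])
            delta = p_new - p_bar
            if abs(delta) <= p_tol:
                return q, True
            if delta_prev is not None and delta != delta_prev:
                omega = -omega * delta_prev / (delta - delta_prev)
                omega = min(max(omega, 0.05), 1.5)
            p_bar = p_bar + omega * delta
            delta_prev = delta
        return q, abs(delta) <= 10 * p_tol

    # storage
    stations = np.linspace(0.0, 1.0, cfg.n_increments + 1)
    T_out = len(stations)
    stretch = np.empty(T_out)
    force = np.empty(T_out)
    pivot = np.empty(T_out)
    disp = np.zeros((T_out, n_nodes, 3))
    seg_eps = np.zeros((T_out, len(model.L0)))
    ext_work = 0.0
    q = np.zeros(n_unknown)

    def record(i, t, q):
        g = presc_vector(t, q[model.pivot_col])
        x, u = deformed(q, g)
        f = model.internal_forces(x)
        stretch[i] = lam_of(t)
        force[i] = float(np.sum(f[2 * model.loaded_nodes]))
        pivot[i] = q[model.pivot_col]
        disp[i, :, 0] = u[0::2]
        disp[i, :, 1] = u[1::2]
        l, n, eps, N = model._truss_state(x)
        seg_eps[i] = eps
        return f

    record(0, 0.0, q)
    t_cur = 0.0
    prev_force = 0.0
    prev_spring = 0.0
    prev_daff = _affine_transverse(box, 1.0)
    prev_qclamp = 0.0
    prev_pivot = 0.0
    clamp_y_dofs = 2 * model.clamp_nodes + 1
    for i, target in enumerate(stations[1:], start=1):
        dt_full = target - t_cur
        dt = dt_full
        cutbacks = 0
        while t_cur < target - 1e-14:
            t_try = min(t_cur + dt, target)
            # affine predictor for the free dofs and pivot
            q_pred = q + _affine_predictor(model, box, spec, t_cur, t_try)
            q_stab = q.copy()
            q_new, ok = solve_step(q_pred, t_try, q_stab)
            if not ok:
                # retry from the previous state without the predictor
                q_new, ok = solve_step(q.copy(), t_try, q_stab)
            if ok:
                q = q_new
                t_cur = t_try
                dt = min(dt * 2.0, target - t_cur) if target > t_cur else dt
            else:
                cutbacks += 1
                if cutbacks > cfg.max_cutbacks:
                    raise SolverError(
                        f"no convergence at t={t_try:.4f} after "
                        f"{cfg.max_cutbacks} cutbacks",
                        partial_result=None,
                    )
                dt *= 0.5
        f = record(i, t_cur, q)
        # external work: trapezoid on the loaded-face reaction, the driven
        # node of the pivot spring, and the grip (clamp-face transverse ramp)
        d_aff = _affine_transverse(box, lam_of(t_cur))
        spring_f = spec.K * (d_aff - q[model.pivot_col])
        q_clamp = float(model.c_clamp @ f[clamp_y_dofs])
        du = (stations[i] - stations[i - 1]) * spec.u_circ
        ext_work += 0.5 * (force[i] + prev_force) * du
        ext_work += 0.5 * (spring_f + prev_spring) * (d_aff - prev_daff)
        ext_work += 0.5 * (q_clamp + prev_qclamp) * (
            q[model.pivot_col] - prev_pivot
        )
        prev_force, prev_spring, prev_daff = force[i], spring_f, d_aff
        prev_qclamp, prev_pivot = q_clamp, q[model.pivot_col]

    g = presc_vector(t_cur, q[model.pivot_col])
    x, _ = deformed(q, g)
    stored = model.strain_energy(x)
    d_aff = _affine_transverse(box, lam_of(t_cur))
    stored += 0.5 * spec.K * (q[model.pivot_col] - d_aff) ** 2

    A0 = box.Ly * box.Lz
    E = model.mat.E_fiber
    N_all, _ = model._axial_law(seg_eps)
    area_phys = math.pi * model.mat.r_phys**2
    result = SimulationResult(
        stretch=stretch,
        force=force,
        pk1=force / A0,
        displacements=disp,
        seg_strain=seg_eps,
        seg_stress=N_all / area_phys,
        pivot=pivot,
        network=model.net,
        metadata={
            "E_fiber": E,
            "r_phys": model.mat.r_phys,
            "r_eff": model.mat.r_eff,
            "K": spec.K,
            "u_circ": spec.u_circ,
            "A0": A0,
            "k_stab": k_stab,
            "external_work": ext_work,
            "stored_energy": stored,
            "affine_rule": "incompressible lambda_t = lambda^(-1/2)",
            "sigma_convention": "doubled-angle circular std, halved degrees",
        },
    )
    return result


def _affine_predictor(model, box, spec, t0, t1):
    """Increment of the affine displacement field, mapped to unknowns."""
    def lam(t):
        return 1.0 + t * spec.u_circ / box.Lx

    l0, l1 = lam(t0), lam(t1)
    X = model.X
    dux = (l1 - l0) * X[:, 0]
    duy = (l1 ** (-0.5) - l0 ** (-0.5)) * (X[:, 1] - box.Ly / 2.0)
    dfull = np.empty(2 * X.shape[0])
    dfull[0::2] = dux
    dfull[1::2] = duy
    dq = np.zeros(model.T.shape[1])
    dq[: len(model.free_dofs)] = dfull[model.free_dofs]
    dq[model.pivot_col] = _affine_transverse(box, l1) - _affine_transverse(
        box, l0
    )
    return dq


def pk1_curve(result: SimulationResult, A0: float | None = None) -> StressStretchCurve:
    """First Piola-Kirchhoff stress curve sigma = F/A0 (MPa)."""
    if A0 is None:
        A0 = result.metadata["A0"]
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    return StressStretchCurve(result.stretch, result.force / A0)


def simulate_network(
    net: FiberNetwork,
    E_fiber: float,
    K: float,
    stretch_max: float = 2.0,
    r_eff: float = 0.1,
    cfg: SolverConfig | None = None,
) -> SimulationResult:
    """Convenience wrapper: assemble, constrain and solve in one call."""
    mat = MaterialParams(E_fiber=E_fiber, r_phys=net.r_phys, r_eff=r_eff)
    model = assemble_model(net, mat)
    spec = BoundarySpec(u_circ=(stretch_max - 1.0) * net.box.Lx, K=K)
    model = apply_boundary_conditions(model, spec)
    return solve_uniaxial(model, cfg)
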