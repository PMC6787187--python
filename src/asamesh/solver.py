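"""Quasi-static finite-element solution of the anchored contraction problem.

The tissue sheet is discretised with linear (constant-strain) triangles
under plane stress; the out-of-plane stretch is condensed out element-wise
by a scalar root solve.  Cellular contraction is ramped through the
activation parameter eta and at every level a Newton iteration with
backtracking line search finds the equilibrium displacement field.  The
rigid micropillars act through a frictionless quadratic penalty on the
signed gap of every node to every pillar circle; weak uniform springs to
the reference positions regularise the otherwise floating rigid-body modes.

The solve is fully deterministic: identical inputs yield bitwise-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    ContactStiffnessError,
    ConvergenceError,
    InvertedElementError,
    ThicknessSolveError,
)
from .geometry import PillarLayout, TissueDomain
from .mechanics import ACTIVE_PRESSURE, AS_PRINTED, MaterialParams


@dataclass(frozen=True)
class ContactParams:
    """Penalty-contact settings for the rigid, frictionless pillars.

    ``penalty_scale`` multiplies mu * element_size to give the per-node
    penalty stiffness; it is doubled automatically (up to ``max_doublings``
    times) whenever the converged penetration exceeds
    ``max_penetration_frac`` of the pillar radius.
    """

    penalty_scale: float = 1e3
    gap_tolerance: float | None = None  # um; default 1e-3 * pillar radius
    max_penetration_frac: float = 1e-3
    max_doublings: int = 5

    def __post_init__(self) -> None:
        if self.penalty_scale <= 0:
            raise ValueError("penalty_scale must be positive")
        if not (0.0 < self.max_penetration_frac <= 0.01):
            raise ValueError("max_penetration_frac must lie in (0, 0.01]")


@dataclass(frozen=True)
class ActivationSchedule:
    """Monotone activation ramp starting at zero."""

    eta_values: np.ndarray

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta_values, dtype=float)
        object.__setattr__(self, "eta_values", eta)
        if eta.ndim != 1 or len(eta) < 1:
            raise ValueError("schedule must be a 1-d sequence")
        if eta[0] != 0.0:
            raise ValueError("schedule must start at eta = 0")
        if np.any(np.diff(eta) < 0):
            raise ValueError("schedule must be non-decreasing")
        if eta[-1] > 1.0:
            raise ValueError("eta must not exceed 1")

    @classmethod
    def uniform(cls, eta_max: float = 1.0, n_steps: int = 20) -> "ActivationSchedule":
        return cls(np.linspace(0.0, eta_max, n_steps + 1))


@dataclass(frozen=True)
class SolverOptions:
    newton_tol: float = 1e-8
    max_newton_iters: int = 30
    max_bisections: int = 8
    armijo_c1: float = 1e-4
    max_line_search: int = 40
    spring_scale: float = 1e-6


@dataclass
class DeformationState:
    """Converged equilibrium at one activation level."""

    u: np.ndarray
    eta: float
    residual_norm: float
    n_iterations: int
    contact_nodes: dict[int, np.ndarray]
    min_gap: dict[int, float]
    fields: dict[str, np.ndarray]
    energy_trace: list[float] = field(default_factory=list)
    contact_force: dict[int, float] = field(default_factory=dict)

    @property
    def max_displacement(self) -> float:
        return float(np.abs(self.u).max()) if self.u.size else 0.0


def contact_gap(x: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Signed distance of deformed point(s) x to a pillar circle (negative = penetration)."""
    x = np.asarray(x, dtype=float)
    d = np.linalg.norm(np.atleast_2d(x) - np.asarray(center, dtype=float), axis=-1)
    gap = d - radius
    return gap if x.ndim > 1 else float(gap[0])


def _lambda3_vec(J2: np.ndarray, eta: float, mat: MaterialParams,
                 t0: np.ndarray | None = None) -> np.ndarray:
    """Vectorised plane-stress thickness solve (safeguarded Newton).

    Solves mu (t^2 - 1) + s(J2 t) = 0 per element; the residual is strictly
    increasing in t so bisection safeguards guarantee convergence.
    """
    mu, lam, beta = mat.mu, mat.lam, mat.beta
    as_printed = mat.active_mode == AS_PRINTED

    def g_and_dg(t):
        J = J2 * t
        lnJ = np.log(J)
        if as_printed:
            le = lam + 2.0 * eta * beta
            s = le * lnJ
            sp_ = le / J
        else:
            s = lam * lnJ + eta * beta * J
            sp_ = lam / J + eta * beta
        return mu * (t * t - 1.0) + s, 2.0 * mu * t + sp_ * J2

    lo = np.full_like(J2, 1e-3)
    hi = np.full_like(J2, 1e3)
    t = np.clip(t0 if t0 is not None else np.ones_like(J2), 1e-2, 1e2)
    tol = 1e-12 * (mu + lam + beta + 1.0)
    for _ in range(100):
        g, dg = g_and_dg(t)
        if np.all(np.abs(g) <= tol):
            break
        lo = np.where(g < 0, t, lo)
        hi = np.where(g > 0, t, hi)
        t_new = t - g / dg
        bad = ~np.isfinite(t_new) | (t_new <= lo) | (t_new >= hi)
        t = np.where(bad, 0.5 * (lo + hi), t_new)
    else:
        g, _ = g_and_dg(t)
        if np.any(np.abs(g) > 1e6 * tol):
            raise ThicknessSolveError("vectorised thickness solve failed to converge")
    return t


class ContractionProblem:
    """Assembly and Newton machinery for one domain/layout/material triple."""

    def __init__(self, domain: TissueDomain, layout: PillarLayout,
                 mat: MaterialParams, contact: ContactParams | None = None,
                 options: SolverOptions | None = None) -> None:
        self.domain = domain
        self.layout = layout
        self.mat = mat
        self.contact = contact or ContactParams()
        self.options = options or SolverOptions()

        tris = domain.triangles
        X = domain.nodes
        d1 = X[tris[:, 1]] - X[tris[:, 0]]
        d2 = X[tris[:, 2]] - X[tris[:, 0]]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        if np.any(det <= 0):
            raise InvertedElementError("reference mesh contains non-positive elements")
        self.areas = 0.5 * det
        # shape-function gradients grad N_a, (M, 3, 2)
        inv = np.empty((len(tris), 2, 2))
        inv[:, 0, 0] = d2[:, 1] / det
        inv[:, 0, 1] = -d2[:, 0] / det
        inv[:, 1, 0] = -d1[:, 1] / det
        inv[:, 1, 1] = d1[:, 0] / det
        G = np.empty((len(tris), 3, 2))
        G[:, 1, :] = inv[:, 0, :]
        G[:, 2, :] = inv[:, 1, :]
        G[:, 0, :] = -inv[:, 0, :] - inv[:, 1, :]
        self.G = G

        self.n_dof = 2 * len(X)
        dof = np.stack([2 * tris, 2 * tris + 1], axis=-1)  # (M, 3, 2)
        rows = np.repeat(dof.reshape(len(tris), 6), 6, axis=1)
        cols = np.tile(dof.reshape(len(tris), 6), (1, 6))
        self._erows = rows.ravel()
        self._ecols = cols.ravel()

        h = domain.element_size
        self.k_contact0 = self.contact.penalty_scale * mat.mu * h
        self.k_contact = self.k_contact0
        self.k_spring = self.options.spring_scale * mat.mu * h
        self.force_scale = mat.mu * h
        self.gap_tol = (self.contact.gap_tolerance
                        if self.contact.gap_tolerance is not None
                        else 1e-3 * layout.radius)
        # toe width of the C2-smoothed penalty (um): curvature ramps from 0
        # at zero gap to k over this depth, so Newton never crosses a kink
        self.toe_width = 0.5 * self.contact.max_penetration_frac * layout.radius \
            if layout.n_pillars else 0.0
        self._lam3_prev = np.ones(len(tris))

    def _penalty_terms(self, gap: np.ndarray):
        """Energy, first and second gap-derivatives of the smoothed penalty.

        Quadratic wall of stiffness k for penetrations beyond the toe width
        w, cubic toe in (-w, 0) making the force C1 and the energy C2 at
        contact onset; zero outside.
        """
        k = self.k_contact
        w = self.toe_width
        E = np.zeros_like(gap)
        d1 = np.zeros_like(gap)
        d2 = np.zeros_like(gap)
        toe = (gap < 0) & (gap >= -w)
        g = gap[toe]
        E[toe] = -k * g**3 / (6.0 * w)
        d1[toe] = -k * g**2 / (2.0 * w)
        d2[toe] = -k * g / w
        deep = gap < -w
        g = gap[deep]
        E[deep] = 0.5 * k * (g + 0.5 * w) ** 2 + k * w**2 / 24.0
        d1[deep] = k * (g + 0.5 * w)
        d2[deep] = k
        return E, d1, d2
        self._lam3_prev = np.ones(len(tris))

    # -- kinematics -------------------------------------------------------

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.domain.triangles]  # (M, 3, 2)
        F2 = np.einsum("mai,maJ->miJ", ue, self.G)
        F2[:, 0, 0] += 1.0
        F2[:, 1, 1] += 1.0
        return F2

    def _stress_terms(self, F2: np.ndarray, eta: float, need_tangent: bool):
        mat = self.mat
        mu, lam, beta = mat.mu, mat.lam, mat.beta
        as_printed = mat.active_mode == AS_PRINTED
        J2 = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
        if np.any(J2 <= 0):
            return None
        lam3 = _lambda3_vec(J2, eta, mat, self._lam3_prev)
        J = J2 * lam3
        lnJ = np.log(J)
        if as_printed:
            le = lam + 2.0 * eta * beta
            s = le * lnJ
            sp_ = le / J
        else:
            s = lam * lnJ + eta * beta * J
            sp_ = lam / J + eta * beta
        Fi = np.empty_like(F2)  # F2^{-1}
        Fi[:, 0, 0] = F2[:, 1, 1] / J2
        Fi[:, 0, 1] = -F2[:, 0, 1] / J2
        Fi[:, 1, 0] = -F2[:, 1, 0] / J2
        Fi[:, 1, 1] = F2[:, 0, 0] / J2
        FiT = np.swapaxes(Fi, 1, 2)
        P2 = mu * F2 + (s - mu)[:, None, None] * FiT
        D = None
        if need_tangent:
            eye = np.eye(2)
            # c_s = ds/dJ * dJ/dF2 prefactor after thickness condensation
            denom = 2.0 * mu * lam3 + sp_ * J2
            c_s = sp_ * J * (2.0 * mu * lam3) / denom
            D = (mu * np.einsum("ij,IJ->iIjJ", eye, eye)[None, ...]
                 - (s - mu)[:, None, None, None, None]
                 * np.einsum("mIj,mJi->miIjJ", Fi, Fi)
                 + c_s[:, None, None, None, None]
                 * np.einsum("miI,mjJ->miIjJ", FiT, FiT))
        return J2, lam3, J, lnJ, s, P2, D

    # -- energies and assembly -------------------------------------------

    def elastic_energy(self, u: np.ndarray, eta: float) -> float:
        mat = self.mat
        F2 = self.deformation_gradients(u)
        J2 = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
        if np.any(J2 <= 0):
            return np.inf
        lam3 = _lambda3_vec(J2, eta, mat, self._lam3_prev)
        J = J2 * lam3
        lnJ = np.log(J)
        I_C = np.einsum("mij,mij->m", F2, F2) + lam3**2
        U = 0.5 * mat.mu * (I_C - 3.0 - 2.0 * lnJ) + 0.5 * mat.lam * lnJ**2
        if mat.active_mode == AS_PRINTED:
            U = U + eta * mat.beta * lnJ**2
        else:
            U = U + eta * mat.beta * (J - 1.0)
        return float(np.dot(self.areas, U))

    def total_energy(self, u: np.ndarray, eta: float) -> float:
        E = self.elastic_energy(u, eta)
        if not np.isfinite(E):
            return np.inf
        x = self.domain.nodes + u
        for c in self.layout.centers:
            gap = np.linalg.norm(x - c, axis=1) - self.layout.radius
            Ec, _, _ = self._penalty_terms(gap)
            E += float(Ec.sum())
        E += 0.5 * self.k_spring * float(np.einsum("ni,ni->", u, u))
        return E

    def assemble(self, u: np.ndarray, eta: float, need_tangent: bool = True):
        """Residual (gradient of total potential) and tangent at u."""
        terms = self._stress_terms(self.deformation_gradients(u), eta, need_tangent)
        if terms is None:
            raise InvertedElementError("inverted element during assembly")
        J2, lam3, J, lnJ, s, P2, D = terms
        self._lam3_prev = lam3
        fe = np.einsum("m,miJ,maJ->mai", self.areas, P2, self.G)
        R = np.zeros((self.domain.n_nodes, 2))
        np.add.at(R, self.domain.triangles, fe)

        rows, cols, vals = [self._erows], [self._ecols], []
        if need_tangent:
            Ke = np.einsum("m,maI,miIjJ,mbJ->maibj", self.areas, self.G, D, self.G)
            vals.append(Ke.reshape(len(self.areas), 36).ravel())

        # contact penalty
        x = self.domain.nodes + u
        crows, ccols, cvals = [], [], []
        for c in self.layout.centers:
            vec = x - c
            d = np.linalg.norm(vec, axis=1)
            gap = d - self.layout.radius
            active = gap < 0
            if not np.any(active):
                continue
            idx = np.flatnonzero(active)
            _, d1, d2 = self._penalty_terms(gap[idx])
            n = vec[idx] / d[idx, None]
            R[idx] += d1[:, None] * n
            if need_tangent:
                nn = np.einsum("ni,nj->nij", n, n)
                eye = np.eye(2)[None, :, :]
                H = d2[:, None, None] * nn + (d1 / d[idx])[:, None, None] * (eye - nn)
                dof = np.stack([2 * idx, 2 * idx + 1], axis=-1)  # (n, 2)
                crows.append(np.repeat(dof, 2, axis=1).ravel())
                ccols.append(np.tile(dof, (1, 2)).ravel())
                cvals.append(H.ravel())

        # regularising springs
        R += self.k_spring * u

        K = None
        if need_tangent:
            all_rows = np.concatenate(rows + crows + [np.arange(self.n_dof)])
            all_cols = np.concatenate(cols + ccols + [np.arange(self.n_dof)])
            all_vals = np.concatenate(vals + cvals + [np.full(self.n_dof, self.k_spring)])
            K = sp.coo_matrix((all_vals, (all_rows, all_cols)),
                              shape=(self.n_dof, self.n_dof)).tocsc()
        return R, K

    # -- Newton -----------------------------------------------------------

    def _newton(self, u0: np.ndarray, eta: float):
        opts = self.options
        u = u0.copy()
        R, K = self.assemble(u, eta)
        Rn0 = np.abs(R).max()
        # relative to the larger of the step-start residual and the natural
        # force scale mu*h; the absolute floor guards the zero-load case
        tol = max(opts.newton_tol * max(Rn0, self.force_scale),
                  1e-12 * self.force_scale)
        E = self.total_energy(u, eta)
        trace = [E]
        tau = 0.0  # Levenberg shift, activated near indefinite tangents
        diag_scale = None
        for it in range(opts.max_newton_iters):
            Rn = np.abs(R).max()
            if Rn <= tol:
                return u, Rn, it, trace
            if diag_scale is None:
                diag_scale = float(np.abs(K.diagonal()).max())
            accepted = False
            for _ in range(8):  # escalate the shift until a descent step works
                Ks = K if tau == 0.0 else K + tau * diag_scale * sp.identity(
                    self.n_dof, format="csc")
                du = spla.spsolve(Ks, -R.ravel())
                slope = float(R.ravel() @ du)
                if np.isfinite(slope) and slope < 0:
                    du = du.reshape(-1, 2)
                    alpha = 1.0
                    for _ in range(opts.max_line_search):
                        u_t = u + alpha * du
                        E_t = self.total_energy(u_t, eta)
                        if E_t <= E + opts.armijo_c1 * alpha * slope:
                            accepted = True
                            break
                        alpha *= 0.5
                if accepted and alpha * np.abs(du).max() >= \
                        1e-13 * self.domain.element_size:
                    break
                accepted = False
                tau = max(4.0 * tau, 1e-6)
            if not accepted:
                return None
            tau *= 0.25  # relax the shift after a successful step
            if tau < 1e-8:
                tau = 0.0
            u = u_t
            E = E_t
            trace.append(E)
            R, K = self.assemble(u, eta)
            diag_scale = None
        Rn = np.abs(R).max()
        if Rn <= tol:
            return u, Rn, opts.max_newton_iters, trace
        return None

    def _advance(self, u: np.ndarray, eta_from: float, eta_to: float):
        """Newton continuation from eta_from to eta_to with step bisection."""
        current = eta_from
        target_stack = [eta_to]
        depth = 0
        info = None
        while target_stack:
            eta = target_stack[-1]
            result = self._newton(u, eta)
            if result is None:
                depth += 1
                if depth > self.options.max_bisections:
                    raise ConvergenceError(
                        f"Newton failed below eta = {eta:g}; last converged eta = {current:g}"
                    )
                target_stack.append(0.5 * (current + eta))
                continue
            u, rn, nit, trace = result
            current = eta
            target_stack.pop()
            info = (rn, nit, trace)
        return u, info

    def max_penetration(self, u: np.ndarray) -> float:
        if self.layout.n_pillars == 0:
            return 0.0
        x = self.domain.nodes + u
        worst = 0.0
        for c in self.layout.centers:
            gap = np.linalg.norm(x - c, axis=1) - self.layout.radius
            worst = max(worst, float(-gap.min()))
        return worst

    def make_state(self, u: np.ndarray, eta: float, residual_norm: float = np.nan,
                   n_iter: int = 0, trace: list[float] | None = None) -> DeformationState:
        terms = self._stress_terms(self.deformation_gradients(u), eta, need_tangent=False)
        if terms is None:
            raise InvertedElementError("inverted element in converged state")
        J2, lam3, J, lnJ, s, P2, _ = terms
        F2 = self.deformation_gradients(u)
        sigma2 = np.einsum("miJ,mkJ->mik", P2, F2) / J[:, None, None]
        I_C = np.einsum("mij,mij->m", F2, F2) + lam3**2
        C2 = np.einsum("mki,mkj->mij", F2, F2)  # in-plane block of C
        fields = {
            "F11": F2[:, 0, 0], "F12": F2[:, 0, 1],
            "F21": F2[:, 1, 0], "F22": F2[:, 1, 1],
            "lambda3": lam3, "J": J, "I_C": I_C,
            "sigma11": sigma2[:, 0, 0], "sigma22": sigma2[:, 1, 1],
            "sigma12": sigma2[:, 0, 1],
            "E11": C2[:, 0, 0] - 1.0, "E22": C2[:, 1, 1] - 1.0,
            "E12": C2[:, 0, 1], "E33": lam3**2 - 1.0,
            "GL11": 0.5 * (C2[:, 0, 0] - 1.0), "GL22": 0.5 * (C2[:, 1, 1] - 1.0),
            "GL12": 0.5 * C2[:, 0, 1], "GL33": 0.5 * (lam3**2 - 1.0),
        }
        x = self.domain.nodes + u
        contact_nodes: dict[int, np.ndarray] = {}
        min_gap: dict[int, float] = {}
        contact_force: dict[int, float] = {}
        for k, c in enumerate(self.layout.centers):
            gap = np.linalg.norm(x - c, axis=1) - self.layout.radius
            contact_nodes[k] = np.flatnonzero(gap <= self.gap_tol)
            min_gap[k] = float(gap.min())
            _, d1, _ = self._penalty_terms(gap)
            contact_force[k] = float(np.abs(d1).sum())
        return DeformationState(
            u=u.copy(), eta=eta, residual_norm=float(residual_norm),
            n_iterations=n_iter, contact_nodes=contact_nodes, min_gap=min_gap,
            fields=fields, energy_trace=list(trace or []),
            contact_force=contact_force,
        )

    def solve(self, schedule: ActivationSchedule | None = None) -> list[DeformationState]:
        schedule = schedule or ActivationSchedule.uniform()
        etas = schedule.eta_values
        u = np.zeros((self.domain.n_nodes, 2))
        self.k_contact = self.k_contact0
        states = [self.make_state(u, float(etas[0]), residual_norm=0.0)]
        pen_limit = self.contact.max_penetration_frac * self.layout.radius
        for eta_prev, eta in zip(etas[:-1], etas[1:]):
            u_new, info = self._advance(u, float(eta_prev), float(eta))
            doublings = 0
            while (self.layout.n_pillars and
                   self.max_penetration(u_new) > pen_limit):
                if doublings >= self.contact.max_doublings:
                    raise ContactStiffnessError(
                        f"penetration {self.max_penetration(u_new):g} um exceeds "
                        f"{pen_limit:g} um after {doublings} penalty doublings"
                    )
                self.k_contact *= 2.0
                doublings += 1
                u_new, info = self._advance(u_new, float(eta), float(eta))
            u = u_new
            rn, nit, trace = info if info is not None else (0.0, 0, [])
            states.append(self.make_state(u, float(eta), rn, nit, trace))
        return states


def assemble_system(domain: TissueDomain, u: np.ndarray, layout: PillarLayout,
                    mat: MaterialParams, eta: float,
                    contact: ContactParams | None = None):
    """One-shot residual/tangent assembly (wraps :class:`ContractionProblem`)."""
    prob = ContractionProblem(domain, layout, mat, contact)
    return prob.assemble(np.asarray(u, dtype=float), eta)


def solve_contraction(domain: TissueDomain, layout: PillarLayout,
                      mat: MaterialParams,
                      schedule: ActivationSchedule | None = None,
                      contact: ContactParams | None = None,
                      options: SolverOptions | None = None) -> list[DeformationState]:
    """Solve the activation ramp and return one equilibrium state per level."""
    prob = ContractionProblem(domain, layout, mat, contact, options)
    return prob.solve(schedule)
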