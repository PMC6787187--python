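"""Constitutive model of the contracting cell/fibrin composite.

The tissue sheet is modelled as a compressible Neo-Hookean matrix acting in
parallel with an isotropic active contraction of the embedded cells.  The
stored energy per unit reference volume is

    U(F) = mu/2 * (I_C - 3 - 2 ln J) + lam/2 * (ln J)^2 + U_a(J, eta)

with I_C = tr(C), C = F^T F, J = det F, shear modulus mu and first Lame
parameter lam derived from (E, nu), and an activation level eta in [0, 1]
scaling the active part through the chemo-mechanical stiffness beta (stress
units).  Two forms of the active term are provided:

``as_printed``
    U_a = eta * beta * (ln J)^2.  This term is minimised at J = 1, so the
    undeformed sheet is a stress-free equilibrium at every activation level
    and no contraction is predicted; it is kept for reference and testing.
``active_pressure`` (default)
    U_a = eta * beta * (J - 1), i.e. a constant isotropic active Cauchy
    tension sigma_a = eta * beta * I.  This is the minimal variant in which
    activation actually drives contraction, with beta acting as the
    contractile stress scale.

All quantities use model units: um for length, mN um^-2 for stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import (
    GeometryError,
    IncompressibilityError,
    InvertedElementError,
    KinematicsError,
    ThicknessSolveError,
)

AS_PRINTED = "as_printed"
ACTIVE_PRESSURE = "active_pressure"


def lame_from_engineering(E: float, nu: float) -> tuple[float, float]:
    """Convert Young's modulus / Poisson ratio to (mu, lam).

    mu = E / (2 (1 + nu)),  lam = E nu / ((1 + nu)(1 - 2 nu)).
    """
    if not (-1.0 < nu < 0.5):
        if nu == 0.5:
            raise IncompressibilityError("nu = 0.5: Lame's first parameter diverges")
        raise ValueError(f"nu = {nu} outside the admissible open interval (-1, 0.5)")
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu, lam


@dataclass(frozen=True)
class MaterialParams:
    """Elastic and activation moduli of the cell/fibrin composite.

    Defaults are the calibrated model values: E = 1.9, nu = 0.3, beta = 2
    (all stresses in mN um^-2).
    """

    E_young: float = 1.9
    nu: float = 0.3
    beta: float = 2.0
    active_mode: str = ACTIVE_PRESSURE

    def __post_init__(self) -> None:
        lame_from_engineering(self.E_young, self.nu)  # validates nu
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.active_mode not in (AS_PRINTED, ACTIVE_PRESSURE):
            raise ValueError(f"unknown active mode {self.active_mode!r}")

    @property
    def mu(self) -> float:
        return lame_from_engineering(self.E_young, self.nu)[0]

    @property
    def lam(self) -> float:
        return lame_from_engineering(self.E_young, self.nu)[1]

    def scaled(self, kappa: float) -> "MaterialParams":
        """Scale both stress moduli (E, beta) by kappa."""
        return MaterialParams(self.E_young * kappa, self.nu, self.beta * kappa, self.active_mode)


@dataclass(frozen=True)
class ActivationState:
    """Isotropic contraction intensity eta in [0, 1]."""

    eta_iso: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_iso <= 1.0):
            raise ValueError("eta_iso must lie in [0, 1]")


@dataclass(frozen=True)
class Kinematics:
    """Pointwise deformation measures built from a 3x3 deformation gradient.

    ``el_strain`` is the strain measure F_iI F_jJ - I_IJ (equal to C - I);
    ``green_lagrange`` is the conventional (C - I) / 2.
    """

    F: np.ndarray
    C: np.ndarray = field(init=False)
    I_C: float = field(init=False)
    J: float = field(init=False)
    el_strain: np.ndarray = field(init=False)
    green_lagrange: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise KinematicsError("F must be 3x3")
        object.__setattr__(self, "F", F)
        J = float(np.linalg.det(F))
        if J <= 0:
            raise InvertedElementError(f"non-positive Jacobian J = {J:g}")
        C = F.T @ F
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "I_C", float(np.trace(C)))
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "el_strain", C - np.eye(3))
        object.__setattr__(self, "green_lagrange", 0.5 * (C - np.eye(3)))

    @classmethod
    def from_plane(cls, F2: np.ndarray, lam3: float) -> "Kinematics":
        """Assemble the plane-stress F: in-plane 2x2 block plus stretch lam3."""
        F = np.zeros((3, 3))
        F[:2, :2] = F2
        F[2, 2] = lam3
        return cls(F)


@dataclass(frozen=True)
class StressState:
    """First Piola-Kirchhoff and Cauchy stress at a point."""

    P: np.ndarray
    sigma: np.ndarray

    @property
    def sigma11(self) -> float:
        return float(self.sigma[0, 0])

    @property
    def sigma22(self) -> float:
        return float(self.sigma[1, 1])

    @property
    def sigma12(self) -> float:
        return float(self.sigma[0, 1])


def _active_energy(J: float, eta: float, mat: MaterialParams) -> float:
    if mat.active_mode == AS_PRINTED:
        return eta * mat.beta * np.log(J) ** 2
    return eta * mat.beta * (J - 1.0)


def free_energy_density(kin: Kinematics, act: ActivationState, mat: MaterialParams) -> float:
    """Stored energy per unit reference volume, passive plus active part."""
    J = kin.J
    lnJ = np.log(J)
    U = 0.5 * mat.mu * (kin.I_C - 3.0 - 2.0 * lnJ) + 0.5 * mat.lam * lnJ**2
    return float(U + _active_energy(J, act.eta_iso, mat))


def first_pk_stress(kin: Kinematics, act: ActivationState, mat: MaterialParams) -> StressState:
    """P = dU/dF and the associated Cauchy stress sigma = P F^T / J.

    ``as_printed``:  P = mu (F - F^-T) + (lam + 2 eta beta) ln J F^-T
    ``active_pressure``:  P = mu (F - F^-T) + lam ln J F^-T + eta beta J F^-T
    """
    F = kin.F
    J = kin.J
    try:
        FiT = np.linalg.inv(F).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - J>0 guards this
        raise KinematicsError("singular deformation gradient") from exc
    lnJ = np.log(J)
    eta = act.eta_iso
    if mat.active_mode == AS_PRINTED:
        s = (mat.lam + 2.0 * eta * mat.beta) * lnJ
    else:
        s = mat.lam * lnJ + eta * mat.beta * J
    P = mat.mu * (F - FiT) + s * FiT
    sigma = P @ F.T / J
    return StressState(P=P, sigma=sigma)


def _thickness_residual(t: float, J2: float, eta: float, mat: MaterialParams) -> float:
    # J * sigma_33 expressed in terms of lam3 = t; strictly increasing in t
    J = J2 * t
    if mat.active_mode == AS_PRINTED:
        s = (mat.lam + 2.0 * eta * mat.beta) * np.log(J)
    else:
        s = mat.lam * np.log(J) + eta * mat.beta * J
    return mat.mu * (t * t - 1.0) + s


def plane_stress_thickness(
    F2: np.ndarray, act: ActivationState, mat: MaterialParams,
    bracket: tuple[float, float] = (1e-3, 1e3),
) -> float:
    """Out-of-plane stretch lam3 making the 33 Cauchy stress vanish.

    The residual mu (lam3^2 - 1) + s(J2 lam3) is strictly increasing in
    lam3, so the root is unique; it is found by Brent's method on the
    given bracket.
    """
    F2 = np.asarray(F2, dtype=float)
    J2 = float(np.linalg.det(F2))
    if J2 <= 0:
        raise InvertedElementError("in-plane gradient has non-positive determinant")
    lo, hi = bracket
    flo = _thickness_residual(lo, J2, act.eta_iso, mat)
    fhi = _thickness_residual(hi, J2, act.eta_iso, mat)
    if flo > 0 or fhi < 0:
        raise ThicknessSolveError(
            f"no thickness root in [{lo:g}, {hi:g}] for J2 = {J2:g}"
        )
    return float(brentq(_thickness_residual, lo, hi, args=(J2, act.eta_iso, mat),
                        xtol=1e-14, rtol=1e-15, maxiter=200))


def kinematics_from_displacement(
    X: np.ndarray, u: np.ndarray, lam3: float | None = None,
    act: ActivationState | None = None, mat: MaterialParams | None = None,
) -> Kinematics:
    """Constant deformation gradient of a linear triangle.

    ``X`` and ``u`` are (3, 2) arrays of reference coordinates and nodal
    displacements.  If ``lam3`` is not given it is obtained from the
    plane-stress condition (requires ``act`` and ``mat``).
    """
    X = np.asarray(X, dtype=float)
    u = np.asarray(u, dtype=float)
    if X.shape != (3, 2) or u.shape != (3, 2):
        raise GeometryError("triangle kinematics need (3, 2) coordinate arrays")
    d1 = X[1] - X[0]
    d2 = X[2] - X[0]
    det = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(det) < 1e-14 * max(1.0, np.abs(X).max()) ** 2:
        raise GeometryError("degenerate reference triangle")
    Dm = np.column_stack([d1, d2])
    Ds = np.column_stack([d1 + u[1] - u[0], d2 + u[2] - u[0]])
    F2 = Ds @ np.linalg.inv(Dm)
    if lam3 is None:
        if act is None or mat is None:
            raise ValueError("lam3 absent: act and mat are required for the plane-stress solve")
        lam3 = plane_stress_thickness(F2, act, mat)
    return Kinematics.from_plane(F2, lam3)
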