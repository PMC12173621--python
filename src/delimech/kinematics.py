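"""Incompressible isotropic biaxial kinematics.

A shear-free planar biaxial stretch state is described by the two in-plane
stretches (lambda1, lambda2).  Incompressibility fixes the thickness stretch
lambda3 = 1/(lambda1*lambda2), so the deformation gradient is
F = diag{lambda1, lambda2, 1/(lambda1*lambda2)} and the deformation is fully
characterised by the first two isotropic invariants

    I1 = lambda1**2 + lambda2**2 + (lambda1*lambda2)**-2
    I2 = lambda1**-2 + lambda2**-2 + (lambda1*lambda2)**2

A strain-energy model ``psi(I1, I2)`` (kPa) yields the in-plane Piola
stresses through the zero-thickness-stress condition P33 = 0, which
eliminates the incompressibility pressure analytically:

    P11 = 2*(l1 - 1/(l1**3 l2**2)) dpsi/dI1 + 2*(l1 l2**2 - 1/l1**3) dpsi/dI2
    P22 = 2*(l2 - 1/(l1**2 l2**3)) dpsi/dI1 + 2*(l1**2 l2 - 1/l2**3) dpsi/dI2

All stretches are dimensionless; energies and stresses are in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "STRETCH_DOMAIN",
    "EnergyModel",
    "BiaxialDeformation",
    "invariants",
    "piola_biaxial",
    "stress_coefficients",
]

#: Admissible stretch range.  The experiments this package targets stay in
#: [1, 1.25]; anything outside [0.5, 2] indicates corrupted input.
STRETCH_DOMAIN = (0.5, 2.0)


@runtime_checkable
class EnergyModel(Protocol):
    """Isotropic incompressible strain energy ``psi(I1, I2)`` in kPa.

    Implementations must satisfy ``psi(3, 3) == 0`` (stress-free reference)
    and provide the two partial derivatives used by :func:`piola_biaxial`.
    """

    def psi(self, I1, I2): ...

    def dpsi_dI1(self, I1, I2): ...

    def dpsi_dI2(self, I1, I2): ...


@dataclass(frozen=True)
class BiaxialDeformation:
    """A shear-free biaxial stretch state with incompressible thickness."""

    lambda1: float
    lambda2: float

    def __post_init__(self):
        _check_stretch(self.lambda1)
        _check_stretch(self.lambda2)

    @property
    def lambda3(self) -> float:
        return 1.0 / (self.lambda1 * self.lambda2)

    @property
    def deformation_gradient(self) -> np.ndarray:
        return np.diag([self.lambda1, self.lambda2, self.lambda3])

    def invariants(self):
        return invariants(self.lambda1, self.lambda2)


def _check_stretch(lam) -> None:
    lam = np.asarray(lam, dtype=float)
    if np.any(~np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError("stretches must be finite and positive")
    lo, hi = STRETCH_DOMAIN
    if np.any(lam < lo) or np.any(lam > hi):
        raise ValueError(
            f"stretch outside admissible domain {STRETCH_DOMAIN}; "
            "biaxial tests stay within [1, 1.25]"
        )


def invariants(lambda1, lambda2):
    """First and second isotropic invariants of an incompressible biaxial state.

    Parameters
    ----------
    lambda1, lambda2 : float or array
        In-plane stretches (> 0).

    Returns
    -------
    I1, I2 : float or array
        Both are >= 3, with equality iff lambda1 = lambda2 = 1.
    """
    _check_stretch(lambda1)
    _check_stretch(lambda2)
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    I1 = l1**2 + l2**2 + (l1 * l2) ** -2
    I2 = l1**-2 + l2**-2 + (l1 * l2) ** 2
    if np.ndim(lambda1) == 0 and np.ndim(lambda2) == 0:
        return float(I1), float(I2)
    return I1, I2


def stress_coefficients(lambda1, lambda2):
    """Geometric factors multiplying dpsi/dI1 and dpsi/dI2 in the Piola stress.

    Returns ``(a1_11, a2_11, a1_22, a2_22)`` such that

        P11 = 2*a1_11*dpsi_dI1 + 2*a2_11*dpsi_dI2
        P22 = 2*a1_22*dpsi_dI1 + 2*a2_22*dpsi_dI2
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    a1_11 = l1 - 1.0 / (l1**3 * l2**2)
    a2_11 = l1 * l2**2 - 1.0 / l1**3
    a1_22 = l2 - 1.0 / (l1**2 * l2**3)
    a2_22 = l1**2 * l2 - 1.0 / l2**3
    return a1_11, a2_11, a1_22, a2_22


def piola_biaxial(model: EnergyModel, lambda1, lambda2):
    """In-plane Piola stresses (P11, P22) in kPa for a strain-energy model.

    The thickness stress vanishes (P33 = 0): the incompressibility pressure
    has already been eliminated analytically, so only the two invariant
    derivatives of the model are needed.  Broadcasts over array stretches.
    """
    _check_stretch(lambda1)
    _check_stretch(lambda2)
    I1, I2 = invariants(lambda1, lambda2)
    d1 = np.asarray(model.dpsi_dI1(I1, I2), dtype=float)
    d2 = np.asarray(model.dpsi_dI2(I1, I2), dtype=float)
    if np.any(~np.isfinite(d1)) or np.any(~np.isfinite(d2)):
        raise FloatingPointError(
            f"non-finite energy derivatives at I1={I1!r}, I2={I2!r}"
        )
    a1_11, a2_11, a1_22, a2_22 = stress_coefficients(lambda1, lambda2)
    P11 = 2.0 * a1_11 * d1 + 2.0 * a2_11 * d2
    P22 = 2.0 * a1_22 * d1 + 2.0 * a2_22 * d2
    if np.ndim(lambda1) == 0 and np.ndim(lambda2) == 0:
        return float(P11), float(P22)
    return P11, P22
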