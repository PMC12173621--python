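"""Neo-Hooke and Mooney-Rivlin fitting for planar biaxial data.

Both classical models are linear in their parameters, so identification is
ordinary linear least squares on the stacked Piola stress components of all
five loading modes:

    neo-Hooke       psi = c1/2 (I1 - 3)            mu = c1
    Mooney-Rivlin   psi = c1/2 (I1 - 3) + c2/2 (I2 - 3)   mu = c1 + c2

with closed-form biaxial stresses

    P11 = c1 [l1 - 1/(l1^3 l2^2)] + c2 [l1 l2^2 - 1/l1^3]
    P22 = c1 [l2 - 1/(l1^2 l2^3)] + c2 [l1^2 l2 - 1/l2^3].

The incompressible elastic modulus is E = 2 mu (1 + nu) with nu = 1/2,
i.e. E = 3 mu.

Goodness of fit is reported per retained mode-direction curve (both
directions for the off and equibiaxial modes, only the stretched direction
for the strip modes) and averaged.  The default convention is the
coefficient of determination 1 - SSres/SStot per curve, which reproduces
the published per-product values; a squared-Pearson-correlation variant is
available via ``method="pearson"``.

The estimators follow the scikit-learn protocol: hyperparameters in
``__init__``, data in ``fit(X, y)`` with ``X`` the (n, 2) stretch pairs and
``y`` the (n, 2) stress pairs in kPa, fitted attributes with a trailing
underscore, and ``predict`` returning stresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import kinematics
from .biaxial_io import MeatDataset, StretchStressCurve, MODES

__all__ = [
    "NeoHookeEnergy",
    "MooneyRivlinEnergy",
    "Moduli",
    "FitResult",
    "NeoHooke",
    "MooneyRivlin",
    "nh_stress",
    "mr_stress",
    "moduli",
    "fit_model",
    "fit_samples",
    "goodness_of_fit",
    "r_squared",
]


# ---------------------------------------------------------------------------
# energy models


@dataclass(frozen=True)
class MooneyRivlinEnergy:
    """psi = c1/2 (I1 - 3) + c2/2 (I2 - 3), parameters in kPa."""

    c1: float
    c2: float

    def psi(self, I1, I2):
        return 0.5 * self.c1 * (np.asarray(I1) - 3.0) + 0.5 * self.c2 * (
            np.asarray(I2) - 3.0
        )

    def dpsi_dI1(self, I1, I2):
        return 0.5 * self.c1 * np.ones_like(np.asarray(I1, dtype=float))

    def dpsi_dI2(self, I1, I2):
        return 0.5 * self.c2 * np.ones_like(np.asarray(I2, dtype=float))


@dataclass(frozen=True)
class NeoHookeEnergy:
    """psi = c1/2 (I1 - 3); the c2 = 0 special case of Mooney-Rivlin."""

    c1: float

    def psi(self, I1, I2):
        return 0.5 * self.c1 * (np.asarray(I1) - 3.0)

    def dpsi_dI1(self, I1, I2):
        return 0.5 * self.c1 * np.ones_like(np.asarray(I1, dtype=float))

    def dpsi_dI2(self, I1, I2):
        return np.zeros_like(np.asarray(I2, dtype=float))


@dataclass(frozen=True)
class Moduli:
    """Shear and elastic moduli of an incompressible material (kPa)."""

    shear_mu: float
    elastic_E: float
    poisson_nu: float = 0.5


def moduli(params, model_kind: str) -> Moduli:
    """Moduli from fitted parameters: mu = c1 (+ c2), E = 3 mu.

    ``params`` is a scalar c1, a (c1, c2) pair, or a dict with those keys.
    """
    if isinstance(params, dict):
        c1 = params["c1"]
        c2 = params.get("c2", 0.0)
    elif np.isscalar(params):
        c1, c2 = float(params), 0.0
    else:
        c1, c2 = params
    if model_kind == "neo_hooke":
        mu = c1
    elif model_kind == "mooney_rivlin":
        mu = c1 + c2
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return Moduli(shear_mu=mu, elastic_E=3.0 * mu)


# ---------------------------------------------------------------------------
# closed-form stresses


def nh_stress(c1: float, lambda1, lambda2):
    """Neo-Hooke biaxial Piola stresses (P11, P22) in kPa."""
    a1_11, _, a1_22, _ = kinematics.stress_coefficients(lambda1, lambda2)
    return c1 * a1_11, c1 * a1_22


def mr_stress(c1: float, c2: float, lambda1, lambda2):
    """Mooney-Rivlin biaxial Piola stresses (P11, P22) in kPa."""
    a1_11, a2_11, a1_22, a2_22 = kinematics.stress_coefficients(lambda1, lambda2)
    return c1 * a1_11 + c2 * a2_11, c1 * a1_22 + c2 * a2_22


# ---------------------------------------------------------------------------
# estimators


class _LinearHyperelastic(RegressorMixin, BaseEstimator):
    """Shared linear-least-squares machinery for the two classical models."""

    _n_params: int  # 1 for neo-Hooke, 2 for Mooney-Rivlin

    @staticmethod
    def _design(X, component=None):
        l1, l2 = X[:, 0], X[:, 1]
        a1_11, a2_11, a1_22, a2_22 = kinematics.stress_coefficients(l1, l2)
        if component is None:
            return np.stack([a1_11, a2_11], -1), np.stack([a1_22, a2_22], -1)
        a1 = np.where(component == 0, a1_11, a1_22)
        a2 = np.where(component == 0, a2_11, a2_22)
        return np.stack([a1, a2], -1)

    def fit(self, X, y, component=None):
        """Identify parameters by ordinary least squares.

        Parameters
        ----------
        X : (n, 2) array
            Stretch pairs (lambda1, lambda2).
        y : (n, 2) or (n,) array
            Piola stresses in kPa.  The (n, 2) form carries both components
            per stretch state; the flat form requires ``component`` (0 for
            the 11-, 1 for the 22-component) per row.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2) stretch pairs")
        if y.ndim == 2:
            A11, A22 = self._design(X)
            A = np.vstack([A11, A22])
            b = np.concatenate([y[:, 0], y[:, 1]])
        else:
            if component is None:
                raise ValueError("flat y requires a per-row component array")
            A = self._design(X, np.asarray(component))
            b = y
        keep = ~np.isnan(b)
        A, b = A[keep, : self._n_params], b[keep]
        if A.shape[0] < self._n_params or np.linalg.matrix_rank(A) < self._n_params:
            raise np.linalg.LinAlgError(
                "singular fit: data do not constrain the parameters "
                "(e.g. all points at stretch 1)"
            )
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        self._set_coef(coef)
        self.loss_ = float(np.sum((A @ coef - b) ** 2))
        self.n_points_ = int(b.size)
        return self

    def predict(self, X):
        """Predicted (P11, P22) stress pairs, shape (n, 2)."""
        X = np.asarray(X, dtype=float)
        A11, A22 = self._design(X)
        c = self._coef()
        return np.stack([A11[:, : self._n_params] @ c, A22[:, : self._n_params] @ c], -1)


class NeoHooke(_LinearHyperelastic):
    """One-parameter neo-Hooke regressor; fitted attribute ``c1_`` (kPa)."""

    _n_params = 1
    model_kind = "neo_hooke"

    def _set_coef(self, coef):
        self.c1_ = float(coef[0])
        self.energy_ = NeoHookeEnergy(self.c1_)
        self.moduli_ = moduli(self.c1_, self.model_kind)

    def _coef(self):
        return np.array([self.c1_])


class MooneyRivlin(_LinearHyperelastic):
    """Two-parameter Mooney-Rivlin regressor; fitted ``c1_``, ``c2_`` (kPa)."""

    _n_params = 2
    model_kind = "mooney_rivlin"

    def _set_coef(self, coef):
        self.c1_, self.c2_ = (float(c) for c in coef)
        self.energy_ = MooneyRivlinEnergy(self.c1_, self.c2_)
        self.moduli_ = moduli((self.c1_, self.c2_), self.model_kind)

    def _coef(self):
        return np.array([self.c1_, self.c2_])


_ESTIMATORS = {"neo_hooke": NeoHooke, "mooney_rivlin": MooneyRivlin}


# ---------------------------------------------------------------------------
# goodness of fit


def r_squared(predicted, observed, method: str = "determination") -> float:
    """Goodness of fit of one curve.

    ``"determination"``: classic 1 - SSres/SStot (can be negative for fits
    worse than the mean).  ``"pearson"``: squared Pearson correlation, which
    is insensitive to affine miscalibration of the predictions.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if observed.std() == 0:
        return float("nan")
    if method == "determination":
        ss_res = np.sum((predicted - observed) ** 2)
        ss_tot = np.sum((observed - observed.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot)
    if method == "pearson":
        return float(np.corrcoef(predicted, observed)[0, 1] ** 2)
    raise ValueError(f"unknown R^2 method {method!r}")


def goodness_of_fit(
    model: kinematics.EnergyModel,
    dataset: MeatDataset,
    method: str = "determination",
    include_hold: bool = False,
) -> tuple[dict[str, float], float, float]:
    """Per-curve R^2 of an energy model on a dataset, with mean and std.

    Returns ``(per_curve, mean, std)`` where ``per_curve`` maps
    ``"<mode>:<direction>"`` to the curve's R^2.  By default the held
    channels of the strip modes are excluded, matching the published
    convention; curves with constant measured stress yield NaN and are
    dropped from the aggregates.
    """
    per_curve: dict[str, float] = {}
    for mode in MODES:
        cx = dataset.curve(mode, "x")
        cy = dataset.curve(mode, "y")
        p11, p22 = kinematics.piola_biaxial(model, cx.stretch, cy.stretch)
        for curve, pred in ((cx, p11), (cy, p22)):
            if curve.is_hold and not include_hold:
                continue
            per_curve[f"{mode}:{curve.direction}"] = r_squared(
                pred, curve.stress, method=method
            )
    vals = np.array([v for v in per_curve.values() if np.isfinite(v)])
    if vals.size < len(per_curve):
        import warnings

        warnings.warn("curve(s) with constant stress excluded from mean R^2")
    return per_curve, float(vals.mean()), float(vals.std())


# ---------------------------------------------------------------------------
# dataset-level fitting


@dataclass
class FitResult:
    """Identified parameters, moduli, and goodness of fit for one product."""

    model_kind: str
    params: dict[str, float]
    moduli: Moduli
    r2_per_curve: dict[str, float]
    r2_mean: float
    r2_std: float
    loss_value: float
    n_points: int
    product_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "product_id": self.product_id,
            "params_kPa": self.params,
            "shear_mu_kPa": self.moduli.shear_mu,
            "elastic_E_kPa": self.moduli.elastic_E,
            "r2_per_curve": self.r2_per_curve,
            "r2_mean": self.r2_mean,
            "r2_std": self.r2_std,
            "loss_value": self.loss_value,
            "n_points": self.n_points,
        }


def fit_model(
    dataset: MeatDataset,
    model_kind: str = "neo_hooke",
    include_hold: bool = True,
    r2_method: str = "determination",
    r2_include_hold: bool = False,
) -> FitResult:
    """Least-squares fit of a classical model to one product's dataset.

    All five modes are stacked into a single unweighted least-squares
    problem.  The held strip-mode channels are *included* in the fit by
    default (they are measured stresses) but *excluded* from R^2, the
    combination used for the published parameter and fit-quality tables;
    both choices are exposed.
    """
    if model_kind not in _ESTIMATORS:
        raise ValueError(f"model_kind must be one of {sorted(_ESTIMATORS)}")
    l1, l2, p, comp = dataset.stacked(include_hold=include_hold)
    est = _ESTIMATORS[model_kind]()
    est.fit(np.stack([l1, l2], -1), p, component=comp)
    per_curve, r2_mean, r2_std = goodness_of_fit(
        est.energy_, dataset, method=r2_method, include_hold=r2_include_hold
    )
    params = {"c1": est.c1_}
    if model_kind == "mooney_rivlin":
        params["c2"] = est.c2_
    return FitResult(
        model_kind=model_kind,
        params=params,
        moduli=est.moduli_,
        r2_per_curve=per_curve,
        r2_mean=r2_mean,
        r2_std=r2_std,
        loss_value=est.loss_,
        n_points=est.n_points_,
        product_id=dataset.product_id,
    )


def fit_samples(
    sample_datasets: list[MeatDataset], model_kind: str = "neo_hooke", **kwargs
) -> dict:
    """Fit each per-sample dataset individually; report mean +/- std.

    This is the published convention for *parameters* (each sample fitted
    on its own, then averaged), complementing :func:`fit_model` on the mean
    data, which is the published convention for R^2.
    """
    fits = [fit_model(d, model_kind, **kwargs) for d in sample_datasets]
    names = fits[0].params.keys()
    out = {
        "model_kind": model_kind,
        "n_samples": len(fits),
        "fits": fits,
        "params_mean": {k: float(np.mean([f.params[k] for f in fits])) for k in names},
        "params_std": {k: float(np.std([f.params[k] for f in fits], ddof=1)) for k in names},
        "shear_mu_mean": float(np.mean([f.moduli.shear_mu for f in fits])),
        "shear_mu_std": float(np.std([f.moduli.shear_mu for f in fits], ddof=1)),
        "elastic_E_mean": float(np.mean([f.moduli.elastic_E for f in fits])),
        "elastic_E_std": float(np.std([f.moduli.elastic_E for f in fits], ddof=1)),
    }
    return out
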