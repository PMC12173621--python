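"""Sparse automated discovery of two-term strain-energy models.

The discovery network is a fixed library of eight invariant-based energy
terms — the identity and the exponential applied to the first and second
powers of (I1 - 3) and (I2 - 3):

    psi = w1 w1* (I1-3)  + w2 [exp(w2* (I1-3)) - 1]
        + w3 w3* (I1-3)^2 + w4 [exp(w4* (I1-3)^2) - 1]
        + w5 w5* (I2-3)  + w6 [exp(w6* (I2-3)) - 1]
        + w7 w7* (I2-3)^2 + w8 [exp(w8* (I2-3)^2) - 1]

with eight external weights w (kPa scale) and eight internal weights w*
(dimensionless), all constrained non-negative.  Term 1 alone is the
neo-Hooke model with c1 = 2 w1 w1*; terms {1, 5} embed Mooney-Rivlin.

Training minimises the mean squared Piola-stress error over all five
biaxial modes simultaneously, plus an L1 penalty alpha * sum(w) on the
external weights, by Adam gradient descent with analytic gradients and
projection onto w >= 0.  Sweeping alpha upward and keeping the smallest
value at which exactly two terms survive yields a sparse, interpretable
two-term model, which is then refit without penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import kinematics
from .biaxial_io import MeatDataset
from .classical_fits import goodness_of_fit

__all__ = [
    "N_TERMS",
    "TERM_LABELS",
    "NetworkEnergy",
    "TrainingConfig",
    "DiscoveryResult",
    "ConstitutiveNetwork",
    "TwoTermDiscovery",
    "cann_energy",
    "cann_stress",
    "train",
    "discover_two_term",
    "n_two_term_models",
]

N_TERMS = 8
TERM_LABELS = (
    "(I1-3)",
    "exp(I1-3)-1",
    "(I1-3)^2",
    "exp((I1-3)^2)-1",
    "(I2-3)",
    "exp(I2-3)-1",
    "(I2-3)^2",
    "exp((I2-3)^2)-1",
)

_EXP_GUARD = 50.0  # exponent cap before declaring overflow


def n_two_term_models() -> int:
    """Number of distinct two-term models the library admits."""
    return sum(1 for _ in combinations(range(N_TERMS), 2))


def _term_features(w_ext, w_int, x):
    """Per-term energy and d(energy)/d(invariant) for one invariant offset x.

    ``x`` is I1-3 (terms 0..3) or I2-3 (terms 4..7); the caller passes the
    4-slice of weights belonging to that invariant.  Returns arrays of shape
    (4, len(x)): psi_k, f_k = dpsi_k/dI, plus partials of f_k with respect
    to the external and internal weight of term k.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w_ext, dtype=float)
    ws = np.asarray(w_int, dtype=float)
    psi = np.empty((4, x.size))
    f = np.empty((4, x.size))
    df_dw = np.empty((4, x.size))
    df_dws = np.empty((4, x.size))
    # identity of power 1
    psi[0] = w[0] * ws[0] * x
    f[0] = w[0] * ws[0]
    df_dw[0] = ws[0]
    df_dws[0] = w[0]
    # exponential of power 1
    arg = ws[1] * x
    if np.any(arg > _EXP_GUARD):
        raise OverflowError("exponential-linear term overflow (internal weight too large)")
    e = np.exp(arg)
    psi[1] = w[1] * (e - 1.0)
    f[1] = w[1] * ws[1] * e
    df_dw[1] = ws[1] * e
    df_dws[1] = w[1] * e * (1.0 + ws[1] * x)
    # identity of power 2
    psi[2] = w[2] * ws[2] * x**2
    f[2] = 2.0 * w[2] * ws[2] * x
    df_dw[2] = 2.0 * ws[2] * x
    df_dws[2] = 2.0 * w[2] * x
    # exponential of power 2
    arg = ws[3] * x**2
    if np.any(arg > _EXP_GUARD):
        raise OverflowError("exponential-quadratic term overflow (internal weight too large)")
    eq = np.exp(arg)
    psi[3] = w[3] * (eq - 1.0)
    f[3] = 2.0 * w[3] * ws[3] * x * eq
    df_dw[3] = 2.0 * ws[3] * x * eq
    df_dws[3] = 2.0 * w[3] * x * eq * (1.0 + ws[3] * x**2)
    return psi, f, df_dw, df_dws


@dataclass(frozen=True)
class NetworkEnergy:
    """The eight-term energy with fixed weights; implements ``EnergyModel``."""

    w_ext: np.ndarray
    w_int: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w_ext, dtype=float)
        ws = np.asarray(self.w_int, dtype=float)
        if w.shape != (N_TERMS,) or ws.shape != (N_TERMS,):
            raise ValueError(f"need {N_TERMS} external and {N_TERMS} internal weights")
        if np.any(w < 0) or np.any(ws < 0):
            raise ValueError("network weights must be non-negative")
        object.__setattr__(self, "w_ext", w)
        object.__setattr__(self, "w_int", ws)

    def psi(self, I1, I2):
        p1, *_ = _term_features(self.w_ext[:4], self.w_int[:4], np.asarray(I1) - 3.0)
        p2, *_ = _term_features(self.w_ext[4:], self.w_int[4:], np.asarray(I2) - 3.0)
        out = p1.sum(0) + p2.sum(0)
        return out if out.size > 1 else float(out[0])

    def dpsi_dI1(self, I1, I2):
        _, f, _, _ = _term_features(self.w_ext[:4], self.w_int[:4], np.asarray(I1) - 3.0)
        out = f.sum(0)
        return out if out.size > 1 else float(out[0])

    def dpsi_dI2(self, I1, I2):
        _, f, _, _ = _term_features(self.w_ext[4:], self.w_int[4:], np.asarray(I2) - 3.0)
        out = f.sum(0)
        return out if out.size > 1 else float(out[0])

    def term_products(self) -> np.ndarray:
        """w_k * w*_k per term — the effective contribution scale."""
        return self.w_ext * self.w_int

    def active_terms(self, zero_threshold: float = 1e-3) -> tuple[int, ...]:
        """1-based indices of terms whose weight product exceeds the
        threshold relative to the largest product."""
        prod = self.term_products()
        top = prod.max()
        if top <= 0:
            return ()
        return tuple(int(i) + 1 for i in np.flatnonzero(prod > zero_threshold * top))


def cann_energy(w_ext, w_int, I1, I2):
    """Strain energy psi(I1, I2) in kPa of the eight-term network."""
    return NetworkEnergy(np.asarray(w_ext), np.asarray(w_int)).psi(I1, I2)


def cann_stress(w_ext, w_int, lambda1, lambda2):
    """Biaxial Piola stresses (P11, P22) in kPa of the eight-term network."""
    model = NetworkEnergy(np.asarray(w_ext), np.asarray(w_int))
    return kinematics.piola_biaxial(model, lambda1, lambda2)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingConfig:
    """Hyperparameters of network training and of the sparsity sweep.

    ``l1_alpha`` weights the L1 penalty on the external (stress-scale)
    weights; ``alpha_sweep`` is the ascending list tried by
    :func:`discover_two_term`; ``zero_threshold`` declares a term inactive
    when its weight product falls below this fraction of the largest one.
    """

    learning_rate: float = 1e-3
    epochs: int = 20000
    l1_alpha: float = 0.0
    alpha_sweep: tuple[float, ...] = tuple(np.logspace(-4, 0, 9))
    zero_threshold: float = 1e-3
    seed: int = 0
    refit_after_selection: bool = True
    include_hold: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l1_alpha < 0:
            raise ValueError("l1_alpha must be non-negative")


class ConstitutiveNetwork(RegressorMixin, BaseEstimator):
    """Eight-term invariant network trained by Adam with optional L1 sparsity.

    Parameters
    ----------
    alpha : float
        L1 penalty weight on the external weights (0 disables sparsity).
    learning_rate, epochs : Adam step size and iteration count.
    random_state : seed for the uniform(0, 1) weight initialisation.
    term_mask : optional boolean mask (8,) freezing masked-out terms at 0,
        used for refitting a selected sparse model.
    penalize_internal : also apply the L1 penalty to internal weights.

    Fitted attributes: ``w_ext_``, ``w_int_`` (8,) arrays, ``energy_``
    (:class:`NetworkEnergy`), ``loss_trajectory_`` (recorded every 100
    epochs), ``loss_``.
    """

    def __init__(
        self,
        alpha: float = 0.0,
        learning_rate: float = 1e-3,
        epochs: int = 20000,
        random_state: int = 0,
        zero_threshold: float = 1e-3,
        term_mask=None,
        penalize_internal: bool = False,
    ):
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.random_state = random_state
        self.zero_threshold = zero_threshold
        self.term_mask = term_mask
        self.penalize_internal = penalize_internal

    def _stress_and_grads(self, theta, x, y, A1, A2):
        _, f1, df1_dw, df1_dws = _term_features(theta[0:4], theta[8:12], x)
        _, f2, df2_dw, df2_dws = _term_features(theta[4:8], theta[12:16], y)
        P = A1 * f1.sum(0) + A2 * f2.sum(0)
        dP = np.empty((16, x.size))
        dP[0:4] = A1 * df1_dw
        dP[4:8] = A2 * df2_dw
        dP[8:12] = A1 * df1_dws
        dP[12:16] = A2 * df2_dws
        return P, dP

    def fit(self, X, y, component=None):
        """Train the network on stacked biaxial stress data.

        ``X`` is (n, 2) stretch pairs; ``y`` is (n, 2) stress pairs (NaN
        entries are ignored) or flat (n,) with a per-row ``component``
        array (0 -> P11, 1 -> P22).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2) stretch pairs")
        l1, l2 = X[:, 0], X[:, 1]
        a1_11, a2_11, a1_22, a2_22 = kinematics.stress_coefficients(l1, l2)
        if y.ndim == 2:
            l1 = np.concatenate([l1, l1])
            l2 = np.concatenate([l2, l2])
            A1 = 2.0 * np.concatenate([a1_11, a1_22])
            A2 = 2.0 * np.concatenate([a2_11, a2_22])
            p = np.concatenate([y[:, 0], y[:, 1]])
        else:
            if component is None:
                raise ValueError("flat y requires a per-row component array")
            component = np.asarray(component)
            A1 = 2.0 * np.where(component == 0, a1_11, a1_22)
            A2 = 2.0 * np.where(component == 0, a2_11, a2_22)
            p = y
        keep = ~np.isnan(p)
        A1, A2, p = A1[keep], A2[keep], p[keep]
        I1, I2 = kinematics.invariants(l1[keep], l2[keep])
        x_feat = np.asarray(I1) - 3.0
        y_feat = np.asarray(I2) - 3.0

        mask = np.ones(16, dtype=bool)
        if self.term_mask is not None:
            tm = np.asarray(self.term_mask, dtype=bool)
            if tm.shape != (N_TERMS,):
                raise ValueError("term_mask must have shape (8,)")
            mask = np.concatenate([tm, tm])

        rng = np.random.default_rng(self.random_state)
        theta = rng.uniform(0.0, 1.0, 16)
        theta[~mask] = 0.0
        n = p.size
        penalty = np.zeros(16)
        penalty[0:8] = self.alpha
        if self.penalize_internal:
            penalty[8:16] = self.alpha

        m = np.zeros(16)
        v = np.zeros(16)
        b1, b2, eps = 0.9, 0.999, 1e-8
        trajectory = []
        for step in range(1, self.epochs + 1):
            P, dP = self._stress_and_grads(theta, x_feat, y_feat, A1, A2)
            r = P - p
            mse = float(np.mean(r**2))
            if not np.isfinite(mse):
                raise FloatingPointError(
                    "training diverged (loss is not finite); lower the learning rate"
                )
            g = (2.0 / n) * (dP @ r) + penalty  # subgradient of alpha*|w| on w>=0
            g[~mask] = 0.0
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            theta -= self.learning_rate * (m / (1 - b1**step)) / (
                np.sqrt(v / (1 - b2**step)) + eps
            )
            np.maximum(theta, 0.0, out=theta)  # projection: non-negative weights
            theta[~mask] = 0.0
            if step % 100 == 0 or step == 1:
                trajectory.append(mse + float(penalty @ theta))
        P, _ = self._stress_and_grads(theta, x_feat, y_feat, A1, A2)
        self.w_ext_ = theta[:8].copy()
        self.w_int_ = theta[8:].copy()
        self.energy_ = NetworkEnergy(self.w_ext_, self.w_int_)
        self.loss_ = float(np.mean((P - p) ** 2))
        self.loss_trajectory_ = np.asarray(trajectory)
        self.n_iter_ = self.epochs
        return self

    def predict(self, X):
        """Predicted (P11, P22) stress pairs, shape (n, 2)."""
        X = np.asarray(X, dtype=float)
        P11, P22 = kinematics.piola_biaxial(self.energy_, X[:, 0], X[:, 1])
        return np.stack([np.atleast_1d(P11), np.atleast_1d(P22)], -1)

    def active_terms(self) -> tuple[int, ...]:
        return self.energy_.active_terms(self.zero_threshold)


@dataclass
class DiscoveryResult:
    """Outcome of the two-term discovery sweep for one product."""

    product_id: str | None
    alpha: float
    active_terms: tuple[int, ...]
    term_labels: tuple[str, ...]
    energy: NetworkEnergy
    penalized_energy: NetworkEnergy
    r2_per_curve: dict[str, float]
    r2_mean: float
    r2_std: float
    loss_trajectory: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "product_id": self.product_id,
            "alpha": self.alpha,
            "active_terms": list(self.active_terms),
            "term_labels": list(self.term_labels),
            "w_ext_kPa": self.energy.w_ext.tolist(),
            "w_int": self.energy.w_int.tolist(),
            "r2_per_curve": self.r2_per_curve,
            "r2_mean": self.r2_mean,
            "r2_std": self.r2_std,
            "seed": self.seed,
        }


class TwoTermDiscovery(BaseEstimator):
    """Sweep the L1 weight upward until exactly two terms survive.

    Trains the eight-term network at each alpha of ``alpha_sweep``
    (ascending, stopping early at the first success), selects the smallest
    alpha whose trained weights leave exactly two terms above the zero
    threshold, and by default refits those two terms without penalty.

    Fitted attributes: ``alpha_``, ``active_terms_`` (1-based),
    ``term_labels_``, ``network_`` (the refit :class:`ConstitutiveNetwork`),
    ``penalized_network_``, ``term_count_profile_``.
    """

    def __init__(
        self,
        alpha_sweep=tuple(np.logspace(-4, 0, 9)),
        learning_rate: float = 1e-3,
        epochs: int = 20000,
        random_state: int = 0,
        zero_threshold: float = 1e-3,
        refit_after_selection: bool = True,
        penalize_internal: bool = False,
    ):
        self.alpha_sweep = alpha_sweep
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.random_state = random_state
        self.zero_threshold = zero_threshold
        self.refit_after_selection = refit_after_selection
        self.penalize_internal = penalize_internal

    def fit(self, X, y, component=None):
        sweep = sorted(self.alpha_sweep)
        if not sweep:
            raise ValueError("alpha_sweep must be non-empty")
        profile = {}
        chosen = None
        for alpha in sweep:
            net = ConstitutiveNetwork(
                alpha=alpha,
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                random_state=self.random_state,
                zero_threshold=self.zero_threshold,
                penalize_internal=self.penalize_internal,
            ).fit(X, y, component=component)
            active = net.active_terms()
            profile[alpha] = len(active)
            if len(active) == 2:
                chosen = (alpha, net, active)
                break
        self.term_count_profile_ = profile
        if chosen is None:
            raise RuntimeError(
                "no alpha in the sweep produced exactly two active terms; "
                f"term counts per alpha: {profile}"
            )
        self.alpha_, self.penalized_network_, self.active_terms_ = chosen
        self.term_labels_ = tuple(TERM_LABELS[i - 1] for i in self.active_terms_)
        if self.refit_after_selection:
            term_mask = np.zeros(N_TERMS, dtype=bool)
            term_mask[[i - 1 for i in self.active_terms_]] = True
            self.network_ = ConstitutiveNetwork(
                alpha=0.0,
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                random_state=self.random_state,
                zero_threshold=self.zero_threshold,
                term_mask=term_mask,
            ).fit(X, y, component=component)
        else:
            self.network_ = self.penalized_network_
        return self

    def predict(self, X):
        return self.network_.predict(X)


# ---------------------------------------------------------------------------
# dataset-level wrappers


def train(dataset: MeatDataset, config: TrainingConfig | None = None):
    """Train the eight-term network on all five modes of one product.

    Returns ``(energy, loss_trajectory)``.
    """
    config = config or TrainingConfig()
    l1, l2, p, comp = dataset.stacked(include_hold=config.include_hold)
    net = ConstitutiveNetwork(
        alpha=config.l1_alpha,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        random_state=config.seed,
        zero_threshold=config.zero_threshold,
    ).fit(np.stack([l1, l2], -1), p, component=comp)
    return net.energy_, net.loss_trajectory_


def discover_two_term(
    dataset: MeatDataset, config: TrainingConfig | None = None
) -> DiscoveryResult:
    """Two-term model discovery for one product (see :class:`TwoTermDiscovery`)."""
    config = config or TrainingConfig()
    l1, l2, p, comp = dataset.stacked(include_hold=config.include_hold)
    disc = TwoTermDiscovery(
        alpha_sweep=config.alpha_sweep,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        random_state=config.seed,
        zero_threshold=config.zero_threshold,
        refit_after_selection=config.refit_after_selection,
    ).fit(np.stack([l1, l2], -1), p, component=comp)
    per_curve, r2_mean, r2_std = goodness_of_fit(disc.network_.energy_, dataset)
    return DiscoveryResult(
        product_id=dataset.product_id,
        alpha=disc.alpha_,
        active_terms=disc.active_terms_,
        term_labels=disc.term_labels_,
        energy=disc.network_.energy_,
        penalized_energy=disc.penalized_network_.energy_,
        r2_per_curve=per_curve,
        r2_mean=r2_mean,
        r2_std=r2_std,
        loss_trajectory=disc.network_.loss_trajectory_,
        seed=config.seed,
    )
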