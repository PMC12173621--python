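"""Synthetic biaxial recordings and sensory panels with known ground truth.

The biaxial generator emulates the study design this package analyses:
n = 8 samples per product, five stretch modes per sample (strip-y, off-y,
equibiaxial, off-x, strip-x), three stretch-recovery cycles per mode at a
quasi-static 1 %/s rate up to stretch 1.10 (1.25 for prosciutto-style
products), a 30 mN pre-load on both axes preceded by a short slack-removal
ramp, loading/unloading hysteresis, and multiplicative measurement noise.
Forces and gauge lengths are back-computed from the generating energy model
through the Piola definitions, so the raw-processing pipeline round-trips.

Mode couplings (driven stretch s): strip holds the other axis at 1,
equibiaxial sets both to s, and the off modes drive one axis while the
other follows as sqrt(s).

Hysteresis is a symmetric multiplicative split about the elastic curve
(loading x (1+gap), unloading x (1-gap)) so that averaging loading and
unloading recovers the elastic response exactly.  Noise is multiplicative
lognormal by default — stress magnitudes span an order of magnitude across
modes, and additive noise would distort the small-stress modes
disproportionately — with an additive option.

The survey generator plants a monotone latent link between product
stiffness and each texture feature, discretised to the 1..5 scale, plus
questionnaire responses drawn to hit configurable target totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kinematics
from .biaxial_io import (
    MODES,
    BiaxialRecording,
    MeatDataset,
    StretchStressCurve,
    TestProtocol,
    average_mode,
)
from .classical_fits import MooneyRivlinEnergy, NeoHookeEnergy
from .sensory_stats import FEATURES, MEAT_ATTACHMENT, NEOPHOBIA, Instrument, LikertTable

__all__ = [
    "GroundTruthSpec",
    "SurveyLinkSpec",
    "FixturePanel",
    "mode_stretch_path",
    "simulate_biaxial_samples",
    "simulate_sample_curves",
    "samples_to_datasets",
    "make_fixture_panel",
    "simulate_survey",
    "DEFAULT_FEATURE_LINKS",
]


def mode_stretch_path(mode: str, s):
    """Stretch pair (lambda1, lambda2) for driven stretch ``s`` in a mode."""
    s = np.asarray(s, dtype=float)
    one = np.ones_like(s)
    if mode == "strip-x":
        return s, one
    if mode == "strip-y":
        return one, s
    if mode == "equibiax":
        return s, s
    if mode == "off-x":
        return s, np.sqrt(s)
    if mode == "off-y":
        return np.sqrt(s), s
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class GroundTruthSpec:
    """Generating conditions for one product's synthetic biaxial samples.

    Defaults mirror the study conditions: 8 samples, 5 % multiplicative
    noise, 10 % symmetric hysteresis, 0.9 mm slices, the standard protocol.
    """

    energy: kinematics.EnergyModel
    thickness_mm: float = 0.9
    thickness_rel_sd: float = 0.08
    noise_sigma: float = 0.05
    noise_kind: str = "multiplicative"
    hysteresis_gap: float = 0.10
    n_samples: int = 8
    protocol: TestProtocol = field(default_factory=TestProtocol)
    seed: int = 0
    #: reference rake spacing (mm) in x and y
    gauge_mm: tuple[float, float] = (12.0, 12.0)
    #: recording time step, s
    dt: float = 0.25
    #: slack fraction taken up before the pre-load reference
    slack: float = 0.01

    def __post_init__(self):
        if self.noise_sigma < 0 or self.hysteresis_gap < 0:
            raise ValueError("noise_sigma and hysteresis_gap must be >= 0")
        if self.noise_kind not in ("multiplicative", "additive"):
            raise ValueError("noise_kind must be 'multiplicative' or 'additive'")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _noise(rng, sigma, kind, shape, scale=1.0):
    if sigma == 0:
        return np.ones(shape) if kind == "multiplicative" else np.zeros(shape)
    if kind == "multiplicative":
        return np.exp(rng.normal(0.0, sigma, shape))
    return rng.normal(0.0, sigma * scale, shape)


def _apply_noise(P, rng, sigma, kind):
    if kind == "multiplicative":
        return P * _noise(rng, sigma, kind, P.shape)
    return P + _noise(rng, sigma, kind, P.shape, scale=np.max(np.abs(P), initial=1e-9))


def simulate_biaxial_samples(spec: GroundTruthSpec) -> list[dict[str, BiaxialRecording]]:
    """Raw recordings per sample and mode (forces mN, gauges mm).

    Each recording starts with a slack-removal ramp whose forces rise
    linearly to the pre-load, reaching it exactly when the gauges reach the
    reference spacing, followed by the protocol's stretch-recovery cycles.
    """
    rng = np.random.default_rng(spec.seed)
    proto = spec.protocol
    L1, L2 = spec.gauge_mm
    out = []
    for _ in range(spec.n_samples):
        t_mm = spec.thickness_mm * float(
            np.exp(rng.normal(0.0, spec.thickness_rel_sd))
        )
        recs: dict[str, BiaxialRecording] = {}
        for mode in proto.mode_order:
            lam_lead, phase_sign = _cycle_path(proto, spec.dt)
            lam1, lam2 = mode_stretch_path(mode, lam_lead)
            P11, P22 = kinematics.piola_biaxial(spec.energy, lam1, lam2)
            hyst = 1.0 + spec.hysteresis_gap * phase_sign
            P11 = _apply_noise(P11 * hyst, rng, spec.noise_sigma, spec.noise_kind)
            P22 = _apply_noise(P22 * hyst, rng, spec.noise_sigma, spec.noise_kind)
            F1 = P11 * L2 * t_mm + proto.preload
            F2 = P22 * L1 * t_mm + proto.preload
            g1 = lam1 * L1
            g2 = lam2 * L2
            # slack-removal approach ending exactly at the reference state
            if proto.preload > 0 and spec.slack > 0:
                n_app = max(2, int(round(spec.slack / proto.stretch_rate / spec.dt)))
                ramp = np.linspace(1.0 - spec.slack, 1.0, n_app, endpoint=False)
                frac = (ramp - (1.0 - spec.slack)) / spec.slack
                F1 = np.concatenate([frac * proto.preload, F1])
                F2 = np.concatenate([frac * proto.preload, F2])
                g1 = np.concatenate([ramp * L1, g1])
                g2 = np.concatenate([ramp * L2, g2])
            time = np.arange(g1.size) * spec.dt
            recs[mode] = BiaxialRecording(
                time=time,
                force_x=F1,
                force_y=F2,
                gauge_x=g1,
                gauge_y=g2,
                thickness=t_mm,
                mode_label=mode,
            )
        out.append(recs)
    return out


def _cycle_path(proto: TestProtocol, dt: float):
    """Driven stretch over the protocol's cycles, and hysteresis phase signs.

    Signs are +1 on loading and -1 on unloading; the turning point carries
    0 because the hysteresis loop closes at the peak.
    """
    span = proto.max_stretch - 1.0
    n_leg = max(2, int(round(span / proto.stretch_rate / dt)))
    up = np.linspace(1.0, proto.max_stretch, n_leg, endpoint=False)
    down = np.linspace(proto.max_stretch, 1.0, n_leg, endpoint=False)[1:]
    lam, sign = [], []
    for _ in range(proto.cycles):
        lam += [up, [proto.max_stretch], down]
        sign += [np.ones(n_leg), [0.0], -np.ones(n_leg - 1)]
    lam.append(np.array([1.0]))
    sign.append(np.array([-1.0]))
    return np.concatenate(lam), np.concatenate(sign)


def simulate_sample_curves(
    spec: GroundTruthSpec, n_grid: int = 60
) -> list[dict[str, list[tuple[StretchStressCurve, StretchStressCurve]]]]:
    """Per-sample loading/unloading curve pairs, skipping the raw-force layer.

    Equivalent to simulating recordings and extracting the last cycle, but
    directly on stress-stretch curves; used where the raw pipeline itself
    is not under study.  Returns, per sample and mode, the list
    ``[(x, y) loading, (x, y) unloading]``.
    """
    rng = np.random.default_rng(spec.seed)
    proto = spec.protocol
    out = []
    for _ in range(spec.n_samples):
        per_mode: dict[str, list] = {}
        for mode in proto.mode_order:
            s = np.linspace(1.0, proto.max_stretch, n_grid)
            lam1, lam2 = mode_stretch_path(mode, s)
            P11, P22 = kinematics.piola_biaxial(spec.energy, lam1, lam2)
            pairs = []
            for sign in (+1.0, -1.0):
                hyst = 1.0 + spec.hysteresis_gap * sign
                p11 = _apply_noise(P11 * hyst, rng, spec.noise_sigma, spec.noise_kind)
                p22 = _apply_noise(P22 * hyst, rng, spec.noise_sigma, spec.noise_kind)
                pairs.append(
                    (
                        StretchStressCurve(mode, "x", lam1, p11),
                        StretchStressCurve(mode, "y", lam2, p22),
                    )
                )
            per_mode[mode] = pairs
        out.append(per_mode)
    return out


def samples_to_datasets(
    sample_curves, product_id: str = "SYN", n_points: int = 11
) -> tuple[MeatDataset, list[MeatDataset]]:
    """Average loading/unloading pairs into per-sample and mean datasets."""
    per_sample = []
    for i, per_mode in enumerate(sample_curves):
        curves = {}
        for mode, pairs in per_mode.items():
            cx, cy = average_mode(pairs, n_points=n_points)
            curves[mode] = {"x": cx, "y": cy}
        per_sample.append(
            MeatDataset(f"{product_id}-s{i + 1}", curves, n_samples=1)
        )
    mean_curves = {}
    for mode in sample_curves[0]:
        all_pairs = [p for per_mode in sample_curves for p in per_mode[mode]]
        cx, cy = average_mode(all_pairs, n_points=n_points)
        mean_curves[mode] = {"x": cx, "y": cy}
    mean = MeatDataset(product_id, mean_curves, n_samples=len(sample_curves))
    return mean, per_sample


# ---------------------------------------------------------------------------
# eight-product fixture panel


#: Generating models of the synthetic eight-product panel.  Shear moduli
#: follow the plant/animal stiffness ladder of the real products (E from
#: ~380 down to ~50 kPa); the animal-prosciutto analogue is an exact
#: Mooney-Rivlin material so that discovery can be exercised on a product
#: whose true model has both invariant terms.
PANEL_TRUTH = {
    "PT": NeoHookeEnergy(126.1),
    "PH": NeoHookeEnergy(114.4),
    "PD": NeoHookeEnergy(71.06),
    "PP": NeoHookeEnergy(37.50),
    "AT": NeoHookeEnergy(44.66),
    "AC": NeoHookeEnergy(39.09),
    "AH": NeoHookeEnergy(38.88),
    "AP": MooneyRivlinEnergy(7.429, 7.196),
}

_PROSCIUTTO_STYLE = {"PP", "AP"}


@dataclass
class FixturePanel:
    """Synthetic eight-product panel with its generating ground truth."""

    mean_datasets: dict[str, MeatDataset]
    sample_datasets: dict[str, list[MeatDataset]]
    ground_truth: dict[str, kinematics.EnergyModel]
    stiffness_by_product: dict[str, float]
    seed: int


def make_fixture_panel(
    seed: int = 0,
    n_samples: int = 8,
    noise_sigma: float = 0.05,
    hysteresis_gap: float = 0.10,
    n_points: int = 11,
) -> FixturePanel:
    """Generate the eight-product synthetic panel.

    Per-product seeds are spawned from ``seed``; changing the seed changes
    the noise but never the generating parameters.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(PANEL_TRUTH))
    mean_datasets, sample_datasets, stiffness = {}, {}, {}
    for (pid, energy), s in zip(PANEL_TRUTH.items(), seeds):
        proto = TestProtocol(max_stretch=1.25 if pid in _PROSCIUTTO_STYLE else 1.10)
        spec = GroundTruthSpec(
            energy=energy,
            noise_sigma=noise_sigma,
            hysteresis_gap=hysteresis_gap,
            n_samples=n_samples,
            protocol=proto,
            seed=int(s % (2**31)),
        )
        curves = simulate_sample_curves(spec)
        mean, per_sample = samples_to_datasets(curves, product_id=pid, n_points=n_points)
        mean_datasets[pid] = mean
        sample_datasets[pid] = per_sample
        if isinstance(energy, NeoHookeEnergy):
            mu = energy.c1
        else:
            mu = energy.c1 + energy.c2
        stiffness[pid] = 3.0 * mu
    return FixturePanel(mean_datasets, sample_datasets, PANEL_TRUTH.copy(), stiffness, seed)


# ---------------------------------------------------------------------------
# sensory survey generator


#: Latent slope per texture feature against standardised log-stiffness.
#: The brittle link is calibrated so the recovered product-level Spearman
#: correlation with stiffness averages ~0.86 for an 18-participant panel;
#: negative links mimic features that fall with stiffness; zero links give
#: null features for type-I checks.
DEFAULT_FEATURE_LINKS = {
    "soft": -0.6,
    "hard": 0.6,
    "brittle": 1.1,
    "chewy": 0.3,
    "gummy": 0.2,
    "viscous": 0.0,
    "springy": 0.0,
    "sticky": 0.0,
    "fibrous": -0.8,
    "fatty": -1.0,
    "moist": -0.8,
    "meaty": -0.8,
}


@dataclass(frozen=True)
class SurveyLinkSpec:
    """Latent stiffness-to-texture link and panel noise for the generator."""

    feature_links: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_LINKS))
    baseline: float = 3.0
    noise_sd: float = 0.8
    thresholds: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5)
    n_participants: int = 18
    seed: int = 0
    neophobia_target: tuple[float, float] = (24.3, 8.0)
    meat_attachment_target: tuple[float, float] = (48.7, 15.0)

    def __post_init__(self):
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")


def _discretize(latent, thresholds):
    score = np.ones(latent.shape, dtype=int)
    for t in thresholds:
        score += (latent > t).astype(int)
    return score


def _instrument_responses(rng, instrument: Instrument, target: float) -> np.ndarray:
    """Scored item values summing to the (clipped, rounded) target total."""
    lo, hi = instrument.score_range
    total = int(np.clip(round(target), lo, hi))
    items = np.full(instrument.n_items, total // instrument.n_items)
    extra = total - items.sum()
    if extra > 0:
        items[rng.choice(instrument.n_items, size=extra, replace=False)] += 1
    items = np.clip(items, 1, instrument.scale_points)
    # repair any clipping drift
    while items.sum() != total:
        i = rng.integers(instrument.n_items)
        if items.sum() < total and items[i] < instrument.scale_points:
            items[i] += 1
        elif items.sum() > total and items[i] > 1:
            items[i] -= 1
    return items


def simulate_survey(
    link: SurveyLinkSpec, stiffness_by_product: dict[str, float]
) -> tuple[LikertTable, dict[str, pd.DataFrame]]:
    """Likert panel plus questionnaire responses with planted ground truth.

    Latent feature intensity is ``baseline + slope * z`` where ``z`` is the
    product's standardised log-stiffness, plus iid participant noise, then
    discretised through the thresholds.  Questionnaire responses are drawn
    to hit normally-distributed target totals (reverse-keyed items are
    emitted in raw, un-reflected form).
    """
    rng = np.random.default_rng(link.seed)
    products = sorted(stiffness_by_product)
    z = np.log([stiffness_by_product[p] for p in products])
    z = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
    rows = []
    for i, p in enumerate(products):
        for feat in FEATURES:
            slope = link.feature_links.get(feat, 0.0)
            latent = link.baseline + slope * z[i] + rng.normal(
                0.0, link.noise_sd, link.n_participants
            )
            scores = _discretize(latent, link.thresholds)
            for part, sc in enumerate(scores, start=1):
                rows.append((part, p, feat, int(sc)))
    table = LikertTable(
        pd.DataFrame(rows, columns=["participant", "product", "feature", "score"])
    )
    instruments = {}
    for inst, (mean, sd) in (
        (NEOPHOBIA, link.neophobia_target),
        (MEAT_ATTACHMENT, link.meat_attachment_target),
    ):
        recs = []
        for part in range(1, link.n_participants + 1):
            scored = _instrument_responses(rng, inst, rng.normal(mean, sd))
            for item, val in enumerate(scored, start=1):
                raw = inst.scale_points + 1 - val if item in inst.reverse_items else val
                recs.append((part, item, int(raw)))
        instruments[inst.name] = pd.DataFrame(
            recs, columns=["participant", "item", "response"]
        )
    return table, instruments
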