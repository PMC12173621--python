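"""Sensory texture survey statistics.

Covers the scoring of two validated questionnaires (a ten-item, 7-point
food neophobia survey and a sixteen-item, 5-point meat attachment
questionnaire), summary and one-way ANOVA of a twelve-feature, 5-point
Likert texture panel over eight products, and Spearman rank correlation
between physical stiffness and sensory features with an exact permutation
null at small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEATURES",
    "NEOPHOBIA",
    "MEAT_ATTACHMENT",
    "Instrument",
    "LikertTable",
    "CorrelationResult",
    "AnovaResult",
    "score_instrument",
    "summarize_features",
    "feature_anova",
    "spearman",
    "stiffness_texture_correlations",
]

FEATURES = (
    "soft", "hard", "brittle", "chewy", "gummy", "viscous",
    "springy", "sticky", "fibrous", "fatty", "moist", "meaty",
)


@dataclass(frozen=True)
class Instrument:
    """A fixed-length Likert questionnaire with reverse-keyed items.

    Totals are simple sums after reflecting reverse-keyed items
    (x -> scale_points + 1 - x), so they range over
    [n_items, n_items * scale_points].
    """

    name: str
    n_items: int
    scale_points: int
    reverse_items: frozenset[int] = frozenset()

    @property
    def score_range(self) -> tuple[int, int]:
        return (self.n_items, self.n_items * self.scale_points)


#: Ten 7-point items; higher totals = more neophobic (reluctant to try new
#: foods).  The reverse-key set follows the instrument's common scoring and
#: is configuration, not a modelling result.
NEOPHOBIA = Instrument("neophobia", 10, 7, frozenset({1, 4, 6, 9, 10}))

#: Sixteen 5-point items; higher totals = more attached to eating meat.
#: The reverse-keyed items are the negatively-phrased affinity block.
MEAT_ATTACHMENT = Instrument("meat_attachment", 16, 5, frozenset({6, 7, 8, 9}))


def score_instrument(responses: pd.DataFrame, instrument: Instrument) -> pd.Series:
    """Total instrument score per participant.

    ``responses`` is long-format with columns ``participant``, ``item``
    (1-based), ``response``.  Reverse-keyed items are reflected before
    summation; totals are guaranteed inside ``instrument.score_range``.
    """
    df = responses.copy()
    required = {"participant", "item", "response"}
    if not required.issubset(df.columns):
        raise ValueError(f"responses need columns {sorted(required)}")
    bad = ~df["item"].between(1, instrument.n_items)
    if bad.any():
        raise ValueError(
            f"{instrument.name}: item {df['item'][bad].iloc[0]} outside "
            f"1..{instrument.n_items}"
        )
    out_of_scale = ~df["response"].between(1, instrument.scale_points)
    if out_of_scale.any():
        row = df[out_of_scale].iloc[0]
        raise ValueError(
            f"{instrument.name}: participant {row['participant']} item "
            f"{row['item']}: response {row['response']} outside the "
            f"1..{instrument.scale_points} scale"
        )
    counts = df.groupby("participant")["item"].count()
    if (counts != instrument.n_items).any():
        p = counts[counts != instrument.n_items].index[0]
        raise ValueError(
            f"{instrument.name}: participant {p} answered {counts[p]} of "
            f"{instrument.n_items} items"
        )
    rev = df["item"].isin(instrument.reverse_items)
    df.loc[rev, "response"] = instrument.scale_points + 1 - df.loc[rev, "response"]
    return df.groupby("participant")["response"].sum()


@dataclass
class LikertTable:
    """Participant x product x feature integer scores on a 1..5 scale."""

    scores: pd.DataFrame  # long format: participant, product, feature, score
    scale_points: int = 5

    def __post_init__(self):
        required = {"participant", "product", "feature", "score"}
        if not required.issubset(self.scores.columns):
            raise ValueError(f"scores need columns {sorted(required)}")
        s = self.scores["score"]
        if not np.issubdtype(s.dtype, np.integer):
            if not np.allclose(s, s.astype(int)):
                raise ValueError("scores must be integers")
            self.scores = self.scores.assign(score=s.astype(int))
        if not self.scores["score"].between(1, self.scale_points).all():
            raise ValueError(f"scores must lie in 1..{self.scale_points}")

    @property
    def participants(self) -> list:
        return sorted(self.scores["participant"].unique())

    @property
    def products(self) -> list:
        return sorted(self.scores["product"].unique())

    @property
    def features(self) -> list:
        seen = self.scores["feature"].unique()
        return [f for f in FEATURES if f in seen] + sorted(set(seen) - set(FEATURES))

    def feature_scores(self, feature: str) -> dict[str, np.ndarray]:
        """Per-product arrays of participant scores for one feature."""
        sub = self.scores[self.scores["feature"] == feature]
        if sub.empty:
            raise KeyError(f"feature {feature!r} not in table")
        return {p: g["score"].to_numpy() for p, g in sub.groupby("product")}


def summarize_features(table: LikertTable) -> pd.DataFrame:
    """Mean and sample std of each (product, feature) cell.

    Returns a frame indexed by product with a (feature, stat) column
    MultiIndex; products are orderable by mean within each feature.
    """
    if len(table.participants) < 2:
        raise ValueError("need at least two participants to summarise")
    g = table.scores.groupby(["product", "feature"])["score"]
    out = g.agg(["mean", "std"]).unstack("feature")
    out.columns = out.columns.reorder_levels([1, 0])
    order = [f for f in table.features]
    return out.sort_index(axis=1).reindex(
        columns=pd.MultiIndex.from_product([order, ["mean", "std"]])
    )


@dataclass(frozen=True)
class AnovaResult:
    feature: str
    F: float
    p_value: float
    significant: bool
    degenerate: bool = False


def feature_anova(table: LikertTable, feature: str, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of one feature's scores across products.

    Participants are pooled as independent observations (no repeated-
    measures correction), mirroring how such panels are commonly analysed.
    Zero total variance yields an undefined F, reported as not significant
    with ``degenerate=True``.
    """
    groups = list(table.feature_scores(feature).values())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 products with >= 2 scores each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return AnovaResult(feature, float("nan"), float("nan"), False, degenerate=True)
    F, p = stats.f_oneway(*groups)
    return AnovaResult(feature, float(F), float(p), bool(p < alpha))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    method: str  # exact_permutation | t_approximation
    n: int


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    # Pearson on midranks; tie-corrected by construction, and equal to
    # 1 - 6*sum(d^2)/(n(n^2-1)) when there are no ties.
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(np.corrcoef(rx, ry)[0, 1])


from functools import lru_cache


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))))


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by full enumeration of all n! orderings of one variable."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    u = rx - rx.mean()
    w = ry - ry.mean()
    denom = np.sqrt((u @ u) * (w @ w))
    n = len(x)
    perms = _all_permutations(n)
    rhos = (w[perms] @ u) / denom
    hits = int(np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return hits / math.factorial(n)


def spearman(x, y, method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with a small-sample exact p-value.

    rho is the Pearson correlation of midranks.  The two-sided p-value is
    computed by full permutation enumeration for n <= 10 (``method="auto"``
    or ``"exact_permutation"``) and by the t approximation with n - 2
    degrees of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rho = _rank_rho(x, y)
    if method == "auto":
        method = "exact_permutation" if n <= 10 else "t_approximation"
    if method == "exact_permutation":
        if n > 10:
            raise ValueError("exact enumeration limited to n <= 10")
        p = _exact_permutation_p(x, y, rho)
    elif method == "t_approximation":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho=rho, p_value=float(p), method=method, n=n)


def stiffness_texture_correlations(
    stiffness_by_product: dict[str, float],
    feature_summaries: pd.DataFrame,
    significant_features: list[str],
    alpha: float = 0.05,
) -> dict:
    """Pairwise Spearman correlations among stiffness and feature means.

    ``feature_summaries`` is the output of :func:`summarize_features`;
    features are restricted to the ANOVA-significant set.  Correlations use
    the per-product feature means (one point per product).  Returns the rho
    and p matrices plus the list of significant pairs with signs.
    """
    products = sorted(stiffness_by_product)
    missing = set(products) - set(feature_summaries.index)
    if missing:
        raise ValueError(f"products missing from feature summaries: {sorted(missing)}")
    columns = {"stiffness": np.array([stiffness_by_product[p] for p in products])}
    for f in significant_features:
        columns[f] = feature_summaries.loc[products, (f, "mean")].to_numpy()
    names = list(columns)
    k = len(names)
    rho = pd.DataFrame(np.eye(k), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    significant_pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman(columns[names[i]], columns[names[j]])
            rho.iloc[i, j] = rho.iloc[j, i] = res.rho
            pval.iloc[i, j] = pval.iloc[j, i] = res.p_value
            if res.p_value < alpha:
                significant_pairs.append(
                    {
                        "pair": (names[i], names[j]),
                        "rho": res.rho,
                        "p_value": res.p_value,
                        "sign": "positive" if res.rho > 0 else "negative",
                    }
                )
    return {"rho": rho, "p": pval, "significant_pairs": significant_pairs, "n": len(products)}
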