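"""RReliefF feature ranking of RBP-centric features.

Regressional ReliefF estimates, for every feature F, the weight

    W(F) = P(diff F | diff y) P(diff y) / P(diff y)          (near pairs)
         - (1 - P(diff F | diff y)) P(diff F) / (1 - P(diff y))

via the accumulation of Robnik-Sikonja & Kononenko: each sampled
instance contributes its k nearest neighbors, with exponential rank
weights, to three accumulators N_dC (response difference), N_dF[i]
(feature difference) and N_dC&dF[i] (their product); the final weight is

    W[i] = N_dC&dF[i] / N_dC - (N_dF[i] - N_dC&dF[i]) / (m - N_dC).

Distances are Manhattan over min-max-normalized predictors; the diff
function for numeric attributes is |a - b| / range. A feature whose
weight survives shuffling of its own column carries real information
about the response (here: median binding-site conservation per RBP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RbpFeatureTable:
    """Per-RBP feature table: one response column plus numeric predictors."""

    frame: pd.DataFrame
    response: str = "response"

    def __post_init__(self):
        if self.response not in self.frame.columns:
            raise ValueError(f"response column {self.response!r} not in table")
        if len(self.frame) < 2:
            raise ValueError("feature table needs at least 2 rows")
        if self.frame.isna().any().any():
            raise ValueError("feature table must be complete (no missing values)")
        non_numeric = [
            c for c in self.frame.columns
            if not np.issubdtype(self.frame[c].dtype, np.number)
        ]
        if non_numeric:
            raise ValueError(f"non-numeric columns: {non_numeric}")

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.response]

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.frame[self.predictors].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, source, response: str = "response") -> "RbpFeatureTable":
        frame = pd.read_csv(source, sep="\t", index_col=0)
        return cls(frame=frame, response=response)

    def to_tsv(self, dest) -> None:
        self.frame.to_csv(dest, sep="\t", index_label="rbp")


@dataclass
class FeatureWeights:
    weights: dict[str, float]
    rank: list[str]  # features by descending weight
    parameters: dict = field(default_factory=dict)

    def rank_of(self, feature: str) -> int:
        """1-based rank (1 = most important)."""
        return self.rank.index(feature) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.rank,
                "weight": [self.weights[f] for f in self.rank],
                "rank": np.arange(1, len(self.rank) + 1),
            }
        )


def _minmax(x: np.ndarray) -> np.ndarray:
    """Min-max normalize columns; constant columns map to 0."""
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0
    return (x - lo) / span


def rrelieff(
    table: RbpFeatureTable,
    k: int = 10,
    m: Union[int, str] = "all",
    sigma: float = 20.0,
    seed: int = 0,
) -> FeatureWeights:
    """RReliefF attribute importances.

    Parameters
    ----------
    k : number of nearest neighbors per sampled instance (must be below
        the row count; neighbors exclude the instance itself).
    m : number of instances to sample, or "all" for a deterministic
        full sweep in row order.
    sigma : rank-weighting scale; neighbor at rank r contributes
        proportionally to exp(-(r / sigma)**2).
    seed : RNG seed, used only when m != "all".
    """
    n_rows = len(table.frame)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n_rows:
        raise ValueError(f"k ({k}) must be smaller than the row count ({n_rows})")
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    y = table.y
    y_range = y.max() - y.min()
    if y_range == 0:
        raise ValueError("response has zero variance")
    x = _minmax(table.x)
    n_feat = x.shape[1]

    if m == "all":
        sample = np.arange(n_rows)
    else:
        m_int = int(m)
        if not (1 <= m_int <= n_rows):
            raise ValueError(f"m must be in [1, {n_rows}]")
        rng = np.random.default_rng(seed)
        sample = rng.choice(n_rows, size=m_int, replace=False)

    ranks = np.arange(1, k + 1)
    rank_w = np.exp(-((ranks / sigma) ** 2))
    rank_w /= rank_w.sum()

    n_dc = 0.0
    n_df = np.zeros(n_feat)
    n_dcdf = np.zeros(n_feat)
    for r_idx in sample:
        dist = np.abs(x - x[r_idx]).sum(axis=1)
        dist[r_idx] = np.inf  # exclude self
        # stable sort -> ties in distance broken by row order
        neighbors = np.argsort(dist, kind="stable")[:k]
        d_y = np.abs(y[neighbors] - y[r_idx]) / y_range
        d_f = np.abs(x[neighbors] - x[r_idx])  # (k, n_feat), range-normalized
        n_dc += float(d_y @ rank_w)
        n_df += rank_w @ d_f
        n_dcdf += (rank_w * d_y) @ d_f

    m_eff = float(len(sample))
    weights = np.zeros(n_feat)
    nonzero = n_df > 0  # constant columns keep exact weight 0
    if n_dc > 0:
        weights[nonzero] = n_dcdf[nonzero] / n_dc - (
            n_df[nonzero] - n_dcdf[nonzero]
        ) / (m_eff - n_dc)
    names = table.predictors
    wmap = {names[i]: float(weights[i]) for i in range(n_feat)}
    order = sorted(names, key=lambda f: (-wmap[f], f))
    return FeatureWeights(
        weights=wmap,
        rank=order,
        parameters={"k": k, "m": m, "sigma": sigma, "distance": "manhattan"},
    )


def shuffle_robustness(
    table: RbpFeatureTable,
    k: int = 10,
    m: Union[int, str] = "all",
    sigma: float = 20.0,
    n_shuffles: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank stability of each feature under shuffling of its own column.

    Each feature's values are permuted across RBPs ``n_shuffles`` times
    (other columns fixed), RReliefF is re-run, and the feature's new
    rank recorded. A feature is flagged ``rank_critical`` when it
    started outside the bottom third of the ranking but its median
    post-shuffle rank falls into the bottom third: its position depended
    on its actual values, i.e. it carries signal.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    base = rrelieff(table, k=k, m=m, sigma=sigma, seed=seed)
    n_feat = len(base.rank)
    bottom_tier_start = n_feat - int(np.ceil(n_feat / 3)) + 1
    rng = np.random.default_rng(seed)
    rows = []
    for feature in table.predictors:
        shuffled_ranks = []
        for _ in range(n_shuffles):
            frame = table.frame.copy()
            frame[feature] = rng.permutation(frame[feature].to_numpy())
            fw = rrelieff(
                RbpFeatureTable(frame, table.response), k=k, m=m, sigma=sigma, seed=seed
            )
            shuffled_ranks.append(fw.rank_of(feature))
        med = float(np.median(shuffled_ranks))
        orig = base.rank_of(feature)
        rows.append(
            {
                "feature": feature,
                "original_rank": orig,
                "median_shuffled_rank": med,
                "rank_shift": med - orig,
                "rank_critical": bool(
                    orig < bottom_tier_start and med >= bottom_tier_start
                ),
            }
        )
    return pd.DataFrame(rows)


def regress_response_on_feature(
    table: RbpFeatureTable, feature: str
) -> tuple[float, float, float]:
    """OLS simple regression of the response on one feature.

    Returns (slope, intercept, two-sided t-test p for the slope).
    """
    if feature not in table.predictors:
        raise ValueError(f"unknown feature {feature!r}")
    if len(table.frame) < 3:
        raise ValueError("need at least 3 rows for regression")
    x = table.frame[feature].to_numpy(dtype=float)
    if x.max() == x.min():
        raise ValueError(f"feature {feature!r} has zero variance")
    res = stats.linregress(x, table.y)
    return float(res.slope), float(res.intercept), float(res.pvalue)
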