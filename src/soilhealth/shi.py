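"""Soil health index construction.

The index follows the PCA minimum-data-set recipe widely used in soil
quality assessment: standardize the attribute matrix, eigendecompose its
correlation matrix, retain components with eigenvalue >= 1 that explain
> 5% of variance, pick from each retained component the highest-loading
attribute plus any attribute loading within 10% of that maximum, score
each selected indicator onto [0, 1] with a linear scoring function
oriented by agronomic meaning (salinity "less is better", nutrients and
biology "more is better"), weight each indicator by its source
component's share of variance, and sum:

    SHI = sum_i  w_i * s_i

Sorghum- and wheat-season tables are indexed separately; the index is
computed per plot observation and averaged to treatment means afterwards.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ATTRIBUTES

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """An input has no usable variation (constant column, zero variance)."""


@dataclass
class PcaResult:
    """Eigendecomposition of the attribute correlation matrix.

    ``eigenvalues`` descend and sum to the number of attributes;
    ``loadings`` (attribute x PC) are unit-norm eigenvectors with the
    sign fixed so each PC's largest-|loading| entry is positive;
    ``proportions`` are eigenvalue shares of total variance.
    """

    eigenvalues: np.ndarray
    proportions: np.ndarray
    cumulative: np.ndarray
    loadings: pd.DataFrame
    correlation: pd.DataFrame

    @property
    def n_attributes(self) -> int:
        return self.loadings.shape[0]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pc": [f"PC{i+1}" for i in range(len(self.eigenvalues))],
                "eigenvalue": self.eigenvalues,
                "proportion": self.proportions,
                "cumulative": self.cumulative,
            }
        )


@dataclass
class MdsSelection:
    """Minimum-data-set listing: one row per selected indicator with its
    source PC (1-based), loading, and weight."""

    table: pd.DataFrame  # columns: indicator, pc, loading, weight
    retained_pcs: list[int]
    within_frac: float
    eigen_min: float
    var_min: float

    @property
    def indicators(self) -> list[str]:
        return list(self.table["indicator"])

    def weights(self) -> pd.Series:
        return self.table.set_index("indicator")["weight"]


@dataclass
class ScoringSpec:
    """Per-indicator scoring directions and bounds.

    ``directions`` maps indicator -> 'more_is_better' | 'less_is_better'
    | 'optimum'; optimum indicators need a midpoint (None = data median).
    ``variant`` selects min-max scoring (default) or the ratio form
    (x / x_max for more, x_min / x for less).  Bounds default to the
    observed per-table min/max; ``bounds`` overrides per indicator.
    """

    directions: dict[str, str] = field(default_factory=dict)
    optimum_midpoints: dict[str, float | None] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    variant: str = "minmax"

    def direction(self, indicator: str) -> str:
        try:
            return self.directions[indicator]
        except KeyError:
            raise KeyError(f"no scoring direction for {indicator!r}") from None


#: Default orientations: salinity and alkalinity score down, nutrients,
#: organic C, biomass and enzymes score up; the MBC:MBN ratio has no
#: agreed direction and defaults to an optimum at the data median.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "pH_s": "less_is_better",
    "EC_e": "less_is_better",
    "WBOC": "more_is_better",
    "KMnO4_N": "more_is_better",
    "OlsenP": "more_is_better",
    "NH4OAcK": "more_is_better",
    "MBC": "more_is_better",
    "MBN": "more_is_better",
    "MBCN": "optimum",
    "DHA": "more_is_better",
    "AlP": "more_is_better",
    "Ur": "more_is_better",
    "alpha_glu": "more_is_better",
    "beta_glu": "more_is_better",
}


def default_scoring_spec(**overrides: str) -> ScoringSpec:
    d = dict(DEFAULT_DIRECTIONS)
    d.update(overrides)
    return ScoringSpec(directions=d)


def standardize(table: pd.DataFrame, attributes: Sequence[str] = ATTRIBUTES) -> pd.DataFrame:
    """Column-standardize attributes to mean 0, SD 1 (n-1 denominator)."""
    X = table[list(attributes)].astype(float)
    sd = X.std(ddof=1)
    for attr in attributes:
        if not np.isfinite(sd[attr]) or sd[attr] == 0:
            raise DegenerateInputError(f"attribute {attr!r} has zero variance")
    return (X - X.mean()) / sd


def run_pca(z: pd.DataFrame) -> PcaResult:
    """PCA as the eigendecomposition of the sample correlation matrix.

    ``z`` must be a standardized attribute matrix (see :func:`standardize`).
    Eigenvalues are returned in descending order; loadings are unit-norm
    with each PC's largest-|loading| entry made positive so results are
    reproducible across eigensolvers.
    """
    arr = z.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("standardized matrix contains non-finite entries")
    n, p = arr.shape
    if n <= p:
        warnings.warn(
            f"only {n} observations for {p} attributes; PCA will be unstable",
            stacklevel=2,
        )
    corr = arr.T @ arr / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for k in range(p):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    prop = eigval / eigval.sum()
    loadings = pd.DataFrame(
        eigvec, index=list(z.columns), columns=[f"PC{i+1}" for i in range(p)]
    )
    corr_df = pd.DataFrame(corr, index=list(z.columns), columns=list(z.columns))
    return PcaResult(eigval, prop, np.cumsum(prop), loadings, corr_df)


def retain_pcs(
    pca: PcaResult, eigen_min: float = 1.0, var_min: float = 0.05
) -> list[int]:
    """Indices (0-based) of PCs with eigenvalue >= ``eigen_min`` that explain
    more than ``var_min`` of total variance."""
    if eigen_min <= 0 or var_min <= 0:
        raise ValueError("thresholds must be positive")
    kept = [
        k
        for k in range(len(pca.eigenvalues))
        if pca.eigenvalues[k] >= eigen_min and pca.proportions[k] > var_min
    ]
    if not kept:
        logger.warning(
            "no principal component meets eigenvalue >= %.3g and share > %.3g",
            eigen_min, var_min,
        )
    return kept


def select_indicators(
    pca: PcaResult,
    retained: Sequence[int],
    within_frac: float = 0.10,
    redundancy_r: float | None = None,
    eigen_min: float = float("nan"),
    var_min: float = float("nan"),
) -> MdsSelection:
    """Minimum-data-set selection from the retained PCs.

    Per retained PC (in order): take the attribute with the highest
    absolute loading, plus every attribute whose |loading| is within
    ``within_frac`` of that maximum (inclusive, i.e. >= (1 - f) * max;
    ties keep input-attribute order).  Attributes already selected from an
    earlier PC are skipped.  If ``redundancy_r`` is set, co-selected
    attributes within one PC correlated above it are pruned down to the
    highest-|loading| member.
    """
    if len(retained) == 0:
        raise ValueError("no retained PCs to select from")
    attrs = list(pca.loadings.index)
    chosen: list[tuple[str, int, float]] = []
    taken: set[str] = set()
    for k in retained:
        col = pca.loadings.iloc[:, k]
        avail = [a for a in attrs if a not in taken]
        if not avail:
            break
        absl = col.loc[avail].abs()
        top = float(absl.max())
        if top == 0:
            continue
        cands = [a for a in avail if absl[a] >= (1.0 - within_frac) * top]
        if redundancy_r is not None and len(cands) > 1:
            keep = []
            for a in sorted(cands, key=lambda a: -absl[a]):
                if all(
                    abs(pca.correlation.loc[a, b]) <= redundancy_r for b in keep
                ):
                    keep.append(a)
            cands = [a for a in cands if a in keep]
        for a in cands:
            chosen.append((a, k + 1, float(col[a])))
            taken.add(a)
    tab = pd.DataFrame(chosen, columns=["indicator", "pc", "loading"])
    tab["weight"] = np.nan
    return MdsSelection(tab, [k + 1 for k in retained], within_frac,
                        eigen_min, var_min)


def compute_weights(
    pca: PcaResult, selection: MdsSelection, normalize: bool = False
) -> MdsSelection:
    """Assign PC-variance-share weights to the selected indicators.

    Each indicator receives the full weight of its source PC (no
    splitting): ``w = proportion(PC) / cumulative proportion of all
    retained PCs``.  With ``normalize`` the weights are rescaled so they
    sum to 1 over the distinct PCs that actually contributed an indicator.
    """
    if selection.table.empty:
        raise ValueError("empty selection")
    retained0 = [k - 1 for k in selection.retained_pcs]
    cum = float(pca.proportions[retained0].sum())
    tab = selection.table.copy()
    tab["weight"] = [
        float(pca.proportions[pc - 1]) / cum for pc in tab["pc"]
    ]
    if normalize:
        distinct = tab.drop_duplicates("pc")
        total = float(distinct["weight"].sum())
        tab["weight"] /= total
    return replace(selection, table=tab)


def _score_column(x: np.ndarray, direction: str, lo: float, hi: float,
                  midpoint: float | None, variant: str) -> np.ndarray:
    if hi == lo:
        raise DegenerateInputError("scoring bounds coincide (x_max == x_min)")
    if variant == "ratio":
        if direction == "more_is_better":
            if hi == 0:
                raise DegenerateInputError("x_max is zero for ratio scoring")
            return np.clip(x / hi, 0.0, 1.0)
        if direction == "less_is_better":
            with np.errstate(divide="ignore"):
                s = np.where(x > 0, lo / np.where(x > 0, x, 1.0), 1.0)
            return np.clip(s, 0.0, 1.0)
        raise ValueError("ratio variant supports more/less directions only")
    if direction == "more_is_better":
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    if direction == "less_is_better":
        return np.clip((hi - x) / (hi - lo), 0.0, 1.0)
    if direction == "optimum":
        mid = float(np.median(x)) if midpoint is None else float(midpoint)
        s = np.where(
            x <= mid,
            (x - lo) / (mid - lo) if mid > lo else 1.0,
            (hi - x) / (hi - mid) if hi > mid else 1.0,
        )
        return np.clip(s, 0.0, 1.0)
    raise ValueError(f"unknown scoring direction {direction!r}")


def score_indicators(
    table: pd.DataFrame, selection: MdsSelection, spec: ScoringSpec | None = None
) -> pd.DataFrame:
    """Score each selected indicator onto [0, 1] per observation.

    Bounds come from the observed per-table minimum and maximum unless
    the spec configures them; under observed bounds at least one
    observation attains 0 and one attains 1 for each indicator (min-max
    variant, more/less directions).
    """
    spec = spec if spec is not None else default_scoring_spec()
    scores = {}
    for ind in selection.indicators:
        if ind not in table.columns:
            raise KeyError(f"indicator {ind!r} missing from table")
        x = table[ind].to_numpy(dtype=float)
        lo, hi = spec.bounds.get(ind, (float(x.min()), float(x.max())))
        direction = spec.direction(ind)
        mid = spec.optimum_midpoints.get(ind)
        scores[ind] = _score_column(x, direction, lo, hi, mid, spec.variant)
    return pd.DataFrame(scores, index=table.index)


@dataclass
class ShiResult:
    """Per-observation soil health index values with their provenance."""

    values: pd.Series
    selection: MdsSelection
    season: str | None = None

    @property
    def weight_sum(self) -> float:
        return float(self.selection.table["weight"].sum())


def compute_shi(
    scores: pd.DataFrame, selection: MdsSelection, season: str | None = None
) -> ShiResult:
    """Weighted linear index: ``SHI = sum_i w_i * s_i`` per observation."""
    w = selection.weights()
    if w.isna().any():
        raise ValueError("selection has no weights; run compute_weights first")
    missing = [i for i in w.index if i not in scores.columns]
    if missing:
        raise ValueError(f"missing score column(s): {', '.join(missing)}")
    vals = scores[list(w.index)].to_numpy() @ w.to_numpy()
    return ShiResult(pd.Series(vals, index=scores.index, name="SHI"),
                     selection, season)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def shi_yield_regression(shi: pd.Series | ShiResult, yields: pd.Series) -> RegressionResult:
    """Ordinary least squares of yield on SHI; returns slope, intercept,
    R^2 (= 1 - SS_res/SS_tot) and the slope's p-value."""
    x = shi.values if isinstance(shi, ShiResult) else shi
    x = np.asarray(x, dtype=float)
    y = np.asarray(yields, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("SHI has zero variance")
    if np.ptp(y) == 0:
        # flat response: slope 0, nothing explained
        return RegressionResult(0.0, float(y.mean()), 0.0, 1.0, int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2),
        float(res.pvalue), int(x.size),
    )
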