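"""Split-plot factorial ANOVA with two error strata, Tukey HSD compact
letter displays, and LSD interaction comparisons.

The design analysed here is the classic split-factorial layout: tillage
randomized to main plots within blocks, repeated over years, with the
irrigation x mulch factorial randomized to subplots.  Main-plot terms
(replication, year, tillage, year x tillage) are tested against the
whole-plot error "Error (a)" — the pooled block x (year, tillage)
interaction — while every term involving a subplot factor is tested
against the subplot residual "Error (b)".

Sums of squares use the standard balanced-design decomposition
(inclusion-exclusion over marginal cell means); unbalanced tables are a
hard error.  Only fixed effects are fitted — no REML, no type-III.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

WHOLE_PLOT = "whole_plot"
SUBPLOT = "subplot"


class DesignError(ValueError):
    """The design is degenerate or the table does not match it."""


class BalanceError(DesignError):
    """The table is not a complete balanced replicate of the design."""


@dataclass(frozen=True)
class DesignSpec:
    """Level counts of a split-factorial design.

    ``block`` and ``tillage`` index the whole-plot structure (tillage main
    plots within blocks, crossed with years); ``irrigation`` and ``mulch``
    are the subplot factorial.
    """

    n_blocks: int = 3
    n_years: int = 2
    n_tillage: int = 3
    n_irrigation: int = 3
    n_mulch: int = 2

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise DesignError("need >= 2 replications (blocks)")
        for name in ("n_tillage", "n_irrigation", "n_mulch"):
            if getattr(self, name) < 2:
                raise DesignError(f"{name} must be >= 2")
        if self.n_years < 1:
            raise DesignError("n_years must be >= 1")

    @property
    def n_obs(self) -> int:
        return (self.n_blocks * self.n_years * self.n_tillage
                * self.n_irrigation * self.n_mulch)

    @property
    def levels(self) -> dict[str, int]:
        return {
            "block": self.n_blocks,
            "year": self.n_years,
            "tillage": self.n_tillage,
            "irrigation": self.n_irrigation,
            "mulch": self.n_mulch,
        }


def _term_df(term: tuple[str, ...], levels: dict[str, int]) -> int:
    df = 1
    for f in term:
        df *= levels[f] - 1
    return df


def _term_name(term: tuple[str, ...]) -> str:
    names = {"block": "Replication"}
    return " x ".join(names.get(f, f.capitalize()) for f in term)


def design_terms(design: DesignSpec) -> list[tuple[tuple[str, ...], str]]:
    """Ordered (term, stratum) pairs for the split-factorial model.

    Whole-plot terms first (replication, year, tillage, year x tillage),
    then subplot terms in increasing order of the number of subplot
    factors, mirroring the conventional table layout.  Terms with zero
    degrees of freedom (e.g. year terms in a one-year design) are omitted.
    """
    levels = design.levels
    wp_candidates = [("block",), ("year",), ("tillage",), ("year", "tillage")]
    terms = [(t, WHOLE_PLOT) for t in wp_candidates if _term_df(t, levels) > 0]
    sub_order = [
        ("irrigation",), ("mulch",), ("irrigation", "mulch"),
        ("year", "irrigation"), ("tillage", "irrigation"),
        ("year", "tillage", "irrigation"),
        ("year", "mulch"), ("tillage", "mulch"), ("year", "tillage", "mulch"),
        ("year", "irrigation", "mulch"), ("tillage", "irrigation", "mulch"),
        ("year", "tillage", "irrigation", "mulch"),
    ]
    terms += [(t, SUBPLOT) for t in sub_order if _term_df(t, levels) > 0]
    return terms


def build_anova_skeleton(design: DesignSpec) -> pd.DataFrame:
    """Term/df/stratum table for a design, including both error strata.

    Whole-plot error df = (whole-plot units - 1) - sum of whole-plot term
    df; subplot error df is the remainder to N - 1.
    """
    levels = design.levels
    terms = design_terms(design)
    rows = []
    wp_df = sub_df = 0
    for term, stratum in terms:
        df = _term_df(term, levels)
        rows.append((_term_name(term), df, stratum))
        if stratum == WHOLE_PLOT:
            wp_df += df
        else:
            sub_df += df
    n_wp_units = design.n_blocks * design.n_years * design.n_tillage
    err_a = (n_wp_units - 1) - wp_df
    err_b = (design.n_obs - 1) - wp_df - sub_df - err_a
    if err_a < 1:
        raise DesignError(f"whole-plot error has {err_a} df; design degenerate")
    if err_b < 1:
        raise DesignError(f"subplot error has {err_b} df; design degenerate")
    wp_rows = [r for r in rows if r[2] == WHOLE_PLOT]
    sub_rows = [r for r in rows if r[2] == SUBPLOT]
    out = wp_rows + [("Error (a)", err_a, WHOLE_PLOT)] + sub_rows + [
        ("Error (b)", err_b, SUBPLOT)
    ]
    skel = pd.DataFrame(out, columns=["term", "df", "stratum"])
    assert skel["df"].sum() == design.n_obs - 1
    return skel


def _marginal_ss(y: np.ndarray, codes: dict[str, np.ndarray],
                 levels: dict[str, int], term: tuple[str, ...],
                 cache: dict) -> float:
    """Uncorrected sum over the cells of ``term`` of (cell sum)^2 / n_cell."""
    if term in cache:
        return cache[term]
    n = y.size
    if not term:
        val = y.sum() ** 2 / n
    else:
        idx = np.zeros(n, dtype=np.int64)
        ncells = 1
        for f in term:
            idx = idx * levels[f] + codes[f]
            ncells *= levels[f]
        sums = np.bincount(idx, weights=y, minlength=ncells)
        counts = np.bincount(idx, minlength=ncells)
        if counts.min() == 0 or counts.max() != counts.min():
            raise BalanceError(
                f"table is unbalanced over {' x '.join(term)}"
            )
        val = float((sums**2 / counts[0]).sum())
    cache[term] = val
    return val


def _term_ss(y, codes, levels, term, cache) -> float:
    """Balanced-design SS of a term by inclusion-exclusion over subsets."""
    ss = 0.0
    k = len(term)
    for r in range(k + 1):
        for sub in combinations(term, r):
            ss += (-1) ** (k - r) * _marginal_ss(y, codes, levels, sub, cache)
    return ss


def significance_code(p: float) -> str:
    """Star convention: *, **, *** at 0.05/0.01/0.001, NS otherwise."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def fit_split_factorial_anova(
    table: pd.DataFrame,
    response: str,
    design: DesignSpec | None = None,
    season: str | None = None,
) -> pd.DataFrame:
    """Fit the split-factorial ANOVA of ``response`` on a balanced table.

    Returns a table with columns term, df, ss, ms, F, p, stratum, sig.
    F for whole-plot terms uses MS of Error (a); every term involving
    irrigation or mulch uses MS of Error (b).  p-values come from the F
    distribution.  Raises :class:`BalanceError` on unbalanced input.
    """
    df_in = table
    if season is not None:
        df_in = df_in[df_in["season"] == season]
    if response not in df_in.columns:
        raise KeyError(f"unknown response {response!r}")
    sub = df_in.dropna(subset=[response])
    if len(sub) < len(df_in):
        raise BalanceError(f"response {response!r} has missing values")

    factors = ("block", "year", "tillage", "irrigation", "mulch")
    level_values = {f: np.sort(sub[f].unique()) for f in factors}
    if design is None:
        design = DesignSpec(
            n_blocks=len(level_values["block"]),
            n_years=len(level_values["year"]),
            n_tillage=len(level_values["tillage"]),
            n_irrigation=len(level_values["irrigation"]),
            n_mulch=len(level_values["mulch"]),
        )
    levels = design.levels
    for f in factors:
        if len(level_values[f]) != levels[f]:
            raise BalanceError(
                f"factor {f!r} has {len(level_values[f])} levels, design "
                f"expects {levels[f]}"
            )
    if len(sub) != design.n_obs:
        raise BalanceError(
            f"{len(sub)} rows, design expects {design.n_obs}"
        )

    y = sub[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise BalanceError("response contains non-finite values")
    codes = {
        f: np.searchsorted(level_values[f], sub[f].to_numpy())
        for f in factors
    }
    cache: dict = {}
    cf = _marginal_ss(y, codes, levels, (), cache)
    ss_total = float((y**2).sum()) - cf

    terms = design_terms(design)
    rows = []
    ss_wp_terms = 0.0
    ss_sub_terms = 0.0
    df_wp = df_sub = 0
    for term, stratum in terms:
        ss = _term_ss(y, codes, levels, term, cache)
        dfree = _term_df(term, levels)
        rows.append([_term_name(term), dfree, ss, stratum])
        if stratum == WHOLE_PLOT:
            ss_wp_terms += ss
            df_wp += dfree
        else:
            ss_sub_terms += ss
            df_sub += dfree

    # Whole-plot cells are block x year x tillage; error (a) is what the
    # whole-plot terms leave unexplained within that margin.
    ss_wp_cells = (
        _marginal_ss(y, codes, levels, ("block", "year", "tillage"), cache) - cf
    )
    n_wp_units = design.n_blocks * design.n_years * design.n_tillage
    df_err_a = (n_wp_units - 1) - df_wp
    ss_err_a = ss_wp_cells - ss_wp_terms
    df_err_b = (design.n_obs - 1) - df_wp - df_sub - df_err_a
    ss_err_b = ss_total - ss_wp_cells - ss_sub_terms
    if df_err_a < 1 or df_err_b < 1:
        raise DesignError("error stratum with zero degrees of freedom")
    ms_err_a = ss_err_a / df_err_a
    ms_err_b = ss_err_b / df_err_b
    if ms_err_a <= 0 or ms_err_b <= 0:
        raise DesignError("error mean square is not positive")

    out = []
    for name, dfree, ss, stratum in rows:
        ms = ss / dfree
        ms_err, df_err = (
            (ms_err_a, df_err_a) if stratum == WHOLE_PLOT else (ms_err_b, df_err_b)
        )
        f_stat = ms / ms_err
        p = float(stats.f.sf(f_stat, dfree, df_err))
        out.append([name, dfree, ss, ms, f_stat, p, stratum])
    # interleave error rows in display order
    result = []
    for row in out:
        if row[6] == WHOLE_PLOT:
            result.append(row)
    result.append(["Error (a)", df_err_a, ss_err_a, ms_err_a,
                   np.nan, np.nan, WHOLE_PLOT])
    for row in out:
        if row[6] == SUBPLOT:
            result.append(row)
    result.append(["Error (b)", df_err_b, ss_err_b, ms_err_b,
                   np.nan, np.nan, SUBPLOT])
    anova = pd.DataFrame(
        result, columns=["term", "df", "ss", "ms", "F", "p", "stratum"]
    )
    anova["sig"] = anova["p"].map(significance_code)
    return anova


# ---------------------------------------------------------------------------
# Mean separation

from functools import lru_cache


@lru_cache(maxsize=256)
def _q_crit(conf: float, k: int, df: float) -> float:
    """Cached studentized-range quantile (ppf is expensive)."""
    return float(stats.studentized_range.ppf(conf, k, df))


@dataclass
class MeanSeparation:
    """Factor-level means with compact-letter groups.

    ``table`` has columns level, mean, letters (descending mean order);
    levels sharing a letter are not significantly different at ``alpha``.
    """

    table: pd.DataFrame
    alpha: float
    ms_error: float
    df_error: float
    critical_difference: float
    n_per_level: int = 0
    method: str = "tukey_hsd"

    @property
    def se_mean(self) -> float:
        """Standard error of a level mean, sqrt(MS_error / n)."""
        if self.n_per_level <= 0:
            return float("nan")
        return float(np.sqrt(self.ms_error / self.n_per_level))

    def letters(self) -> dict[str, str]:
        return dict(zip(self.table["level"], self.table["letters"]))


def _compact_letters(names: list, sig_pairs: set[frozenset]) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``names`` are level names sorted by descending mean; ``sig_pairs``
    the significantly different pairs.  Returns one letter string per
    name, uppercase letters assigned in descending-mean order.
    """
    cols: list[set] = [set(names)]
    for pair in sorted(sig_pairs, key=sorted):
        a, b = sorted(pair)
        for col in [c for c in cols if a in c and b in c]:
            cols.remove(col)
            for new in (col - {b}, col - {a}):
                # absorb: keep only if not contained in an existing column
                if new and not any(new <= other for other in cols):
                    cols.append(new)
                    cols = [c for c in cols if not (c is not new and c < new)]
    uniq: list[set] = []
    for c in cols:
        if c not in uniq:
            uniq.append(c)
    order = {n: i for i, n in enumerate(names)}
    uniq.sort(key=lambda c: min(order[n] for n in c))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = []
    for n in names:
        out.append("".join(alphabet[i] for i, c in enumerate(uniq) if n in c))
    return out


def tukey_hsd(
    means: pd.Series | dict,
    ms_error: float,
    df_error: float,
    n_per_level: int,
    alpha: float = 0.05,
) -> MeanSeparation:
    """Tukey honestly-significant-difference separation of level means.

    ``HSD = q(1-alpha; k, df_error) * sqrt(ms_error / n_per_level)``; any
    pair of means further apart than HSD receives different letters.
    ``means`` must be the per-level means of a balanced factor with
    ``n_per_level`` observations behind each mean and ``ms_error`` the
    mean square of the appropriate error stratum.
    """
    m = pd.Series(means, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite means")
    if not (np.isfinite(ms_error) and ms_error > 0):
        raise ValueError("ms_error must be positive and finite")
    if df_error < 1 or n_per_level < 2:
        raise ValueError("df_error must be >= 1 and n_per_level >= 2")
    k = len(m)
    if k < 2:
        hsd = np.inf
    else:
        q = _q_crit(round(1 - alpha, 12), k, float(df_error))
        hsd = float(q * np.sqrt(ms_error / n_per_level))
    order = m.sort_values(ascending=False)
    names = list(order.index)
    sig = {
        frozenset((a, b))
        for a, b in combinations(names, 2)
        if abs(order[a] - order[b]) > hsd
    }
    letters = _compact_letters(names, sig)
    tab = pd.DataFrame(
        {"level": names, "mean": order.to_numpy(), "letters": letters}
    )
    return MeanSeparation(tab, alpha, float(ms_error), float(df_error), hsd,
                          int(n_per_level))


def lsd_interaction(
    cell_means: pd.Series | dict,
    ms_error: float,
    df_error: float,
    n_per_cell: int,
    alpha: float = 0.05,
) -> dict:
    """Fisher LSD comparison of interaction cell means.

    ``LSD = t(1-alpha/2; df_error) * sqrt(2 * ms_error / n_per_cell)``;
    returns ``{"lsd": value, "significant": boolean DataFrame}`` with a
    symmetric pairwise significance matrix.
    """
    m = pd.Series(cell_means, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite cell means")
    if not (np.isfinite(ms_error) and ms_error > 0):
        raise ValueError("ms_error must be positive and finite")
    if df_error < 1 or n_per_cell < 2:
        raise ValueError("df_error must be >= 1 and n_per_cell >= 2")
    t = stats.t.ppf(1 - alpha / 2, df_error)
    lsd = float(t * np.sqrt(2.0 * ms_error / n_per_cell))
    diff = np.abs(m.to_numpy()[:, None] - m.to_numpy()[None, :])
    sig = pd.DataFrame(diff > lsd, index=m.index, columns=m.index)
    np.fill_diagonal(sig.values, False)
    return {"lsd": lsd, "significant": sig}


def factor_separation(
    table: pd.DataFrame,
    response: str,
    factor: str,
    anova: pd.DataFrame,
    design: DesignSpec,
    alpha: float = 0.05,
    season: str | None = None,
) -> MeanSeparation:
    """Tukey separation of a design factor's means from a fitted ANOVA.

    Uses the stratum-appropriate error mean square: Error (a) for
    whole-plot factors (year, tillage), Error (b) for irrigation/mulch.
    ``n_per_level`` counts all observations behind each level mean.
    """
    from .data import treatment_means

    stratum = WHOLE_PLOT if factor in ("block", "year", "tillage") else SUBPLOT
    err_name = "Error (a)" if stratum == WHOLE_PLOT else "Error (b)"
    err = anova.loc[anova["term"] == err_name].iloc[0]
    means = treatment_means(table, response, factor, season)
    n_total = design.n_obs
    n_per_level = n_total // len(means)
    return tukey_hsd(means, err["ms"], err["df"], n_per_level, alpha)
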