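"""Trial-table containers, I/O, validation and laboratory conversions.

A trial table is a tidy :class:`pandas.DataFrame` with one row per
plot x year x season observation from a split-plot factorial trial:
tillage on main plots, an irrigation x mulch factorial on subplots,
replicated in blocks over years.  Columns are the design factors
(:data:`DESIGN_COLUMNS`), fourteen soil chemical/biological attributes
(:data:`ATTRIBUTES`) and season-specific yields (:data:`YIELD_COLUMNS`).

All downstream stages (ANOVA, PCA, index construction) consume tables
validated by :func:`validate_trial_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS: tuple[str, ...] = ("sorghum", "wheat")
TILLAGE_LEVELS: tuple[str, ...] = ("CT", "RT", "ZT")
IRRIGATION_LEVELS: tuple[str, ...] = ("CWR100", "CWR80", "CWR60")
MULCH_LEVELS: tuple[str, ...] = ("none", "mulch")

#: Soil attributes in canonical order. pH_s/EC_e are saturation-paste
#: chemistry, WBOC is oxidizable organic C (g kg-1), KMnO4_N/OlsenP/NH4OAcK
#: are available N/P/K (kg ha-1), MBC/MBN microbial biomass C/N, MBCN their
#: ratio, and the last five are enzyme activities in assay units.
ATTRIBUTES: tuple[str, ...] = (
    "pH_s", "EC_e", "WBOC", "KMnO4_N", "OlsenP", "NH4OAcK",
    "MBC", "MBN", "MBCN", "DHA", "AlP", "Ur", "alpha_glu", "beta_glu",
)

#: Yield columns by season (Mg ha-1): sorghum green/dry fodder, wheat
#: grain/straw.  A validated table carries yields only for its own season.
YIELD_COLUMNS: dict[str, tuple[str, ...]] = {
    "sorghum": ("gfy", "dfy"),
    "wheat": ("grain", "straw"),
}
ALL_YIELDS: tuple[str, ...] = ("gfy", "dfy", "grain", "straw")

DESIGN_COLUMNS: tuple[str, ...] = (
    "block", "year", "season", "tillage", "irrigation", "mulch",
)

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "season": SEASONS,
    "tillage": TILLAGE_LEVELS,
    "irrigation": IRRIGATION_LEVELS,
    "mulch": MULCH_LEVELS,
}

#: Attributes constrained to be non-negative on physical grounds.
NONNEGATIVE_ATTRIBUTES: tuple[str, ...] = (
    "EC_e", "WBOC", "KMnO4_N", "OlsenP", "NH4OAcK",
    "MBC", "MBN", "MBCN", "DHA", "AlP", "Ur", "alpha_glu", "beta_glu",
)


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class IntegrityError(ValueError):
    """Table contents violate a trial-table invariant."""


class DomainError(ValueError):
    """A scalar input is outside its physical domain."""


@dataclass(frozen=True)
class LabCalibration:
    """Chloroform fumigation-extraction calibration.

    ``k_ec`` is the extraction-efficiency factor relating the measured
    C (or N) flush to microbial biomass; the standard value is 0.38.
    """

    k_ec: float = 0.38

    def __post_init__(self) -> None:
        if not (0.0 < self.k_ec <= 1.0):
            raise DomainError(f"k_ec must be in (0, 1], got {self.k_ec}")


def mbc_from_flush(c_flush, calib: LabCalibration = LabCalibration()):
    """Microbial biomass C from the fumigation C flush: ``c_flush / k_ec``.

    Accepts scalars or arrays; the flush (fumigated minus non-fumigated
    extractable C) must be non-negative.
    """
    arr = np.asarray(c_flush, dtype=float)
    if np.any(arr < 0):
        raise DomainError("C flush must be non-negative")
    out = arr / calib.k_ec
    return float(out) if np.isscalar(c_flush) or arr.ndim == 0 else out


def mbn_from_flush(n_diff, calib: LabCalibration = LabCalibration()):
    """Microbial biomass N from the fumigated-minus-nonfumigated N difference."""
    arr = np.asarray(n_diff, dtype=float)
    if np.any(arr < 0):
        raise DomainError("N difference must be non-negative")
    out = arr / calib.k_ec
    return float(out) if np.isscalar(n_diff) or arr.ndim == 0 else out


def _canonicalise_factor(series: pd.Series, column: str) -> pd.Series:
    levels = FACTOR_LEVELS[column]
    lookup = {lv.lower(): lv for lv in levels}
    out = series.astype(str).str.strip().str.lower().map(lookup)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise SchemaError(
            f"column {column!r}: value {bad!r} is not one of {levels}"
        )
    return out


def validate_trial_table(
    table: pd.DataFrame,
    *,
    require_balanced: bool = True,
    drop_incomplete: bool = False,
    mbcn_tol: float = 0.01,
) -> pd.DataFrame:
    """Return a validated, canonically ordered copy of a trial table.

    Checks performed:

    * all design columns present; factor levels parsed case-insensitively;
    * ``block``/``year`` integer labels;
    * attribute columns numeric with no missing values (``drop_incomplete``
      drops incomplete rows with a logged warning instead of raising);
    * non-negativity of EC_e, biomass, enzyme and yield columns;
    * the design key (block, year, season, tillage, irrigation, mulch) is
      unique, and — when ``require_balanced`` — every factor combination
      occurs exactly once per season;
    * yields belong to the row's season (the other season's yields are null);
    * MBCN equals MBC/MBN within ``mbcn_tol`` relative tolerance wherever a
      value was supplied; MBCN is (re)computed from MBC/MBN.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing design column(s): {', '.join(missing)}")
    missing = [c for c in ATTRIBUTES if c not in table.columns and c != "MBCN"]
    if missing:
        raise SchemaError(f"missing attribute column(s): {', '.join(missing)}")

    df = table.copy()
    for col in ("season", "tillage", "irrigation", "mulch"):
        df[col] = _canonicalise_factor(df[col], col)
    for col in ("block", "year"):
        try:
            df[col] = pd.to_numeric(df[col], downcast=None).astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not integer-valued") from exc

    numeric_cols = [c for c in (*ATTRIBUTES, *ALL_YIELDS) if c in df.columns]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"unparseable value in column {col!r}, row {row}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = coerced

    attr_cols = [c for c in ATTRIBUTES if c in df.columns and c != "MBCN"]
    incomplete = df[attr_cols].isna().any(axis=1)
    if incomplete.any():
        if drop_incomplete:
            logger.warning("dropping %d incomplete row(s)", int(incomplete.sum()))
            df = df.loc[~incomplete].reset_index(drop=True)
        else:
            raise IntegrityError(
                f"{int(incomplete.sum())} row(s) have missing attribute values "
                "(pass drop_incomplete=True to drop them)"
            )

    for col in NONNEGATIVE_ATTRIBUTES + ALL_YIELDS:
        if col in df.columns and (df[col].dropna() < 0).any():
            raise IntegrityError(f"column {col!r} contains negative values")

    # Yields must match the row's season.
    for season, own in YIELD_COLUMNS.items():
        other = [y for y in ALL_YIELDS if y not in own]
        mask = df["season"] == season
        for y in other:
            if y in df.columns and df.loc[mask, y].notna().any():
                raise IntegrityError(
                    f"{y!r} yields present on {season} rows"
                )

    # MBC:MBN ratio: recompute, cross-check any supplied column.
    if "MBN" in df.columns and (df["MBN"] <= 0).any():
        raise IntegrityError("MBN must be positive to form the MBC:MBN ratio")
    ratio = df["MBC"] / df["MBN"]
    if "MBCN" in df.columns and df["MBCN"].notna().any():
        supplied = df["MBCN"]
        rel = np.abs(supplied - ratio) / np.abs(ratio)
        if (rel.dropna() > mbcn_tol).any():
            row = int(np.flatnonzero((rel > mbcn_tol).fillna(False).to_numpy())[0])
            raise IntegrityError(
                f"MBCN at row {row} ({supplied.iloc[row]:.4g}) disagrees with "
                f"MBC/MBN ({ratio.iloc[row]:.4g}) beyond {mbcn_tol:.0%}"
            )
    df["MBCN"] = ratio

    key = list(DESIGN_COLUMNS)
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        raise IntegrityError(f"duplicated design key: {first}")

    if require_balanced:
        for season, sub in df.groupby("season", observed=True):
            n_expect = (
                sub["block"].nunique() * sub["year"].nunique()
                * sub["tillage"].nunique() * sub["irrigation"].nunique()
                * sub["mulch"].nunique()
            )
            if len(sub) != n_expect:
                raise IntegrityError(
                    f"season {season!r}: {len(sub)} rows but the full factor "
                    f"cross requires {n_expect}"
                )

    order = [c for c in (*DESIGN_COLUMNS, *ATTRIBUTES, *ALL_YIELDS) if c in df.columns]
    extra = [c for c in df.columns if c not in order]
    return df[order + extra].reset_index(drop=True)


def read_trial_table(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    require_balanced: bool = True,
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Read a delimited trial table (comma default, tab accepted) and validate.

    ``schema`` maps canonical column names to the names used in the file,
    e.g. ``{"EC_e": "ECe_dSm"}``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if schema:
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise SchemaError(
                f"file is missing mapped column(s): {', '.join(missing)}"
            )
        df = df.rename(columns={src: dst for dst, src in schema.items()})
    return validate_trial_table(
        df, require_balanced=require_balanced, drop_incomplete=drop_incomplete
    )


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV; nulls become empty cells.

    Floats are written at full repr precision so that
    ``read_trial_table(write_trial_table(t))`` round-trips exactly.
    """
    table.to_csv(path, index=False, encoding="utf-8")


def treatment_means(
    table: pd.DataFrame,
    response: str,
    factor: str,
    season: str | None = None,
) -> pd.Series:
    """Mean of ``response`` per level of ``factor``, averaged over every
    other design dimension (blocks, years, the remaining factors).

    Level order follows the factor definition.  ``season`` filters to one
    season first; it is required whenever the response is season-specific.
    """
    if response not in table.columns:
        raise KeyError(f"unknown response {response!r}")
    if factor not in FACTOR_LEVELS and factor not in ("block", "year"):
        raise KeyError(f"unknown design factor {factor!r}")
    df = table
    if season is not None:
        if season not in SEASONS:
            raise KeyError(f"unknown season {season!r}")
        df = df[df["season"] == season]
    means = df.groupby(factor, observed=True)[response].mean()
    if factor in FACTOR_LEVELS:
        present = [lv for lv in FACTOR_LEVELS[factor] if lv in means.index]
        means = means.reindex(present)
    else:
        means = means.sort_index()
    means.name = response
    return means


def mean_difference(mean_a: float, mean_b: float) -> float:
    """Signed difference ``mean_a - mean_b`` between two treatment means."""
    a, b = float(mean_a), float(mean_b)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise DomainError("means must be finite")
    return a - b


def percent_change(mean_new: float, mean_ref: float) -> float:
    """Percent change of ``mean_new`` relative to ``mean_ref`` (x100)."""
    new, ref = float(mean_new), float(mean_ref)
    if ref == 0:
        raise DomainError("reference mean must be nonzero")
    return 100.0 * (new - ref) / ref
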