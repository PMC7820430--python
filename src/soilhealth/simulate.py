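"""Seeded generator of synthetic split-plot factorial saline-irrigation trials.

The generator emulates a two-year sorghum-wheat trial on a saline field:
3 tillage main plots (CT/RT/ZT) x 3 saline-irrigation levels (100/80/60%
of wheat crop-water requirement) x 2 mulch levels (0 / 5 Mg ha-1 rice
straw) in 3 blocks, soil sampled after each crop, i.e. 108 observations
per season.  Each attribute is

    value = baseline + block intercept + year shift + sum(factor effects)
            + lambda * sigma * z_latent + sigma * eps

where ``z_latent`` is a single standard-normal latent "plot salinity"
shared by all attributes of an observation.  A positive loading on EC_e
and negative loadings on the microbial attributes produce the negative
salinity-biology correlations the analysis is meant to detect.  Yields
are linear in (attribute - baseline) deviations plus Gaussian noise.

Default baselines and factor effects for the chemical attributes are
anchored to the published two-year treatment means of the reference
trial; residual SDs are back-calculated from the printed standard errors
of means (SD ~ SE_m * sqrt(n)).  Microbial and enzyme attributes, whose
treatment means are only published graphically, use field-plausible
baselines consistent with the reported MBC:MBN range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

from . import data as _data
from .data import (
    ATTRIBUTES,
    IRRIGATION_LEVELS,
    MULCH_LEVELS,
    SEASONS,
    TILLAGE_LEVELS,
    YIELD_COLUMNS,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Synthetic-trial configuration violates an invariant."""


#: Published two-year treatment means (reference trial, Table-style layout):
#: season -> attribute -> factor -> {level: mean}.  These anchor the
#: generator's factor effects and double as printed inputs for derived
#: treatment contrasts.
TABLE1_MEANS: dict[str, dict[str, dict[str, dict[str, float]]]] = {
    "sorghum": {
        "pH_s": {
            "tillage": {"CT": 7.96, "RT": 7.90, "ZT": 7.93},
            "irrigation": {"CWR100": 7.94, "CWR80": 7.95, "CWR60": 7.91},
            "mulch": {"none": 7.92, "mulch": 7.94},
        },
        "EC_e": {
            "tillage": {"CT": 4.79, "RT": 4.54, "ZT": 4.28},
            "irrigation": {"CWR100": 4.97, "CWR80": 4.40, "CWR60": 4.24},
            "mulch": {"none": 4.54, "mulch": 4.53},
        },
        "WBOC": {
            "tillage": {"CT": 3.85, "RT": 3.98, "ZT": 3.99},
            "irrigation": {"CWR100": 3.88, "CWR80": 3.96, "CWR60": 3.99},
            "mulch": {"none": 3.88, "mulch": 4.01},
        },
        "KMnO4_N": {
            "tillage": {"CT": 85.6, "RT": 90.9, "ZT": 86.3},
            "irrigation": {"CWR100": 89.8, "CWR80": 87.2, "CWR60": 85.9},
            "mulch": {"none": 85.2, "mulch": 90.0},
        },
        "OlsenP": {
            "tillage": {"CT": 23.0, "RT": 25.0, "ZT": 22.6},
            "irrigation": {"CWR100": 23.8, "CWR80": 24.0, "CWR60": 22.8},
            "mulch": {"none": 23.2, "mulch": 23.9},
        },
        "NH4OAcK": {
            "tillage": {"CT": 244.4, "RT": 241.3, "ZT": 250.2},
            "irrigation": {"CWR100": 241.8, "CWR80": 240.7, "CWR60": 255.2},
            "mulch": {"none": 241.4, "mulch": 249.3},
        },
    },
    "wheat": {
        "pH_s": {
            "tillage": {"CT": 7.79, "RT": 7.76, "ZT": 7.76},
            "irrigation": {"CWR100": 7.77, "CWR80": 7.78, "CWR60": 7.77},
            "mulch": {"none": 7.77, "mulch": 7.77},
        },
        "EC_e": {
            "tillage": {"CT": 7.90, "RT": 7.83, "ZT": 7.18},
            "irrigation": {"CWR100": 8.23, "CWR80": 7.65, "CWR60": 7.04},
            "mulch": {"none": 7.92, "mulch": 7.35},
        },
        "WBOC": {
            "tillage": {"CT": 4.23, "RT": 4.20, "ZT": 4.44},
            "irrigation": {"CWR100": 4.30, "CWR80": 4.20, "CWR60": 4.37},
            "mulch": {"none": 4.17, "mulch": 4.41},
        },
        "KMnO4_N": {
            "tillage": {"CT": 90.6, "RT": 91.9, "ZT": 91.8},
            "irrigation": {"CWR100": 94.4, "CWR80": 89.9, "CWR60": 90.0},
            "mulch": {"none": 88.1, "mulch": 94.8},
        },
        "OlsenP": {
            "tillage": {"CT": 19.4, "RT": 23.3, "ZT": 21.0},
            "irrigation": {"CWR100": 20.7, "CWR80": 20.0, "CWR60": 23.1},
            "mulch": {"none": 20.6, "mulch": 21.9},
        },
        "NH4OAcK": {
            "tillage": {"CT": 214.4, "RT": 226.2, "ZT": 230.1},
            "irrigation": {"CWR100": 222.2, "CWR80": 220.5, "CWR60": 227.7},
            "mulch": {"none": 218.2, "mulch": 229.3},
        },
    },
}

# Field-plausible baselines for the microbial/enzyme attributes (means only
# published graphically for the reference trial).  MBC/MBN chosen so the
# MBC:MBN ratio sits inside the reported 7.4-8.4 range; glucosidase activity
# higher after wheat, MBC and DHA higher after sorghum.
_BIO_BASELINES = {
    "sorghum": {"MBC": 120.0, "MBN": 14.8, "DHA": 42.0, "AlP": 58.0,
                "Ur": 24.0, "alpha_glu": 8.0, "beta_glu": 16.0},
    "wheat": {"MBC": 102.0, "MBN": 13.2, "DHA": 34.0, "AlP": 52.0,
              "Ur": 22.0, "alpha_glu": 9.0, "beta_glu": 18.0},
}

# Directional treatment effects on the biological attributes (level means as
# deviations to be centred): deficit irrigation and mulch relieve salinity
# stress (higher biomass/enzymes), zero tillage raises MBN, conventional
# tillage raises DHA/AlP after sorghum via incorporated residue.
_BIO_LEVEL_MEANS = {
    "sorghum": {
        "MBC": {"irrigation": {"CWR100": -6.0, "CWR80": 1.0, "CWR60": 5.0}},
        "MBN": {"irrigation": {"CWR100": -0.8, "CWR80": 0.0, "CWR60": 0.8},
                "tillage": {"CT": -0.7, "RT": 0.0, "ZT": 0.7},
                "mulch": {"none": -0.3, "mulch": 0.3}},
        "DHA": {"tillage": {"CT": 3.0, "RT": -1.5, "ZT": -1.5},
                "irrigation": {"CWR100": -1.5, "CWR80": -0.5, "CWR60": 2.0},
                "mulch": {"none": -1.5, "mulch": 1.5}},
        "AlP": {"tillage": {"CT": 4.0, "RT": -2.0, "ZT": -2.0},
                "irrigation": {"CWR100": -2.0, "CWR80": -1.0, "CWR60": 3.0},
                "mulch": {"none": 2.0, "mulch": -2.0}},
        "Ur": {"mulch": {"none": -1.5, "mulch": 1.5}},
        "alpha_glu": {"mulch": {"none": -0.8, "mulch": 0.8}},
        "beta_glu": {"mulch": {"none": -1.2, "mulch": 1.2}},
    },
    "wheat": {
        "MBC": {"irrigation": {"CWR100": -5.0, "CWR80": 0.0, "CWR60": 5.0}},
        "MBN": {"irrigation": {"CWR100": -0.7, "CWR80": 0.0, "CWR60": 0.7},
                "tillage": {"CT": -0.6, "RT": 0.0, "ZT": 0.6}},
        "DHA": {"irrigation": {"CWR100": -1.2, "CWR80": -0.3, "CWR60": 1.5},
                "mulch": {"none": -1.0, "mulch": 1.0}},
        "AlP": {"irrigation": {"CWR100": -1.5, "CWR80": -1.0, "CWR60": 2.5},
                "mulch": {"none": 1.5, "mulch": -1.5}},
        "Ur": {"mulch": {"none": -1.2, "mulch": 1.2}},
        "alpha_glu": {},
        "beta_glu": {},
    },
}

# Residual SDs: chemical attributes back-calculated from printed SE_m values
# (SD ~ SE_m * sqrt(36) for a tillage mean over 36 observations), biological
# attributes at ~10-15% CV.
_RESID_SD = {
    "sorghum": {"pH_s": 0.25, "EC_e": 1.00, "WBOC": 0.60, "KMnO4_N": 9.0,
                "OlsenP": 3.5, "NH4OAcK": 22.0, "MBC": 14.0, "MBN": 1.6,
                "DHA": 6.0, "AlP": 8.0, "Ur": 4.0,
                "alpha_glu": 1.5, "beta_glu": 2.5},
    "wheat": {"pH_s": 0.20, "EC_e": 1.40, "WBOC": 0.70, "KMnO4_N": 9.0,
              "OlsenP": 4.5, "NH4OAcK": 24.0, "MBC": 12.0, "MBN": 1.5,
              "DHA": 5.0, "AlP": 8.0, "Ur": 4.0,
              "alpha_glu": 1.6, "beta_glu": 2.8},
}

# Loadings of each attribute on the latent plot-salinity factor, in residual
# SD units.  Positive for EC_e, negative for the biology; chosen so the
# implied EC_e correlations with MBC/MBN/DHA/beta_glu fall in (-0.6, -0.2).
_SALINITY_LOADINGS = {
    "EC_e": 0.80, "MBC": -0.45, "MBN": -0.50, "DHA": -0.50,
    "beta_glu": -0.45, "Ur": -0.30, "AlP": -0.30, "alpha_glu": -0.15,
}

# Year shifts (deviation of year 1; year 2 is the negative): salinity
# declines and microbial N builds with each crop cycle; wheat Olsen's P and
# grain yield were higher in the second rotation.
_YEAR_SHIFTS = {
    "sorghum": {"EC_e": 0.30, "MBN": -0.5, "DHA": -1.0},
    "wheat": {"EC_e": 0.45, "MBN": -0.5, "OlsenP": -2.8, "grain": -0.13},
}

# Yield model: intercept, linear coefficients on (attribute - baseline),
# residual SD (Mg ha-1).
_YIELD_MODELS = {
    "sorghum": {
        "gfy": (55.0, {"EC_e": -1.8, "MBN": 0.25}, 4.5),
        "dfy": (13.6, {"EC_e": -0.45, "MBN": 0.06}, 1.1),
    },
    "wheat": {
        "grain": (5.9, {"EC_e": -0.20}, 0.45),
        "straw": (8.6, {"EC_e": -0.25}, 0.70),
    },
}

# Direct treatment effects on yields (level means, centred at build time):
# zero tillage penalises wheat grain, mulch helps it.
_YIELD_LEVEL_MEANS = {
    "sorghum": {},
    "wheat": {
        "grain": {"tillage": {"CT": 0.15, "RT": 0.0, "ZT": -0.25},
                  "mulch": {"none": -0.12, "mulch": 0.12}},
        "straw": {"tillage": {"CT": 0.2, "RT": 0.1, "ZT": -0.3}},
    },
}


def _centre(levels: Mapping[str, float]) -> dict[str, float]:
    m = float(np.mean(list(levels.values())))
    return {k: v - m for k, v in levels.items()}


def _default_baselines() -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for season in SEASONS:
        b: dict[str, float] = {}
        for attr, by_factor in TABLE1_MEANS[season].items():
            b[attr] = float(np.mean(list(by_factor["tillage"].values())))
        b.update(_BIO_BASELINES[season])
        out[season] = b
    return out


def _default_effects() -> dict[str, dict[str, dict[str, dict[str, float]]]]:
    """Per-season, per-attribute factor-level effect deviations (sum 0)."""
    out: dict[str, dict[str, dict[str, dict[str, float]]]] = {}
    for season in SEASONS:
        eff: dict[str, dict[str, dict[str, float]]] = {}
        for attr, by_factor in TABLE1_MEANS[season].items():
            eff[attr] = {f: _centre(levels) for f, levels in by_factor.items()}
        for attr, by_factor in _BIO_LEVEL_MEANS[season].items():
            eff.setdefault(attr, {}).update(
                {f: _centre(levels) for f, levels in by_factor.items()}
            )
        for col, by_factor in _YIELD_LEVEL_MEANS[season].items():
            eff[col] = {f: _centre(levels) for f, levels in by_factor.items()}
        out[season] = eff
    return out


@dataclass
class SyntheticConfig:
    """Full parameterisation of the synthetic trial generator.

    Defaults reproduce the reference design: 3 blocks x 2 years x
    3 tillage x 3 irrigation x 2 mulch, 108 rows per season.
    """

    n_blocks: int = 3
    n_years: int = 2
    tillage_levels: tuple[str, ...] = TILLAGE_LEVELS
    irrigation_levels: tuple[str, ...] = IRRIGATION_LEVELS
    mulch_levels: tuple[str, ...] = MULCH_LEVELS
    baselines: dict = field(default_factory=_default_baselines)
    effects: dict = field(default_factory=_default_effects)
    year_shifts: dict = field(default_factory=lambda: {s: dict(_YEAR_SHIFTS[s]) for s in SEASONS})
    resid_sd: dict = field(default_factory=lambda: {s: dict(_RESID_SD[s]) for s in SEASONS})
    salinity_loadings: dict = field(default_factory=lambda: dict(_SALINITY_LOADINGS))
    block_sd_frac: float = 0.3
    yield_models: dict = field(default_factory=lambda: {s: dict(_YIELD_MODELS[s]) for s in SEASONS})
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 2:
            raise ConfigError("need at least 2 blocks")
        if self.n_years < 1:
            raise ConfigError("need at least 1 year")
        for season in SEASONS:
            for attr, sd in self.resid_sd[season].items():
                if not sd > 0:
                    raise ConfigError(f"resid_sd[{season}][{attr}] must be > 0")
            for attr, by_factor in self.effects[season].items():
                for fac, levels in by_factor.items():
                    if abs(sum(levels.values())) > 1e-8 * max(
                        1.0, max(abs(v) for v in levels.values())
                    ):
                        raise ConfigError(
                            f"effects[{season}][{attr}][{fac}] do not sum to 0"
                        )
        for attr, lam in self.salinity_loadings.items():
            if not np.isfinite(lam):
                raise ConfigError(f"non-finite salinity loading for {attr}")
        if self.block_sd_frac < 0:
            raise ConfigError("block_sd_frac must be >= 0")

    def null(self) -> "SyntheticConfig":
        """Copy with every treatment/year effect and coupling zeroed —
        pure noise around the baselines, for type-I-error simulation."""
        import copy

        cfg = copy.deepcopy(self)
        cfg.effects = {s: {} for s in SEASONS}
        cfg.year_shifts = {s: {} for s in SEASONS}
        cfg.salinity_loadings = {}
        cfg.block_sd_frac = 0.0
        cfg.yield_models = {
            s: {y: (m[0], {}, m[2]) for y, m in self.yield_models[s].items()}
            for s in SEASONS
        }
        return cfg


# Attributes that are sampled (MBCN is derived as MBC/MBN afterwards).
_SAMPLED = tuple(a for a in ATTRIBUTES if a != "MBCN")


def generate_trial(config: SyntheticConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate one balanced synthetic trial table (both seasons).

    ``seed`` overrides ``config.rng_seed``.  The same configuration and
    seed always produce an identical table.
    """
    cfg = config if config is not None else SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)

    frames = []
    truncated = 0
    for season in SEASONS:
        design = pd.DataFrame(
            list(
                product(
                    range(1, cfg.n_years + 1),
                    range(1, cfg.n_blocks + 1),
                    cfg.tillage_levels,
                    cfg.irrigation_levels,
                    cfg.mulch_levels,
                )
            ),
            columns=["year", "block", "tillage", "irrigation", "mulch"],
        )
        design.insert(2, "season", season)
        n = len(design)

        block_icpt = rng.normal(
            0.0, cfg.block_sd_frac, size=(cfg.n_blocks, len(_SAMPLED))
        ) if cfg.block_sd_frac > 0 else np.zeros((cfg.n_blocks, len(_SAMPLED)))
        latent = rng.standard_normal(n)
        eps = rng.standard_normal((n, len(_SAMPLED)))

        values = np.empty((n, len(_SAMPLED)))
        effects = cfg.effects.get(season, {})
        shifts = cfg.year_shifts.get(season, {})
        for j, attr in enumerate(_SAMPLED):
            sd = cfg.resid_sd[season][attr]
            lam = cfg.salinity_loadings.get(attr, 0.0)
            col = np.full(n, cfg.baselines[season][attr])
            for fac, levels in effects.get(attr, {}).items():
                col += design[fac].map(levels).to_numpy(dtype=float)
            if attr in shifts and cfg.n_years > 1:
                # deviation of year 1; years alternate sign around 0
                dev = shifts[attr]
                col += np.where(design["year"] == 1, dev, -dev)
            col += block_icpt[design["block"].to_numpy() - 1, j] * sd
            col += lam * sd * latent + sd * eps[:, j]
            values[:, j] = col

        table = pd.concat([design, pd.DataFrame(values, columns=_SAMPLED)], axis=1)
        # clip sampled non-negative attributes at 0 (rare by construction)
        for attr in _SAMPLED:
            if attr in _data.NONNEGATIVE_ATTRIBUTES:
                below = table[attr] < 0
                truncated += int(below.sum())
                table.loc[below, attr] = 0.0
        table["MBCN"] = table["MBC"] / table["MBN"]

        for ycol in YIELD_COLUMNS[season]:
            icpt, coefs, sd = cfg.yield_models[season][ycol]
            y = np.full(n, icpt)
            for attr, c in coefs.items():
                y += c * (table[attr].to_numpy() - cfg.baselines[season][attr])
            for fac, levels in effects.get(ycol, {}).items():
                y += table[fac].map(levels).to_numpy(dtype=float)
            if ycol in shifts and cfg.n_years > 1:
                dev = shifts[ycol]
                y += np.where(table["year"] == 1, dev, -dev)
            y += sd * rng.standard_normal(n)
            table[ycol] = np.clip(y, 0.0, None)
        frames.append(table)

    if truncated:
        logger.warning("truncated %d negative sampled value(s) at 0", truncated)
    out = pd.concat(frames, ignore_index=True)
    return _data.validate_trial_table(out)


def ground_truth(config: SyntheticConfig | None = None) -> dict:
    """Exact design effects and implied residual correlations of a config.

    Returns a dict with the configured per-season effect deviations
    (``effects``), the year shifts, and ``implied_correlations`` — the
    within-cell attribute correlation matrix induced by the latent
    salinity factor, ``r_ab = l_a*l_b / sqrt((1+l_a^2+f^2)(1+l_b^2+f^2))``
    with ``l`` the loadings (SD units) and ``f`` the block-intercept SD
    fraction.
    """
    cfg = config if config is not None else SyntheticConfig()
    cfg.validate()
    lam = np.array([cfg.salinity_loadings.get(a, 0.0) for a in _SAMPLED])
    f2 = cfg.block_sd_frac**2
    denom = np.sqrt(1.0 + lam**2 + f2)
    corr = np.outer(lam, lam) / np.outer(denom, denom)
    np.fill_diagonal(corr, 1.0)
    implied = pd.DataFrame(corr, index=_SAMPLED, columns=_SAMPLED)
    return {
        "effects": {s: {a: {f: dict(v) for f, v in by.items()}
                        for a, by in cfg.effects.get(s, {}).items()}
                    for s in SEASONS},
        "year_shifts": {s: dict(cfg.year_shifts.get(s, {})) for s in SEASONS},
        "implied_correlations": implied,
    }
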