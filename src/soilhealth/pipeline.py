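"""End-to-end run orchestration and report assembly.

``run_pipeline`` ties the stages together — simulate or load a trial
table, validate, fit the split-factorial ANOVA for every response, build
the seasonal soil health indices, separate SHI treatment means, regress
yield on SHI — and writes every intermediate artifact plus a manifest to
an output directory as delimited text.  Two runs with the same config
and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import anova as _anova
from . import data as _data
from . import shi as _shi
from . import simulate as _sim
from .data import ATTRIBUTES, SEASONS, YIELD_COLUMNS

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    When ``input_table`` is None a synthetic trial is generated with
    ``seed`` (and any ``synthetic`` field overrides); otherwise the table
    is read from disk using the optional column ``schema``.
    """

    out_dir: str = "report"
    input_table: str | None = None
    schema: dict | None = None
    seed: int = 0
    seasons: tuple[str, ...] = SEASONS
    alpha: float = 0.05
    eigen_min: float = 1.0
    var_min: float = 0.05
    within_frac: float = 0.10
    redundancy_r: float | None = None
    normalize_weights: bool = False
    scoring_variant: str = "minmax"
    direction_overrides: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.eigen_min <= 0 or not (0 < self.var_min < 1):
            raise ValueError("invalid PC retention thresholds")
        if not (0 <= self.within_frac < 1):
            raise ValueError("within_frac must be in [0, 1)")
        unknown = [s for s in self.seasons if s not in SEASONS]
        if unknown:
            raise ValueError(f"unknown season(s): {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "seasons" in raw:
            raw["seasons"] = tuple(raw["seasons"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seasons"] = list(d["seasons"])
        return d


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def format_treatment_table(
    separations: dict[str, dict[str, _anova.MeanSeparation]],
    responses: list[str],
) -> pd.DataFrame:
    """Assemble a treatment-mean report in the conventional layout.

    One block per design factor: a row per level with "mean^letters"
    entries per response column, followed by an SE_m row for the block.
    """
    rows = []
    for factor, by_resp in separations.items():
        any_sep = next(iter(by_resp.values()), None)
        if any_sep is None:
            continue
        levels = list(any_sep.table["level"])
        # preserve factor-definition order
        if factor in _data.FACTOR_LEVELS:
            levels = [lv for lv in _data.FACTOR_LEVELS[factor] if lv in levels]
        for lv in levels:
            row = {"factor": factor, "level": str(lv)}
            for resp in responses:
                sep = by_resp.get(resp)
                if sep is None:
                    row[resp] = ""
                    continue
                rec = sep.table[sep.table["level"] == lv].iloc[0]
                letters = rec["letters"] if len(sep.table) > 1 else ""
                row[resp] = f"{rec['mean']:.2f}{letters}"
            rows.append(row)
        se_row = {"factor": factor, "level": "SE_m"}
        for resp in responses:
            sep = by_resp.get(resp)
            se_row[resp] = "" if sep is None else _fmt(sep.se_mean)
        rows.append(se_row)
    cols = ["factor", "level"] + list(responses)
    return pd.DataFrame(rows, columns=cols)


def _season_responses(season: str) -> list[str]:
    return list(ATTRIBUTES) + list(YIELD_COLUMNS[season])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of in-memory results keyed by stage/season.  On stage
    failure a ``FAILED`` marker naming the stage is written to the output
    directory and a :class:`PipelineError` is raised; artifacts from
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False, encoding="utf-8")

    try:
        stage = "load"
        if config.input_table is None:
            cfg = _sim.SyntheticConfig(**config.synthetic)
            table = _sim.generate_trial(cfg, seed=config.seed)
            logger.info("simulated %d rows (seed=%d)", len(table), config.seed)
        else:
            table = _data.read_trial_table(config.input_table, config.schema)
            logger.info("loaded %d rows from %s", len(table), config.input_table)
        _write(table, "trial_table.csv")
        results["table"] = table

        for season in config.seasons:
            season_tab = table[table["season"] == season].reset_index(drop=True)
            design = _anova.DesignSpec(
                n_blocks=season_tab["block"].nunique(),
                n_years=season_tab["year"].nunique(),
                n_tillage=season_tab["tillage"].nunique(),
                n_irrigation=season_tab["irrigation"].nunique(),
                n_mulch=season_tab["mulch"].nunique(),
            )
            responses = _season_responses(season)

            stage = f"anova[{season}]"
            full_rows = []
            anovas: dict[str, pd.DataFrame] = {}
            for resp in responses:
                at = _anova.fit_split_factorial_anova(season_tab, resp, design)
                anovas[resp] = at
                at = at.assign(response=resp)
                full_rows.append(at)
            full = pd.concat(full_rows, ignore_index=True)
            _write(full.round(6), f"anova_full_{season}.csv")
            sig = full.pivot(index="term", columns="response", values="sig")
            sig = sig.reindex(index=list(anovas[responses[0]]["term"]),
                              columns=responses).reset_index()
            _write(sig, f"anova_summary_{season}.csv")
            results[f"anova_{season}"] = anovas

            stage = f"letters[{season}]"
            separations: dict[str, dict[str, _anova.MeanSeparation]] = {}
            for factor in ("tillage", "irrigation", "mulch"):
                separations[factor] = {}
                for resp in responses:
                    separations[factor][resp] = _anova.factor_separation(
                        season_tab, resp, factor, anovas[resp], design,
                        config.alpha,
                    )
            report = format_treatment_table(separations, responses)
            _write(report, f"treatment_table_{season}.csv")
            results[f"separations_{season}"] = separations

            stage = f"shi[{season}]"
            z = _shi.standardize(season_tab, ATTRIBUTES)
            pca = _shi.run_pca(z)
            _write(pca.summary().round(6), f"pca_summary_{season}.csv")
            _write(
                pca.loadings.round(6).rename_axis("attribute").reset_index(),
                f"pca_loadings_{season}.csv",
            )
            retained = _shi.retain_pcs(pca, config.eigen_min, config.var_min)
            if not retained:
                (out / f"mds_empty_{season}.txt").write_text(
                    "No principal component met the retention thresholds "
                    f"(eigenvalue >= {config.eigen_min}, share > "
                    f"{config.var_min}); index construction stopped after "
                    "selection.\n",
                    encoding="utf-8",
                )
                results[f"pca_{season}"] = pca
                continue
            selection = _shi.select_indicators(
                pca, retained, config.within_frac, config.redundancy_r,
                eigen_min=config.eigen_min, var_min=config.var_min,
            )
            selection = _shi.compute_weights(pca, selection,
                                             config.normalize_weights)
            _write(selection.table.round(6), f"mds_{season}.csv")
            spec = _shi.default_scoring_spec(**config.direction_overrides)
            spec.variant = config.scoring_variant
            scores = _shi.score_indicators(season_tab, selection, spec)
            shi_res = _shi.compute_shi(scores, selection, season)
            per_plot = pd.concat(
                [season_tab[list(_data.DESIGN_COLUMNS)], scores.round(6),
                 shi_res.values.round(6)],
                axis=1,
            )
            _write(per_plot, f"shi_scores_{season}.csv")
            results[f"pca_{season}"] = pca
            results[f"selection_{season}"] = selection
            results[f"shi_{season}"] = shi_res

            stage = f"shi_anova[{season}]"
            with_shi = season_tab.assign(SHI=shi_res.values)
            shi_anova = _anova.fit_split_factorial_anova(with_shi, "SHI", design)
            _write(shi_anova.round(6), f"shi_anova_{season}.csv")
            shi_seps = {
                factor: {
                    "SHI": _anova.factor_separation(
                        with_shi, "SHI", factor, shi_anova, design, config.alpha
                    )
                }
                for factor in ("tillage", "irrigation", "mulch")
            }
            _write(format_treatment_table(shi_seps, ["SHI"]),
                   f"shi_treatment_table_{season}.csv")
            results[f"shi_anova_{season}"] = shi_anova
            results[f"shi_separations_{season}"] = shi_seps

            stage = f"regression[{season}]"
            ycol = "dfy" if season == "sorghum" else "grain"
            reg = _shi.shi_yield_regression(shi_res, season_tab[ycol])
            _write(
                pd.DataFrame(
                    [{
                        "season": season, "yield": ycol,
                        "slope": round(reg.slope, 6),
                        "intercept": round(reg.intercept, 6),
                        "r_squared": round(reg.r_squared, 6),
                        "p_value": round(reg.p_value, 6),
                        "n": reg.n,
                    }]
                ),
                f"shi_yield_regression_{season}.csv",
            )
            results[f"regression_{season}"] = reg

        stage = "manifest"
        manifest = {
            "package": "soilhealth",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "n_rows": int(len(results["table"])),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n", encoding="utf-8")
        raise PipelineError(f"pipeline failed at stage {stage}: {exc}") from exc
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return results
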