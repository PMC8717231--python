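"""End-to-end orchestration: read -> rates -> baselines -> excess -> reports.

`run_pipeline` composes the library stages on declared input files and writes
tidy CSV outputs plus a JSON run manifest (package/library versions, seed,
record counts, dropped units).  Every stage failure propagates with a
stage-labelled message so the CLI can exit non-zero with context.
"""

from __future__ import annotations

import json
import logging
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, excess, io, rates

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("A", "B")
DEFAULT_PERIODS = ("year", "Q2", "Q3", "Q4")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs and settings for a full run."""

    out_dir: str
    monthly_deaths: str | None = None
    weekly_deaths: str | None = None
    exposures: str | None = None          # needed with weekly input
    covariates: str | None = None
    adjacency: str | None = None
    ref_years: tuple[int, int] = (2015, 2019)
    target_year: int = 2020
    methods: Sequence[str] = DEFAULT_METHODS
    periods: Sequence[str] = DEFAULT_PERIODS
    bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.monthly_deaths is None and self.weekly_deaths is None:
            raise ValueError("either monthly_deaths or weekly_deaths is required")
        if self.weekly_deaths is not None and self.exposures is None:
            raise ValueError("weekly input requires an exposures table")
        if self.ref_years[1] >= self.target_year:
            raise ValueError("reference range must precede the target year")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.update({k: v for k, v in overrides.items() if v is not None})
        if "ref_years" in d:
            d["ref_years"] = tuple(d["ref_years"])
        return cls(**d)

    @property
    def reference_years(self) -> list[int]:
        return list(range(self.ref_years[0], self.ref_years[1] + 1))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


@_stage("read")
def _load_panel(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.monthly_deaths is not None:
        panel = io.read_monthly_panel(cfg.monthly_deaths)
    else:
        weekly = io.read_weekly_series(cfg.weekly_deaths)
        years = cfg.reference_years + [cfg.target_year]
        monthly = io.weekly_to_monthly(weekly, years)
        expo = pd.read_csv(cfg.exposures)
        for col in ("unit_id", "year", "exposure"):
            if col not in expo.columns:
                raise io.SchemaError(f"exposures table missing column {col!r}")
        panel = monthly.merge(expo, on=["unit_id", "year"], how="left")
        if panel["exposure"].isna().any():
            bad = panel.loc[panel["exposure"].isna(), "unit_id"].unique().tolist()
            raise io.CoverageError(f"no exposure for units/years of {bad[:5]}")
        panel = io.validate_panel(panel)
    return panel


def make_quarter_scatter_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """One row per unit with Q2 and Q4 excess, for first- vs second-wave
    scatter plots.  Units missing either quarter are excluded with a warning.
    """
    sub = estimates[estimates["period"].isin(["Q2", "Q4"])]
    wide = sub.pivot_table(
        index="unit_id", columns="period", values="excess_abs", aggfunc="first"
    )
    for q in ("Q2", "Q4"):
        if q not in wide.columns:
            wide[q] = np.nan
    incomplete = wide.index[wide[["Q2", "Q4"]].isna().any(axis=1)].tolist()
    if incomplete:
        warnings.warn(f"units missing a quarter, excluded: {incomplete}", stacklevel=2)
        logger.warning("units missing a quarter, excluded: %s", incomplete)
    wide = wide.dropna(subset=["Q2", "Q4"])
    return (
        wide.reset_index()[["unit_id", "Q2", "Q4"]]
        .rename(columns={"Q2": "q2_excess", "Q4": "q4_excess"})
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``out_dir``.

    Returns a manifest dict (also written as ``run_manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "exmort_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "methods": list(cfg.methods),
        "periods": list(cfg.periods),
        "ref_years": list(cfg.ref_years),
        "target_year": cfg.target_year,
        "bootstrap": cfg.bootstrap,
        "warnings": [],
    }

    panel = _load_panel(cfg)
    all_years = cfg.reference_years + [cfg.target_year]
    before = set(panel["unit_id"])
    panel = io.drop_incomplete_units(panel, all_years)
    dropped = sorted(before - set(panel["unit_id"]))
    if dropped:
        manifest["warnings"].append(f"dropped incomplete units: {dropped}")
    manifest["n_units"] = panel["unit_id"].nunique()
    manifest["n_records"] = len(panel)

    # --- excess estimation (point + bootstrap CI) per unit/method/period
    try:
        estimates = excess.estimate_panel(
            panel,
            methods=cfg.methods,
            target_year=cfg.target_year,
            periods=cfg.periods,
            ref_years=cfg.reference_years,
            B=cfg.bootstrap,
            seed=cfg.seed,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'excess': {exc}") from exc
    estimates.to_csv(out / "excess.csv", index=False)

    # --- rankings on the annual period per method
    rank_frames = []
    if "year" in cfg.periods:
        for method in cfg.methods:
            sub = estimates[
                (estimates["period"] == "year") & (estimates["method"] == method)
            ]
            rank_frames.append(excess.rank_units(sub))
    if rank_frames:
        pd.concat(rank_frames, ignore_index=True).to_csv(
            out / "rankings.csv", index=False
        )

    # --- quarter scatter (first vs second wave) for the last-listed method
    scatter_method = cfg.methods[-1]
    scatter = make_quarter_scatter_table(
        estimates[estimates["method"] == scatter_method]
    )
    scatter.insert(1, "method", scatter_method)
    scatter.to_csv(out / "quarter_scatter.csv", index=False)

    # --- association with reported COVID-19 burden
    if cfg.covariates is not None:
        try:
            cov = io.read_covariates(cfg.covariates)
            cov = io.join_covariates(panel["unit_id"].unique(), cov)
            rows = []
            for method in cfg.methods:
                annual = estimates[
                    (estimates["period"] == "year")
                    & (estimates["method"] == method)
                ].set_index("unit_id")["excess_abs"]
                for covar in ("cases_per_100k", "deaths_per_100k"):
                    res = association.correlate(
                        cov.set_index("unit_id")[covar], annual
                    )
                    rows.append(
                        {
                            "method": method,
                            "covariate": covar,
                            "period": "year",
                            "slope": res.slope,
                            "intercept": res.intercept,
                            "pearson_r": res.pearson_r,
                            "p_value": res.p_value,
                            "n": res.n,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "association.csv", index=False)
        except Exception as exc:
            raise PipelineError(f"stage 'associate': {exc}") from exc

    # --- spatial clusters of excess (per period, last-listed method)
    if cfg.adjacency is not None:
        try:
            w = association.weights_from_adjacency(
                cfg.adjacency, unit_ids=sorted(panel["unit_id"].unique())
            )
            rows = []
            for period in cfg.periods:
                vals = (
                    estimates[
                        (estimates["period"] == period)
                        & (estimates["method"] == scatter_method)
                    ]
                    .set_index("unit_id")["excess_abs"]
                    .loc[w.unit_ids]
                )
                res = association.local_morans_i(
                    vals.to_numpy(), w, permutations=999, seed=cfg.seed
                )
                for uid, li, pp, quad in zip(
                    res.unit_ids, res.local_i, res.pseudo_p, res.quadrant
                ):
                    rows.append(
                        {
                            "unit_id": uid,
                            "period": period,
                            "method": scatter_method,
                            "local_i": li,
                            "pseudo_p": pp,
                            "quadrant": quad,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "local_moran.csv", index=False)
        except Exception as exc:
            raise PipelineError(f"stage 'cluster': {exc}") from exc

    manifest["outputs"] = sorted(p.name for p in out.glob("*.csv"))
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %d units, outputs in %s", manifest["n_units"], out)
    return manifest
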