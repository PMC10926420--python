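"""End-to-end pipeline: simulate, preprocess, fit, compare, and summarise.

The pipeline object ties the stages together behind a single seeded
configuration so a full analysis is reproducible bit-for-bit: identical
config + seed gives identical outputs. Every serialized result carries the
hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import choice as choice_mod
from .compare import LandscapeComparison
from .landscape import LandscapeModel
from .preprocess import prepare_experiment1
from .simulate import (
    Experiment1Design,
    Experiment2Design,
    generate_experiment1,
    generate_experiment2,
)
from .surface import ResponseSurfaceModel, TotalConsumptionModel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of the full analysis run."""

    seed: int = 0
    outdir: str = "results"
    alpha: float = 0.05
    bootstrap_B: int = 0          # 0 disables optimum-region bootstraps
    traits: tuple[str, ...] = ("LS", "LEP", "DEP")
    landscape_grid: int = 60
    run_landscapes: bool = True
    flies_per_cell_exp1: int = 5
    flies_per_cell_exp2: int = 5
    diet_grid_path: str | None = None   # optional external diet grid CSV

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("config.seed: must be a non-negative integer")
        if not 0 < self.alpha < 1:
            raise ValueError("config.alpha: must be in (0, 1)")
        if self.flies_per_cell_exp1 < 1 or self.flies_per_cell_exp2 < 1:
            raise ValueError("config.flies_per_cell_*: must be >= 1")
        bad = [t for t in self.traits if t not in ("LS", "LEP", "DEP")]
        if bad:
            raise ValueError(f"config.traits: unknown traits {bad}")
        if self.diet_grid_path is not None and not Path(self.diet_grid_path).exists():
            raise FileNotFoundError(
                f"config.diet_grid_path: no such file {self.diet_grid_path!r}"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traits"] = list(self.traits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"config: unknown fields {sorted(unknown)}")
        if "traits" in d:
            d = {**d, "traits": tuple(d["traits"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _dump_json(obj: dict, path: Path, config_hash: str) -> None:
    obj = {"config_hash": config_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write results under ``config.outdir``.

    Returns a manifest mapping stage names to output paths. Stage failures
    are logged and their downstream dependents skipped.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash
    manifest: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df2 = df.copy()
        for col in df2.columns:
            if df2[col].map(lambda v: isinstance(v, list)).any():
                df2[col] = df2[col].map(lambda v: ";".join(map(str, v)))
        df2.to_csv(p, index=False, float_format="%.10g")
        manifest[name] = str(p)
        return p

    # --- simulate ----------------------------------------------------------
    d1 = Experiment1Design(seed=config.seed, flies_per_cell=config.flies_per_cell_exp1)
    d2 = Experiment2Design(seed=config.seed + 1, flies_per_cell=config.flies_per_cell_exp2)
    exp1 = generate_experiment1(d1)
    exp2 = generate_experiment2(d2)
    save_df(exp1, "experiment1_flies.csv")
    save_df(exp2, "experiment2_flies.csv")

    # --- preprocess --------------------------------------------------------
    analysis, exclusions = prepare_experiment1(exp1)
    save_df(analysis.drop(columns=["dish_counts"], errors="ignore"), "experiment1_analysis.csv")
    save_df(exclusions, "exclusions.csv")

    # --- per-group response surfaces (coefficient-table-shaped) ------------
    fits = {}
    for (line, sex), grp in analysis.groupby(["line", "sex"], sort=True):
        traits = [t for t in config.traits if sex == "F" or t == "LS"]
        for trait in traits:
            try:
                res = ResponseSurfaceModel(grp, "z" + trait).fit()
                fits[f"{line}_{sex}_{trait}"] = res.to_dict()
            except Exception as e:  # noqa: BLE001 - stage isolation
                logger.error("surface fit %s %s %s failed: %s", line, sex, trait, e)
    _dump_json({"fits": fits}, out / "surface_fits.json", h)
    manifest["surface_fits.json"] = str(out / "surface_fits.json")

    # --- total consumption --------------------------------------------------
    try:
        total = TotalConsumptionModel(analysis).fit()
        _dump_json(total.to_dict(), out / "total_consumption.json", h)
        manifest["total_consumption.json"] = str(out / "total_consumption.json")
    except Exception as e:  # noqa: BLE001
        logger.error("total consumption model failed: %s", e)

    # --- sequential landscape comparisons ----------------------------------
    comparisons = {}
    females = {l: g for l, g in analysis[analysis.sex == "F"].groupby("line")}
    males = {l: g for l, g in analysis[analysis.sex == "M"].groupby("line")}
    jobs = [
        ("CT_vs_US_males_LS", dict(records_a=males["CT"], records_b=males["US"],
                                   trait="LS", group_labels=("CT", "US"))),
        ("CT_vs_US_females_LS", dict(records_a=females["CT"], records_b=females["US"],
                                     trait="LS", group_labels=("CT", "US"))),
        ("CT_females_vs_males_LS", dict(records_a=females["CT"], records_b=males["CT"],
                                        trait="LS", group_labels=("F", "M"))),
        ("US_females_vs_males_LS", dict(records_a=females["US"], records_b=males["US"],
                                        trait="LS", group_labels=("F", "M"))),
        ("CT_females_LS_vs_LEP", dict(records_a=females["CT"], traits=("LS", "LEP"))),
        ("CT_females_LS_vs_DEP", dict(records_a=females["CT"], traits=("LS", "DEP"))),
        ("US_females_LS_vs_LEP", dict(records_a=females["US"], traits=("LS", "LEP"))),
        ("US_females_LS_vs_DEP", dict(records_a=females["US"], traits=("LS", "DEP"))),
    ]
    for name, kw in jobs:
        try:
            comparisons[name] = LandscapeComparison(alpha=config.alpha, **kw).fit().to_dict()
        except Exception as e:  # noqa: BLE001
            logger.error("comparison %s failed: %s", name, e)
    _dump_json({"comparisons": comparisons}, out / "landscape_comparisons.json", h)
    manifest["landscape_comparisons.json"] = str(out / "landscape_comparisons.json")

    # --- thin-plate-spline landscapes and optima ---------------------------
    if config.run_landscapes:
        optima = {}
        for (line, sex), grp in analysis.groupby(["line", "sex"], sort=True):
            try:
                res = LandscapeModel(grp, "LS", grid_size=config.landscape_grid).fit()
                entry = {
                    "optimum_P": res.optimum[0],
                    "optimum_C": res.optimum[1],
                    "optimum_value": res.optimum[2],
                    "lambda": res.lam,
                    "n": len(res.y),
                }
                if config.bootstrap_B >= 200:
                    region = res.optimum_region(
                        B=config.bootstrap_B, alpha=config.alpha, seed=config.seed
                    )
                    entry["region_n_cells"] = int(len(region))
                optima[f"{line}_{sex}_LS"] = entry
            except Exception as e:  # noqa: BLE001
                logger.error("landscape %s %s failed: %s", line, sex, e)
        _dump_json({"optima": optima}, out / "landscape_optima.json", h)
        manifest["landscape_optima.json"] = str(out / "landscape_optima.json")

    # --- dietary choice ------------------------------------------------------
    choice_out: dict = {"random_feeding": {}, "regulated_points": {}, "comparisons": {}}
    for (line, sex, pair), grp in exp2.groupby(["line", "sex", "pair"], sort=True):
        try:
            t = choice_mod.random_feeding_test(grp)
            choice_out["random_feeding"][f"{line}_{sex}_pair{pair}"] = {
                nut: {"mean_diff": float(r.mean_diff), "t": float(r.t), "p": float(r.p)}
                for nut, r in t.iterrows()
            }
        except Exception as e:  # noqa: BLE001
            logger.error("random feeding test %s %s pair %s failed: %s", line, sex, pair, e)
    for line, grp in exp2.groupby("line", sort=True):
        pt = choice_mod.regulated_intake_point(grp)
        choice_out["regulated_points"][line] = {
            "mean_P": pt.mean_P, "mean_C": pt.mean_C, "n": pt.n, "ratio": pt.label,
        }
    try:
        choice_out["comparisons"]["CT_vs_US"] = (
            choice_mod.RegulationModel(exp2, "line").fit().to_dict()
        )
        for line, grp in exp2.groupby("line", sort=True):
            choice_out["comparisons"][f"{line}_female_vs_male"] = (
                choice_mod.RegulationModel(grp, "sex").fit().to_dict()
            )
    except Exception as e:  # noqa: BLE001
        logger.error("regulation comparison failed: %s", e)
    _dump_json(choice_out, out / "choice_regulation.json", h)
    manifest["choice_regulation.json"] = str(out / "choice_regulation.json")

    config.to_yaml(out / "config.yaml")
    manifest["config.yaml"] = str(out / "config.yaml")
    _dump_json({"manifest": manifest}, out / "manifest.json", h)
    return manifest
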