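"""End-to-end pipeline: simulate -> profile -> score -> indicators ->
promotions -> access -> correlate -> report, with a run manifest."""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import accessibility as access_mod
from . import portfolio_indicators as pi
from . import promotion_analysis as promo
from .commitment_scoring import WeightTable, score_frame
from .io import SchemaError, canonical_json, read_csv_checked, sha256_file, sha256_text
from .nutrient_profiling import NOVARules, WHORuleTable, profile_products
from .reporting import render_report
from .stats_linkage import linkage_suite
from .synthetic_data import StudyConfig, generate_study

__all__ = ["PipelineRunner", "StageError", "run_pipeline", "STAGES", "load_config"]

STAGES = (
    "simulate",
    "profile",
    "score",
    "indicators",
    "promotions",
    "access",
    "correlate",
    "report",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path=None, seed: int | None = None, **overrides) -> StudyConfig:
    data = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    if seed is not None:
        data["seed"] = seed
    return StudyConfig.model_validate(data)


class PipelineRunner:
    """Runs stages in dependency order inside ``outdir``.

    Stage outputs are plain CSV; the manifest (written last) records the
    config hash, rule-table versions, per-file checksums, stage timings
    and collected warnings.
    """

    def __init__(
        self,
        config: StudyConfig,
        outdir,
        who_rules: WHORuleTable | None = None,
        nova_rules: NOVARules | None = None,
        weights: WeightTable | None = None,
    ):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.who_rules = who_rules or WHORuleTable.default()
        self.nova_rules = nova_rules or NOVARules.default()
        self.weights = weights or WeightTable.default()
        self.timings: dict[str, float] = {}
        self.warnings: list[str] = []
        self.outputs: list[str] = []

    # -- helpers -----------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _write(self, frame: pd.DataFrame, name: str) -> None:
        frame.to_csv(self._path(name), index=False, lineterminator="\n")
        if name not in self.outputs:
            self.outputs.append(name)

    def _run(self, stage: str, fn) -> None:
        start = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn()
            for w in caught:
                self.warnings.append(f"{stage}: {w.message}")
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise StageError(stage, exc) from exc
        self.timings[stage] = round(time.perf_counter() - start, 4)

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        bundle = generate_study(self.config, who_rules=self.who_rules)
        for path in bundle.write(self.outdir):
            if path.name not in self.outputs:
                self.outputs.append(path.name)

    def profile(self) -> None:
        products = read_csv_checked(
            self._path("products.csv"),
            required_columns=("product_id", "company_id", "who_category"),
        )
        self._write(
            profile_products(products, self.who_rules, self.nova_rules),
            "profile_results.csv",
        )

    def score(self) -> None:
        commitments = read_csv_checked(
            self._path("commitments.csv"),
            required_columns=(
                "company_id", "industry", "stage", "domain",
                "indicator_id", "raw", "max", "applicable",
            ),
        )
        self._write(score_frame(commitments, self.weights), "bia_scores.csv")

    def indicators(self) -> None:
        profiled = read_csv_checked(
            self._path("profile_results.csv"),
            required_columns=("product_id", "company_id", "nutri_class", "nova_group", "permitted"),
        )
        truth = read_csv_checked(
            self._path("truth.csv"), required_columns=("company_id", "industry")
        )
        summaries, flagged = pi.summarize_portfolios(profiled, companies=truth)
        if flagged:
            self.warnings.append(f"indicators: portfolios below minimum size flagged: {flagged}")
        self._write(summaries, "portfolio_summaries.csv")
        aggregates = pd.concat(
            [
                pi.aggregate_industry(summaries, industry)
                for industry in sorted(summaries["industry"].dropna().unique())
            ],
            ignore_index=True,
        )
        self._write(aggregates, "industry_aggregates.csv")

    def promotions(self) -> None:
        flyers = read_csv_checked(
            self._path("flyers.csv"), required_columns=promo.REQUIRED_COLUMNS
        )
        self._write(promo.promotion_table(flyers), "promotion_indicators.csv")

    def access(self) -> None:
        scene = access_mod.load_scene(
            read_csv_checked(self._path("geo_nodes.csv"), ("node_id", "x", "y")),
            read_csv_checked(self._path("geo_edges.csv"), ("u", "v", "length_m")),
            read_csv_checked(self._path("geo_points.csv"), ("kind", "point_id", "node_id")),
        )
        self._write(access_mod.accessibility_table(scene), "accessibility.csv")

    def correlate(self) -> None:
        bia = read_csv_checked(self._path("bia_scores.csv"), ("company_id", "stage", "overall"))
        summaries = read_csv_checked(self._path("portfolio_summaries.csv"), ("company_id",))
        self._write(
            linkage_suite(bia[bia["stage"] == "verified"], summaries), "linkage_results.csv"
        )

    def report(self) -> None:
        bia = read_csv_checked(self._path("bia_scores.csv"), ("company_id", "stage", "overall"))
        summaries = read_csv_checked(self._path("portfolio_summaries.csv"), ("company_id",))
        frame, text = render_report(bia, summaries)
        self._write(frame, "report.csv")
        self._path("report.txt").write_text(text, encoding="utf-8")
        if "report.txt" not in self.outputs:
            self.outputs.append("report.txt")

    # -- orchestration -----------------------------------------------------

    def run(self, stages=STAGES) -> dict:
        for stage in stages:
            self._run(stage, getattr(self, stage))
        manifest = self.manifest()
        with open(self._path("manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest

    def manifest(self) -> dict:
        return {
            "config_hash": sha256_text(canonical_json(self.config.model_dump())),
            "seed": self.config.seed,
            "rule_versions": {
                "who_rules": self.who_rules.version,
                "nova_rules": self.nova_rules.version,
            },
            "outputs": {name: sha256_file(self._path(name)) for name in sorted(self.outputs)},
            "stage_timings_s": self.timings,
            "warnings": self.warnings,
        }


def run_pipeline(config: StudyConfig, outdir, **kwargs) -> dict:
    """Convenience wrapper: run every stage and return the manifest."""
    return PipelineRunner(config, outdir, **kwargs).run()
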