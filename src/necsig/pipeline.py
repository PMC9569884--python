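"""End-to-end orchestration: simulate -> screen -> select -> evaluate -> score.

One :class:`RunConfig` drives the whole analysis.  A single base seed fans
out to per-stage seeds by fixed offsets so each stage is individually
reproducible; rerunning with the same config yields byte-identical output
tables.  Every stage's parameters and output files are recorded in a JSON
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, io, panels, scoring, screening, simulate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_run_config"]

# fixed per-stage seed offsets from the base seed
_STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "parallel_analysis": 1,
    "kmeans": 2,
    "dunnett": 3,
}
_SEED_MODULUS = 2**31


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Either ``pg_path``/``pr_path``/``samples_path`` point at existing
    matrices, or (default) a synthetic cohort is generated from
    ``cohort``.
    """

    out_dir: str | Path = "necsig_run"
    seed: int = 0
    pg_path: str | None = None
    pr_path: str | None = None
    samples_path: str | None = None
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    thresholds: screening.ScreeningThresholds = field(
        default_factory=screening.ScreeningThresholds
    )
    panel_sizes: tuple[int, ...] = (36, 20, 14)
    parallel_iterations: int = 1000

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + _STAGE_SEED_OFFSETS[stage]) % _SEED_MODULUS

    def validate(self) -> None:
        t = self.thresholds
        if not (0 < t.max_missing_fraction < 1):
            raise ValueError("max_missing_fraction must lie in (0, 1)")
        if not (0.5 <= t.auc_min <= 1):
            raise ValueError("auc_min must lie in [0.5, 1]")
        if t.min_precursor_quantified < 0 or t.imputed_zero_class_max < 0:
            raise ValueError("count thresholds must be >= 0")
        if t.redundancy_cap < 1:
            raise ValueError("redundancy_cap must be >= 1")
        sizes = list(self.panel_sizes)
        if any(s % 2 for s in sizes) or sizes != sorted(sizes, reverse=True):
            raise ValueError("panel sizes must be even and descending")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a flat key-value YAML document into a :class:`RunConfig`.

    Keys matching :class:`~necsig.simulate.CohortConfig` or
    :class:`~necsig.screening.ScreeningThresholds` fields are routed there;
    the rest must be RunConfig fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_fields = {f.name for f in dataclasses.fields(simulate.CohortConfig)}
    threshold_fields = {f.name for f in dataclasses.fields(screening.ScreeningThresholds)}
    run_fields = {f.name for f in dataclasses.fields(RunConfig)}
    cohort_kw, threshold_kw, run_kw = {}, {}, {}
    for key, value in raw.items():
        if key in ("cohort", "thresholds"):
            raise ValueError("config must be flat key-value; nesting is not supported")
        if key in threshold_fields:
            threshold_kw[key] = value
        elif key in cohort_fields and key != "seed":
            cohort_kw[key] = value
        elif key in run_fields:
            if key == "panel_sizes":
                value = tuple(
                    int(v) for v in (value.split(",") if isinstance(value, str) else value)
                )
            run_kw[key] = value
        else:
            raise ValueError(f"unknown config key: {key}")
    config = RunConfig(
        cohort=simulate.CohortConfig(**cohort_kw),
        thresholds=screening.ScreeningThresholds(**threshold_kw),
        **run_kw,
    )
    config.cohort.seed = config.stage_seed("simulate")
    return config


def _stage_inputs(config: RunConfig, out: Path):
    """Stage 1: load the cohort from disk or generate and persist one."""
    if config.pg_path is not None:
        samples = io.read_sample_sheet(config.samples_path)
        pg = io.read_pg_matrix(config.pg_path, samples)
        pr = (
            io.read_pr_matrix(config.pr_path, samples, pg)
            if config.pr_path is not None
            else None
        )
        return pg, pr, samples, None
    config.cohort.seed = config.stage_seed("simulate")
    cohort = simulate.generate_cohort(config.cohort)
    simulate.write_cohort(cohort, out, overwrite=True)
    return cohort.pg, cohort.pr, cohort.samples, cohort.truth


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "panel_sizes": list(config.panel_sizes),
        "stages": [],
        "files": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"name": stage, **info})
        logger.info("stage %s done", stage)

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # 1. inputs -------------------------------------------------------------
    pg, pr, samples, truth = run_stage("inputs", lambda: _stage_inputs(config, out))
    source = "synthetic" if config.pg_path is None else "files"
    record("inputs", source=source, n_samples=len(samples), n_proteins=pg.n_groups)
    if source == "synthetic":
        manifest["files"].update(
            {k: str(out / v) for k, v in
             {"pg_matrix": "pg_matrix.tsv", "pr_matrix": "pr_matrix.tsv",
              "samples": "samples.csv", "truth": "truth.tsv"}.items()}
        )

    # 2. screening ----------------------------------------------------------
    stats_list = run_stage(
        "screen", lambda: screening.screen_markers(pg, pr, samples, config.thresholds)
    )
    markers_path = out / "markers.tsv"
    io.write_table(stats_list, markers_path)
    candidates = screening.candidate_set(stats_list)
    record(
        "screen",
        n_tested=len(stats_list),
        n_candidates=len(candidates),
        n_up=sum(s.direction == "up" for s in candidates),
        n_down=sum(s.direction == "down" for s in candidates),
    )
    manifest["files"]["markers"] = str(markers_path)

    # 3. panel selection ----------------------------------------------------
    kept = screening.filter_missingness(pg, config.thresholds.max_missing_fraction)
    values = screening.impute_zeros(kept).to_frame()
    is_case = samples.is_case
    panel_list = run_stage(
        "select",
        lambda: panels.select_nested_panels(
            stats_list, values, is_case, config.panel_sizes
        ),
    )
    panels_path = out / "panels.tsv"
    panels.panels_to_frame(panel_list).to_csv(panels_path, sep="\t", index=False)
    record("select", sizes=[p.size for p in panel_list])
    manifest["files"]["panels"] = str(panels_path)

    # 4. evaluation ---------------------------------------------------------
    def evaluate_panels():
        rows = []
        for panel in panel_list:
            z = evaluate.standardize(values.loc[panel.ids])
            res = evaluate.pca(z)
            res.n_retained_parallel = evaluate.parallel_analysis(
                z,
                n_iterations=config.parallel_iterations,
                seed=config.stage_seed("parallel_analysis"),
            )
            reports = [
                evaluate.pc_regression(res.scores, samples),
                evaluate.hierarchical_two_clusters(z, samples),
                evaluate.kmeans_two_clusters(
                    z, samples, seed=config.stage_seed("kmeans")
                ),
                evaluate.lda_evaluate(z, samples),
            ]
            for rep in reports:
                row = {
                    "panel_size": panel.size,
                    "method": rep.method,
                    "misassigned_total": rep.misassigned_total,
                    "wilks_lambda": rep.wilks_lambda,
                    "chi_square_p": rep.chi_square_p,
                    "pc1_proportion": res.proportion_of_variance[0],
                    "pc2_proportion": res.proportion_of_variance[1],
                    "n_retained_parallel": res.n_retained_parallel,
                }
                row.update(
                    {f"misassigned_{p}": c for p, c in rep.misassigned_by_period.items()}
                )
                rows.append(row)
        return pd.DataFrame(rows)

    eval_frame = run_stage("evaluate", evaluate_panels)
    eval_path = out / "evaluation.tsv"
    eval_frame.to_csv(eval_path, sep="\t", index=False)
    record("evaluate", methods=sorted(eval_frame["method"].unique()))
    manifest["files"]["evaluation"] = str(eval_path)

    # 5. scoring ------------------------------------------------------------
    def score_stage():
        panel = panel_list[0]
        z = evaluate.standardize(values.loc[panel.ids])
        scores = scoring.relative_score(z, panel)
        pair_tests = scoring.paired_t_by_pair(z, panel, samples)
        period = scoring.dunnett_by_period(
            scores["relative_score"], samples, seed=config.stage_seed("dunnett")
        )
        rankit = scoring.rankit_matrix(values.loc[panel.ids])
        return scores, pair_tests, period, rankit

    scores, pair_tests, period, rankit = run_stage("score", score_stage)
    scores_path = out / "scores.tsv"
    scores.rename_axis("sample_id").to_csv(scores_path, sep="\t")
    pair_path = out / "pair_tests.tsv"
    pair_tests.to_csv(pair_path, sep="\t", index=False)
    period_path = out / "period_tests.tsv"
    pd.DataFrame(
        {
            "period": period.periods,
            "adjusted_p": [period.adjusted_p[p] for p in period.periods],
            "group_mean": [period.group_means[p] for p in period.periods],
            "control_mean": period.group_means["control"],
            "f_statistic": period.f_statistic,
            "anova_p": period.anova_p,
        }
    ).to_csv(period_path, sep="\t", index=False)
    rankit_path = out / "rankit.tsv"
    rankit.rename_axis("protein_id").to_csv(rankit_path, sep="\t")
    record("score", panel_size=panel_list[0].size, n_pairs=len(pair_tests))
    manifest["files"].update(
        {
            "scores": str(scores_path),
            "pair_tests": str(pair_path),
            "period_tests": str(period_path),
            "rankit": str(rankit_path),
        }
    )

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["files"]["manifest"] = str(manifest_path)
    return manifest
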