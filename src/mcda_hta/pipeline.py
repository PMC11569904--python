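"""End-to-end pipeline: validate → summarize → weights → score → sensitivity.

One call wires the stages together, writes every table as CSV into an
output directory, and records a run log (package version, config version,
seed, pooling coefficient, rounding policy) so results are reproducible
from the log alone. Any stage failure aborts with the stage name; partial
outputs from the failed run are removed.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .elicitation import read_allocations, summarize_sample
from .reports import distribution_report
from .sensitivity import one_way_weight_sensitivity, probabilistic_sensitivity
from .tree import load_criteria_config, validate_tree
from .value import ScoreSheet, aggregate_value, rank_technologies, results_frame
from .weights import build_weight_table, compare_all_nodes


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    ``scores_path`` is a CSV with columns ``technology_id,node_id,score``;
    ``score_scale`` declares its range. ``sensitivity_node`` switches on a
    one-way sweep over that node; ``psa_draws`` > 0 switches on the
    probabilistic analysis.
    """

    criteria_path: Path
    allocations_path: Path
    out_dir: Path
    scores_path: Optional[Path] = None
    score_scale: tuple[float, float] = (0.0, 1.0)
    lambda_: float = 0.5
    rounding: str = "largest-remainder"
    repair: Optional[str] = None
    sensitivity_node: Optional[str] = None
    sensitivity_grid: tuple[float, ...] = tuple(float(g) for g in range(0, 101, 5))
    psa_draws: int = 0
    seed: int = 0
    report_level: str = "domain"

    def __post_init__(self) -> None:
        self.criteria_path = Path(self.criteria_path)
        self.allocations_path = Path(self.allocations_path)
        self.out_dir = Path(self.out_dir)
        if self.scores_path is not None:
            self.scores_path = Path(self.scores_path)
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lambda_}")
        for p, what in ((self.criteria_path, "criteria config"),
                        (self.allocations_path, "allocations CSV")):
            if not p.exists():
                raise FileNotFoundError(f"{what} not found: {p}")
        if self.scores_path is not None and not self.scores_path.exists():
            raise FileNotFoundError(f"score sheet not found: {self.scores_path}")


def read_score_sheets(
    path: Path, scale: tuple[float, float] = (0.0, 1.0)
) -> list[ScoreSheet]:
    """Read per-technology leaf scores from a long CSV."""
    frame = pd.read_csv(path, dtype={"technology_id": str, "node_id": str})
    required = {"technology_id", "node_id", "score"}
    missing = required.difference(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    sheets = []
    for tech, block in frame.groupby("technology_id", sort=False):
        sheets.append(ScoreSheet(
            technology_id=str(tech),
            scores={nid: float(s) for nid, s in zip(block["node_id"], block["score"])},
            scale=scale,
        ))
    return sheets


def run_full_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the requested stages and write all artifacts under ``cfg.out_dir``.

    Returns a mapping from artifact name to written path. Idempotent: the
    same inputs and seed produce byte-identical tables.
    """
    out = cfg.out_dir
    fresh = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, **kwargs)
        artifacts[name] = path

    try:
        try:
            tree = load_criteria_config(cfg.criteria_path)
            report = validate_tree(tree)
            if not report.ok:
                raise ValueError(str(report))
        except Exception as exc:
            raise PipelineError("validate-tree", exc) from exc

        try:
            allocs, rejections = read_allocations(cfg.allocations_path, tree,
                                                  repair=cfg.repair)
            _write("rejections", rejections, index=False)
        except Exception as exc:
            raise PipelineError("read-allocations", exc) from exc

        try:
            samples = sorted(allocs.samples)
            for sid in samples:
                _write(f"summary_{sid}", summarize_sample(allocs, sid).table)
            _write("distribution_report",
                   distribution_report(allocs, cfg.report_level), index=False)
        except Exception as exc:
            raise PipelineError("summarize", exc) from exc

        try:
            wt = build_weight_table(allocs, lambda_=cfg.lambda_, rounding=cfg.rounding)
            _write("weight_table", wt.table)
            if len(allocs.samples) == 2:
                _write("comparison_tests",
                       compare_all_nodes(allocs, wt.sample_a, wt.sample_b))
        except Exception as exc:
            raise PipelineError("weights", exc) from exc

        sheets = None
        if cfg.scores_path is not None:
            try:
                sheets = read_score_sheets(cfg.scores_path, cfg.score_scale)
                ranked = rank_technologies([aggregate_value(wt, s) for s in sheets])
                _write("values", results_frame(ranked))
            except Exception as exc:
                raise PipelineError("score", exc) from exc

        if cfg.sensitivity_node is not None:
            try:
                if sheets is None:
                    raise ValueError("one-way sensitivity needs a score sheet")
                curve = one_way_weight_sensitivity(
                    wt, sheets, cfg.sensitivity_node, list(cfg.sensitivity_grid))
                _write("one_way_sensitivity", curve.values)
            except Exception as exc:
                raise PipelineError("sensitivity-one-way", exc) from exc

        if cfg.psa_draws > 0:
            try:
                if sheets is None:
                    raise ValueError("probabilistic sensitivity needs a score sheet")
                psa = probabilistic_sensitivity(
                    sheets, n_draws=cfg.psa_draws, seed=cfg.seed,
                    allocs=allocs, lambda_=cfg.lambda_)
                _write("rank_acceptability", psa.rank_fractions)
                _write("value_percentiles", psa.value_stats)
            except Exception as exc:
                raise PipelineError("sensitivity-psa", exc) from exc

        log = {
            "package_version": __version__,
            "criteria_config": {"name": tree.name, "version": tree.version,
                                "path": str(cfg.criteria_path)},
            "allocations": str(cfg.allocations_path),
            "lambda": cfg.lambda_,
            "rounding": cfg.rounding,
            "repair": cfg.repair,
            "seed": cfg.seed,
            "score_scale": list(cfg.score_scale),
            "psa_draws": cfg.psa_draws,
            "broken_sum_groups": list(wt.broken_sum_groups),
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        log_path = out / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2) + "\n", encoding="utf-8")
        artifacts["run_log"] = log_path
        return artifacts
    except PipelineError:
        # remove partial outputs: a half-written bundle is worse than none
        if fresh:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for path in artifacts.values():
                path.unlink(missing_ok=True)
        raise
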