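"""End-to-end analysis runner.

``run_pipeline`` executes the full analysis from a single config:
read (or simulate) the two blocks, covariate-adjust, filter variables,
standardize, select sparsity by grid search, fit the mode, permutation-test
it, compute loading profiles overall and per subgroup, and run the
reliability suite.  Every artifact (TSV tables, JSON summary, config echo,
stage log) lands in one run directory; the config echo plus the seeds in the
summary suffice to reproduce every number bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, inference, reliability, simulate
from .data_io import FeatureTable
from .pmd import fit_scca

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "default_grid"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the artifacts written so far."""

    def __init__(self, stage: str, manifest: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str = "scca_run"
    # either file inputs ...
    behavioral_path: str | None = None
    imaging_path: str | None = None
    id_column: str = "subject_id"
    group_column: str | None = None
    # ... or a synthetic draw
    simulate: dict | None = None
    # pre-analysis transformations
    covariate_column: str | None = None   # column of the imaging table
    covariate_targets: list[str] | None = None
    filter_blocks: list[str] = field(default_factory=lambda: ["behavioral"])
    corr_threshold: float = 0.85
    min_sd: float = 0.0
    # sparsity selection
    grid_x: list[float] | None = None
    grid_y: list[float] | None = None
    grid_points: int = 4
    # inference and reliability
    n_perm: int = 5000
    n_splits: int = 5000
    seed: int = 0
    retune_permutations: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_grid(dim: int, n_points: int = 4) -> list[float]:
    """Evenly spaced L1 bounds from just above 1 to sqrt(dim)."""
    return [float(c) for c in np.linspace(1.1, np.sqrt(dim), n_points)]


def _write_tsv(df: pd.DataFrame, path: Path, manifest: list[str]) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest.append(path.name)


def _load_inputs(cfg: RunConfig) -> tuple[FeatureTable, FeatureTable]:
    if cfg.simulate is not None:
        spec = simulate.SyntheticSpec(**cfg.simulate)
        bx, by, _ = simulate.generate_paired_data(spec)
        return bx, by
    if cfg.behavioral_path is None or cfg.imaging_path is None:
        raise ValueError("config needs either file paths or a simulate block")
    bx = data_io.read_feature_table(
        cfg.behavioral_path, cfg.id_column, cfg.group_column,
        block_label="behavioral")
    by = data_io.read_feature_table(
        cfg.imaging_path, cfg.id_column, cfg.group_column,
        block_label="imaging")
    return bx, by


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and return the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    log_lines: list[str] = []
    t0 = time.perf_counter()

    def log(stage: str) -> None:
        log_lines.append(f"{stage}: done at +{time.perf_counter() - t0:.2f}s")

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    manifest.append("config.yaml")

    stage = "load"
    try:
        behavioral, imaging = _load_inputs(cfg)
        log(stage)

        stage = "covariate_adjust"
        if cfg.covariate_column is not None:
            cov_idx = imaging.variable_names.index(cfg.covariate_column)
            covariate = imaging.values[:, cov_idx]
            targets = cfg.covariate_targets
            keep = [v for v in imaging.variable_names
                    if v != cfg.covariate_column]
            imaging = imaging.select(keep)
            imaging = data_io.covariate_adjust(imaging, covariate, targets)
        log(stage)

        stage = "filter_variables"
        logs = []
        if "behavioral" in cfg.filter_blocks:
            behavioral, flog = data_io.filter_variables(
                behavioral, cfg.corr_threshold, cfg.min_sd)
            logs.extend(flog)
        if "imaging" in cfg.filter_blocks:
            imaging, flog = data_io.filter_variables(
                imaging, cfg.corr_threshold, cfg.min_sd)
            logs.extend(flog)
        _write_tsv(data_io.removal_log_frame(logs),
                   out / "removed_variables.tsv", manifest)
        log(stage)

        stage = "standardize"
        pair = data_io.standardize_pair(behavioral, imaging)
        log(stage)

        stage = "grid_search"
        grid_x = cfg.grid_x or default_grid(pair.X.shape[1], cfg.grid_points)
        grid_y = cfg.grid_y or default_grid(pair.Y.shape[1], cfg.grid_points)
        cx, cy, surface = inference.grid_search_sparsity(pair, grid_x, grid_y)
        _write_tsv(surface, out / "r_surface.tsv", manifest)
        log(stage)

        stage = "fit"
        model = fit_scca(pair, cx, cy)
        _write_tsv(pd.DataFrame({
            "variable": pair.names_x + pair.names_y,
            "side": ["behavioral"] * len(pair.names_x)
                    + ["imaging"] * len(pair.names_y),
            "weight": np.concatenate([model.wx, model.wy]),
        }), out / "weights.tsv", manifest)
        log(stage)

        stage = "permutation_test"
        perm = inference.permutation_test(
            pair, cx, cy, n_perm=cfg.n_perm, seed=cfg.seed,
            retune=cfg.retune_permutations, grid_x=grid_x, grid_y=grid_y)
        _write_tsv(pd.DataFrame({"null_r": perm.null_rs}),
                   out / "permutation_null.tsv", manifest)
        log(stage)

        stage = "loadings"
        if pair.group_labels is not None:
            profiles = inference.subgroup_loadings(pair, model)
        else:
            profiles = [
                inference.compute_loadings(pair.X, model.variate_y,
                                           pair.names_x, "behavioral", "all"),
                inference.compute_loadings(pair.Y, model.variate_x,
                                           pair.names_y, "imaging", "all"),
            ]
        _write_tsv(pd.concat([pr.to_frame() for pr in profiles],
                             ignore_index=True),
                   out / "loadings.tsv", manifest)
        log(stage)

        stage = "reliability"
        rel = reliability.reliability_report(
            pair, cx, cy, n_splits=cfg.n_splits, seed=cfg.seed)
        _write_tsv(pd.DataFrame({"subject_id": pair.subject_ids,
                                 "loo_corr": rel.loo_corrs}),
                   out / "loo.tsv", manifest)
        _write_tsv(pd.DataFrame({"rr_score": rel.rr_scores}),
                   out / "rr_scores.tsv", manifest)
        _write_tsv(pd.DataFrame({"splithalf_r": rel.splithalf_rs}),
                   out / "splithalf.tsv", manifest)
        log(stage)

        stage = "summary"
        summary = {
            "n_subjects": pair.n,
            "p_behavioral": pair.X.shape[1],
            "q_imaging": pair.Y.shape[1],
            "cx": cx,
            "cy": cy,
            "r": model.r,
            "n_iter": model.n_iter,
            "converged": model.converged,
            "p_value": perm.p_value,
            "n_perm": perm.n_perm,
            "seed": cfg.seed,
            "reliability": rel.summary(),
            "n_variables_removed": len(logs),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest.append("summary.json")
        log(stage)
    except Exception as e:  # noqa: BLE001 - abort with stage + manifest
        with open(out / "manifest.json", "w") as fh:
            json.dump({"failed_stage": stage, "artifacts": manifest}, fh,
                      indent=2)
        raise PipelineError(stage, manifest, e) from e

    with open(out / "manifest.json", "w") as fh:
        json.dump({"failed_stage": None, "artifacts": manifest}, fh, indent=2)
    with open(out / "log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return out
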