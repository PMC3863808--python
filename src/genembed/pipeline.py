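"""Pipeline orchestration: one reproducible run directory per configuration.

Stages execute in the canonical order — (optionally) simulate or load a
cohort, invert per subject, embed, residualize confounds, standardize,
cluster and/or classify, validate — and every artefact is written alongside
the configuration and seeds that produced it. Run directories are
content-addressed by a hash of the configuration, so rerunning the same
configuration overwrites the same directory with byte-identical numeric
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .design import build_nback_design
from .embedding import residualize_confounds, standardize
from .supervised import crossval_classify
from .synthetic import generate_feature_cohort, table1_cohort, two_group_cohort
from .validation import (
    LabelledPartition,
    anova_external,
    balanced_purity,
    posterior_model_probability,
    purity,
)
from .vbgmm import select_model_order

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    cohort: str = "table1"  # table1 | two_group | a score-space TSV path
    sd_multiplier: float = 1.0
    seed_cohort: int = 0
    seed_cluster: int = 0
    seed_classify: int = 0
    K_max: int = 6
    n_restarts: int = 5
    tol: float = 1e-6
    cv_folds: int = 5
    regularisation: float = 1.0
    confound_columns: tuple[str, ...] = ("sex", "handedness", "age")
    external_column: str = "score"
    classify: bool = True
    covariates_path: str | None = None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["confound_columns"] = list(self.confound_columns)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["confound_columns"] = tuple(d.get("confound_columns", ()))
        return cls(**d)

    def digest(self) -> str:
        d = asdict(self)
        d["confound_columns"] = list(self.confound_columns)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def _load_inputs(config: RunConfig):
    if config.cohort == "table1":
        spec = table1_cohort(config.sd_multiplier)
        return generate_feature_cohort(spec, config.seed_cohort)
    if config.cohort == "two_group":
        spec = two_group_cohort()
        return generate_feature_cohort(spec, config.seed_cohort)
    space = gio.read_score_space(config.cohort)
    labels = None
    covariates = None
    if config.covariates_path:
        covariates = gio.read_covariates_tsv(config.covariates_path)
        if "label" in covariates.columns:
            labels = covariates["label"].to_numpy()
    return space, labels, covariates


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages; returns the content-addressed run directory."""
    t0 = time.monotonic()
    run_dir = Path(out_dir) / f"run-{config.digest()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    log: list[str] = []

    def stage(name):
        log.append(f"{name} @ {time.monotonic() - t0:.2f}s")

    try:
        space, labels, covariates = _load_inputs(config)
        stage("load")
        gio.write_score_space(space, run_dir / "score_space_raw.tsv")

        if covariates is not None and config.confound_columns:
            missing = [
                c for c in config.confound_columns if c not in covariates.columns
            ]
            if missing:
                raise KeyError(
                    f"stage embed: covariate columns not found: {missing}"
                )
            space = residualize_confounds(
                space, covariates[list(config.confound_columns)]
            )
        space = standardize(space)
        stage("embed")
        gio.write_score_space(space, run_dir / "score_space.tsv")
        if covariates is not None:
            gio.write_covariates_tsv(covariates, run_dir / "covariates.tsv")

        solution = select_model_order(
            space.X, K_max=config.K_max, n_restarts=config.n_restarts,
            seed=config.seed_cluster, tol=config.tol,
        )
        stage("cluster")
        gio.write_solution_json(solution, run_dir / "solution.json")

        report: dict = {
            "selected_K": solution.selected_K,
            "free_energies": {str(k): v for k, v in solution.free_energies.items()},
            "log_bayes_factor": solution.log_bayes_factor,
        }
        if solution.log_bayes_factor is not None:
            report["posterior_model_probability"] = posterior_model_probability(
                solution.log_bayes_factor
            )
        if labels is not None:
            part = LabelledPartition(solution.assignments, np.asarray(labels))
            report["purity"] = purity(part)
            if part.K_classes >= 2:
                report["balanced_purity"] = balanced_purity(part)
        if (covariates is not None
                and config.external_column in covariates.columns
                and np.unique(solution.assignments).size >= 2):
            F, dof, p = anova_external(
                solution.assignments,
                covariates[config.external_column].to_numpy(float),
            )
            report["anova_external"] = {"F": F, "dof": list(dof), "p": p}
        if config.classify and labels is not None and np.unique(labels).size == 2:
            cv = crossval_classify(
                space, np.asarray(labels), n_folds=config.cv_folds,
                seed=config.seed_classify,
                regularisation=config.regularisation,
            )
            report["classification"] = {
                "balanced_accuracy": cv.balanced_accuracy,
                "infraliminal_p": cv.infraliminal_p,
            }
            stage("classify")
        stage("validate")
        (run_dir / "report.json").write_text(json.dumps(report, indent=1))
    except Exception as err:
        (run_dir / "log.txt").write_text("\n".join(log + [f"FAILED: {err}"]))
        raise
    (run_dir / "log.txt").write_text("\n".join(log))
    return run_dir
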