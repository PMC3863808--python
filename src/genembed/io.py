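"""Plain-text file formats: BOLD/design/covariate TSVs and JSON artefacts.

All numeric JSON output keeps full double precision (repr round-trips); TSVs
are written with 15 significant digits and parsed locale-independently by
pandas with the C engine.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StimulusDesign, design_from_events
from .embedding import ScoreSpace
from .invert import PosteriorFit
from .network import BoldRecord
from .vbgmm import ClusterSolution

__all__ = [
    "write_bold_tsv", "read_bold_tsv",
    "write_design_tsv", "read_design_tsv",
    "write_score_space", "read_score_space",
    "write_fit_json", "read_fit_json",
    "write_solution_json",
    "read_covariates_tsv", "write_covariates_tsv",
]


class ParseError(ValueError):
    pass


def write_bold_tsv(rec: BoldRecord, path, metadata: dict | None = None) -> None:
    """First column scan time (s), one column per region; JSON sidecar with TR."""
    path = Path(path)
    df = pd.DataFrame(rec.y, columns=list(rec.region_names))
    df.insert(0, "time_s", rec.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")
    side = {"TR": rec.TR, "region_names": list(rec.region_names)}
    if metadata:
        side.update(metadata)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))


def read_bold_tsv(path) -> BoldRecord:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise ParseError(f"cannot parse {path}: {err}") from err
    if df.columns[0] != "time_s":
        raise ParseError(f"{path}: first column must be time_s")
    side_path = path.with_suffix(path.suffix + ".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        TR = float(side["TR"])
        names = tuple(side["region_names"])
        if list(names) != list(df.columns[1:]):
            raise ParseError(f"{path}: region names disagree with sidecar")
    else:
        t = df["time_s"].to_numpy()
        TR = float(t[1] - t[0]) if len(t) > 1 else 1.0
        names = tuple(df.columns[1:])
    return BoldRecord(y=df.iloc[:, 1:].to_numpy(float), TR=TR, region_names=names)


def write_design_tsv(events: list[tuple[str, float, float, float]], path) -> None:
    df = pd.DataFrame(events, columns=["input_name", "onset_s", "duration_s", "value"])
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_design_tsv(path, TR: float, n_scans: int,
                    micro_dt: float | None = None) -> StimulusDesign:
    try:
        df = pd.read_csv(Path(path), sep="\t")
    except Exception as err:
        raise ParseError(f"cannot parse {path}: {err}") from err
    required = ["input_name", "onset_s", "duration_s", "value"]
    if list(df.columns) != required:
        raise ParseError(f"{path}: columns must be {required}")
    events = [tuple(row) for row in df.itertuples(index=False)]
    return design_from_events(events, TR=TR, n_scans=n_scans, micro_dt=micro_dt)


def write_score_space(space: ScoreSpace, path) -> None:
    path = Path(path)
    df = space.to_dataframe()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", float_format="%.15g")
    side = {"provenance": space.provenance, "log": space.log}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))


def read_score_space(path) -> ScoreSpace:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as err:
        raise ParseError(f"cannot parse {path}: {err}") from err
    provenance, log = "generative", []
    side_path = path.with_suffix(path.suffix + ".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        provenance = side.get("provenance", provenance)
        log = side.get("log", [])
    return ScoreSpace(
        X=df.to_numpy(float),
        feature_names=tuple(df.columns),
        subject_ids=tuple(str(i) for i in df.index),
        provenance=provenance,
        log=log,
    )


def write_covariates_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", float_format="%.15g")


def read_covariates_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(Path(path), sep="\t", index_col=0)
    except Exception as err:
        raise ParseError(f"cannot parse {path}: {err}") from err


def write_fit_json(fit: PosteriorFit, path) -> None:
    payload = {
        "parameter_names": list(fit.parameter_names),
        "posterior_mean": fit.posterior_mean.tolist(),
        "posterior_cov": fit.posterior_cov.tolist(),
        "free_energy": fit.free_energy,
        "noise_log_precision": fit.noise_log_precision.tolist(),
        "n_iterations": fit.n_iterations,
        "converged": fit.converged,
        "r2_per_region": np.asarray(fit.r2_per_region, float).tolist(),
        "residual_sd_per_region": fit.residual_sd_per_region.tolist(),
        "n_neuronal": fit.n_neuronal,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_json(path) -> PosteriorFit:
    d = json.loads(Path(path).read_text())
    return PosteriorFit(
        posterior_mean=np.array(d["posterior_mean"]),
        posterior_cov=np.array(d["posterior_cov"]),
        free_energy=d["free_energy"],
        noise_log_precision=np.array(d["noise_log_precision"]),
        free_energy_trace=np.array([d["free_energy"]]),
        n_iterations=d["n_iterations"],
        converged=d["converged"],
        r2_per_region=np.array(d["r2_per_region"]),
        residual_sd_per_region=np.array(d["residual_sd_per_region"]),
        parameter_names=tuple(d["parameter_names"]),
        n_neuronal=d["n_neuronal"],
    )


def write_solution_json(solution: ClusterSolution, path) -> None:
    payload = {
        "free_energies": {str(k): v for k, v in solution.free_energies.items()},
        "selected_K": solution.selected_K,
        "log_bayes_factor": solution.log_bayes_factor,
        "assignments": solution.assignments.tolist(),
        "responsibilities": solution.posterior.responsibilities.tolist(),
        "expected_weights": solution.posterior.expected_weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
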