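"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The study's raw fMRI data were never deposited, so every stage is exercised
on synthetic cohorts instead. The default patient cohort reproduces the
printed connectivity profiles of the three schizophrenia subgroups
identified in the source dataset (three clusters of 9, 24 and 7 subjects in
the 12-dimensional coupling space of the visual-parietal-prefrontal
working-memory network), together with cluster-dependent negative-symptom
scores (means 15.6 / 19.6 / 27.9, SDs 2.3 / 1.4 / 4.1, truncated at zero).

The printed per-cluster dispersions are standard errors, not SDs; the
generator uses them directly as generative SDs (tight, well-separated
clusters) and exposes an ``sd_multiplier`` to explore overlap — multiplying
by sqrt(cluster size) approximates the empirical between-patient SD.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import StimulusDesign, build_nback_design
from .embedding import ScoreSpace
from .forward import simulate_subject, stability_check
from .network import (
    HemodynamicParams,
    NetworkSpec,
    NeuronalParams,
    default_hemodynamics,
    wm_network,
)

__all__ = [
    "ClusterProfile",
    "CohortSpec",
    "table1_cohort",
    "two_group_cohort",
    "sample_parameters",
    "generate_feature_cohort",
    "generate_cohort_bold",
    "generate_voxel_betas",
]


@dataclass(frozen=True)
class ClusterProfile:
    """One cluster: mean/SD over the 12 neuronal parameters plus the
    external-score model."""

    name: str
    mean: np.ndarray
    sd: np.ndarray
    size: int
    score_mean: float
    score_sd: float

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "sd", np.asarray(self.sd, float))
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if np.any(self.sd < 0) or self.score_sd < 0:
            raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort."""

    network: NetworkSpec
    clusters: tuple[ClusterProfile, ...]
    sd_multiplier: float = 1.0
    confound_effects: np.ndarray | None = None  # (3, d): sex, handedness, age(z)
    hemo_log_sd: float = 0.125
    bold_noise_sd: float = 0.1  # percent signal change
    design: StimulusDesign | None = None

    def __post_init__(self):
        d = self.network.n_free_parameters
        for c in self.clusters:
            if c.mean.size != d or c.sd.size != d:
                raise ValueError("profile dimension must match the network")
        if self.confound_effects is not None:
            eff = np.asarray(self.confound_effects, float)
            if eff.shape != (3, d):
                raise ValueError("confound_effects must be (3, d)")
            object.__setattr__(self, "confound_effects", eff)

    @property
    def n_subjects(self) -> int:
        return sum(c.size for c in self.clusters)


# Published per-cluster coupling profiles (mean, standard error), in the
# documented feature order of the working-memory network: the nine A entries
# (VC self, VC->PC, VC->DLPFC, PC->VC, PC self, PC->DLPFC, DLPFC->VC,
# DLPFC->PC, DLPFC self), the two working-memory modulations (VC->DLPFC,
# DLPFC->PC) and the visual driving input.
_SUBGROUP_MEANS = {
    "cluster1": [-1.000, 0.036, 0.055, 0.017, -1.000, 0.017, 0.043, 0.042,
                 -0.997, 0.110, 0.204, 0.073],
    "cluster2": [-0.994, 0.070, 0.044, 0.014, -0.994, 0.014, 0.021, 0.034,
                 -0.998, 0.124, -0.023, 0.074],
    "cluster3": [-1.001, 0.044, 0.130, 0.017, -0.999, 0.024, 0.019, 0.023,
                 -0.996, 0.267, 0.071, 0.104],
}
_SUBGROUP_SES = {
    "cluster1": [0.001, 0.022, 0.029, 0.001, 0.000, 0.001, 0.026, 0.024,
                 0.003, 0.227, 0.191, 0.043],
    "cluster2": [0.003, 0.036, 0.018, 0.004, 0.004, 0.005, 0.020, 0.012,
                 0.001, 0.102, 0.017, 0.043],
    "cluster3": [0.004, 0.025, 0.068, 0.002, 0.001, 0.007, 0.004, 0.008,
                 0.003, 0.135, 0.064, 0.020],
}
_SUBGROUP_SIZES = {"cluster1": 9, "cluster2": 24, "cluster3": 7}
_SUBGROUP_SCORES = {"cluster1": (15.6, 2.3), "cluster2": (19.6, 1.4), "cluster3": (27.9, 4.1)}


def table1_cohort(sd_multiplier: float = 1.0) -> CohortSpec:
    """Three patient subgroups (sizes 9/24/7) at the printed cluster profiles."""
    clusters = tuple(
        ClusterProfile(
            name=k,
            mean=_SUBGROUP_MEANS[k],
            sd=_SUBGROUP_SES[k],
            size=_SUBGROUP_SIZES[k],
            score_mean=_SUBGROUP_SCORES[k][0],
            score_sd=_SUBGROUP_SCORES[k][1],
        )
        for k in ("cluster1", "cluster2", "cluster3")
    )
    return CohortSpec(network=wm_network(), clusters=clusters,
                      sd_multiplier=sd_multiplier)


# Pooled patient profile (size-weighted mean of the three printed clusters)
# and a SYNTHETIC control profile. The study reports no control-group
# coupling table, so the control values below are declared, not published:
# controls differ mainly in stronger working-memory modulation of both
# modulated connections and a stronger parietal<-prefrontal backbone.
_PATIENT_POOLED_MEAN = [-0.997, 0.058, 0.061, 0.015, -0.996, 0.016, 0.025,
                        0.034, -0.997, 0.145, 0.043, 0.079]
_CONTROL_MEAN = [-0.998, 0.060, 0.065, 0.016, -0.996, 0.035, 0.060,
                 0.100, -0.997, 0.700, 0.400, 0.160]
_TWO_GROUP_SD = [0.003, 0.030, 0.030, 0.003, 0.003, 0.005, 0.020, 0.015,
                 0.003, 0.120, 0.100, 0.040]


def two_group_cohort(n_controls: int = 42, n_patients: int = 41) -> CohortSpec:
    """Synthetic patients-vs-controls cohort (control profile is declared,
    not taken from any published table)."""
    clusters = (
        ClusterProfile("controls", _CONTROL_MEAN, _TWO_GROUP_SD, n_controls,
                       score_mean=5.0, score_sd=2.0),
        ClusterProfile("patients", _PATIENT_POOLED_MEAN, _TWO_GROUP_SD,
                       n_patients, score_mean=20.2, score_sd=8.5),
    )
    return CohortSpec(network=wm_network(), clusters=clusters)


def _draw_features(spec: CohortSpec, rng: np.random.Generator):
    """Per-cluster diagonal-Gaussian feature draws, stability-screened."""
    rows, labels = [], []
    n_a = int(spec.network.a_mask.sum())
    for ci, prof in enumerate(spec.clusters):
        sd = prof.sd * spec.sd_multiplier
        for _ in range(prof.size):
            for attempt in range(101):
                theta = prof.mean + sd * rng.standard_normal(prof.mean.size)
                # stability screen on the A matrix only
                A = np.zeros((spec.network.n_regions,) * 2)
                A.T[spec.network.a_mask.T] = theta[:n_a]
                if np.all(np.diag(A) < 0) and stability_check(A):
                    break
            else:
                raise RuntimeError("100 consecutive stability rejections")
            rows.append(theta)
            labels.append(ci)
    return np.asarray(rows), np.asarray(labels)


def sample_parameters(spec: CohortSpec, seed: int | None = 0):
    """Draw per-subject neuronal parameters; returns (params list, labels)."""
    rng = np.random.default_rng(seed)
    X, labels = _draw_features(spec, rng)
    params = [NeuronalParams.from_vector(row, spec.network) for row in X]
    return params, labels


def _truncated_normal(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size,
        random_state=np.random.default_rng(rng.integers(2**31 - 1)),
    )


def generate_feature_cohort(spec: CohortSpec, seed: int | None = 0):
    """Fast path: draw the feature matrix directly (no BOLD simulation).

    Returns (ScoreSpace, truth_labels, covariates DataFrame). The covariate
    table holds sex and handedness (0/1), age (years) and the external score;
    confound effects, if any, are applied to z-scored covariates.
    """
    rng = np.random.default_rng(seed)
    X, labels = _draw_features(spec, rng)
    n = len(labels)
    sex = rng.binomial(1, 0.25, n).astype(float)
    handedness = rng.binomial(1, 0.9, n).astype(float)
    age = rng.normal(34.1, 10.4, n)
    if spec.confound_effects is not None:
        cov = np.column_stack([sex, handedness, age])
        covz = (cov - cov.mean(axis=0)) / np.maximum(cov.std(axis=0), 1e-12)
        X = X + covz @ spec.confound_effects
    scores = np.empty(n)
    for ci, prof in enumerate(spec.clusters):
        mask = labels == ci
        scores[mask] = _truncated_normal(rng, prof.score_mean, prof.score_sd,
                                         int(mask.sum()))
    space = ScoreSpace(
        X=X,
        feature_names=tuple(spec.network.free_parameter_names()),
        subject_ids=tuple(f"sub-{i:03d}" for i in range(n)),
        provenance="generative",
    )
    covariates = pd.DataFrame(
        {"sex": sex, "handedness": handedness, "age": age, "score": scores},
        index=list(space.subject_ids),
    )
    return space, labels, covariates


def generate_cohort_bold(
    spec: CohortSpec, design: StimulusDesign | None = None, seed: int | None = 0
):
    """Full forward path: per-subject BOLD records with haemodynamic draws.

    Returns (records, truth_labels, params list).
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = spec.design if spec.design is not None else build_nback_design()
    X, labels = _draw_features(spec, rng)
    records, params_list = [], []
    base = default_hemodynamics(spec.network.n_regions)
    for i, row in enumerate(X):
        params = NeuronalParams.from_vector(row, spec.network)
        z = rng.normal(0.0, spec.hemo_log_sd, (spec.network.n_regions, 5))
        hemo = HemodynamicParams(
            signal_decay=base.signal_decay * np.exp(z[:, 0]),
            autoregulation=base.autoregulation * np.exp(z[:, 1]),
            transit_time=base.transit_time * np.exp(z[:, 2]),
            stiffness=np.clip(base.stiffness * np.exp(z[:, 3]), 1e-3, 0.999),
            oxygen_extraction=np.clip(base.oxygen_extraction * np.exp(z[:, 4]),
                                      1e-3, 0.999),
        )
        rec = simulate_subject(
            params, hemo, design,
            noise_sd=spec.bold_noise_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        records.append(rec)
        params_list.append(params)
    return records, labels, params_list


def generate_voxel_betas(
    spec: CohortSpec, voxels_per_region: int = 50, seed: int | None = 0,
    scatter: float = 0.2,
):
    """Voxelwise effect estimates per region, for the regional-activity space.

    Each subject's region-level mean effect is a declared linear read-out of
    their driving/modulatory strengths (visual input for VC, the two
    working-memory modulations for DLPFC and PC) plus voxel scatter.
    Returns (list of region->betas dicts, truth_labels).
    """
    if voxels_per_region < 2:
        raise ValueError("need at least 2 voxels per region")
    rng = np.random.default_rng(seed)
    X, labels = _draw_features(spec, rng)
    names = spec.network.free_parameter_names()
    idx_c = names.index("C: visual->VC")
    idx_b1 = names.index("B(wm): VC->DLPFC")
    idx_b2 = names.index("B(wm): DLPFC->PC")
    out = []
    for row in X:
        effects = {
            "VC": 1.0 + 5.0 * row[idx_c],
            "PC": 0.5 + 2.0 * row[idx_b2],
            "DLPFC": 0.5 + 2.0 * row[idx_b1],
        }
        out.append(
            {
                reg: rng.normal(mu, scatter, voxels_per_region)
                for reg, mu in effects.items()
            }
        )
    return out, labels
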