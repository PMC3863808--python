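"""Generative score spaces and comparator feature spaces.

The generative score space maps each subject to the posterior means of the
neuronal coupling parameters of their fitted network model (for the
three-region working-memory network: 12 features). Two comparator spaces are
provided: pairwise Pearson correlations between regional time courses
(functional connectivity) and per-region means/SDs of voxelwise effect
estimates (regional activity).

Confounds (e.g. sex, handedness, age) are removed feature-by-feature with an
ordinary least-squares regression, after which features are standardized to
zero mean and unit sample SD. The sample (n-1) SD convention is used
throughout and recorded in the preprocessing log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .invert import PosteriorFit
from .network import BoldRecord, NetworkSpec

__all__ = [
    "ScoreSpace",
    "first_eigenvariate",
    "build_score_space",
    "residualize_confounds",
    "standardize",
    "functional_connectivity_features",
    "regional_activity_features",
    "ConfoundRegressor",
    "SampleStandardScaler",
]


@dataclass
class ScoreSpace:
    """Subjects x features matrix with provenance and a preprocessing log."""

    X: np.ndarray
    feature_names: tuple[str, ...]
    subject_ids: tuple[str, ...]
    provenance: str = "generative"
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, float))
        if np.any(~np.isfinite(self.X)):
            raise ValueError("score space contains missing or non-finite values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.X.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("matrix shape must match subject and feature counts")
        self.feature_names = tuple(self.feature_names)
        self.subject_ids = tuple(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=list(self.subject_ids),
                            columns=list(self.feature_names))

    def replace(self, X: np.ndarray, log_entry: dict | None = None) -> "ScoreSpace":
        log = list(self.log)
        if log_entry:
            log.append(log_entry)
        return ScoreSpace(X=X, feature_names=self.feature_names,
                          subject_ids=self.subject_ids,
                          provenance=self.provenance, log=log)


def first_eigenvariate(voxel_ts: np.ndarray) -> np.ndarray:
    """Representative time course of a region: dominant singular direction.

    The voxels x time matrix is column-centred (per-voxel mean removed); the
    first right-singular vector is scaled by its singular value divided by the
    square root of the voxel count, and its sign is fixed so that the mean
    voxel loading is non-negative.
    """
    M = np.atleast_2d(np.asarray(voxel_ts, float))
    n_vox, n_t = M.shape
    if n_t < 2:
        raise ValueError("need at least two time points")
    Mc = M - M.mean(axis=1, keepdims=True)
    if not np.any(Mc):
        raise ValueError("all-zero (constant) voxel matrix has no eigenvariate")
    U, S, Vt = np.linalg.svd(Mc, full_matrices=False)
    v = Vt[0]
    if U[:, 0].mean() < 0:
        v = -v
    return v * S[0] / np.sqrt(n_vox)


def build_score_space(fits: list[PosteriorFit], spec: NetworkSpec) -> ScoreSpace:
    """Stack neuronal posterior means across subjects (haemodynamic and noise
    parameters are excluded by construction)."""
    if not fits:
        raise ValueError("no fits supplied")
    names = tuple(spec.free_parameter_names())
    rows = []
    for i, fit in enumerate(fits):
        if fit.neuronal_names != names:
            raise ValueError(
                f"fit {i} was obtained under a different network spec"
            )
        rows.append(fit.neuronal_means)
    return ScoreSpace(
        X=np.vstack(rows),
        feature_names=names,
        subject_ids=tuple(f"sub-{i:03d}" for i in range(len(fits))),
        provenance="generative",
    )


def residualize_confounds(space: ScoreSpace, confounds: pd.DataFrame) -> ScoreSpace:
    """Replace each feature by its OLS residual on the confounds + intercept."""
    if len(confounds) != space.n_subjects:
        raise ValueError("confound rows must align with subjects")
    Cdf = confounds.select_dtypes(include=[np.number])
    if Cdf.shape[1] != confounds.shape[1]:
        raise ValueError("confound columns must be numeric (code categoricals 0/1)")
    if Cdf.isna().any().any():
        raise ValueError("confound table contains missing values")
    # constant columns are collinear with the intercept and carry nothing:
    # drop them (recorded in the log) instead of failing
    constant = [c for c in Cdf.columns if Cdf[c].nunique() == 1]
    Cdf = Cdf.drop(columns=constant)
    C = np.column_stack([np.ones(space.n_subjects), Cdf.to_numpy(float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = [np.ones(space.n_subjects)]
        for j, name in enumerate(Cdf.columns):
            cand = np.column_stack(cols + [C[:, j + 1]])
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(str(name))
            else:
                cols.append(C[:, j + 1])
        raise ValueError(f"confound matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(C, space.X, rcond=None)
    resid = space.X - C @ beta
    return space.replace(
        resid,
        {"step": "residualize", "confounds": [str(c) for c in Cdf.columns],
         "dropped_constant": [str(c) for c in constant]},
    )


def standardize(space: ScoreSpace) -> ScoreSpace:
    """Centre features and scale to unit sample (n-1) standard deviation."""
    mu = space.X.mean(axis=0)
    sd = space.X.std(axis=0, ddof=1)
    const = np.where(sd == 0)[0]
    if const.size:
        names = [space.feature_names[j] for j in const]
        raise ValueError(f"constant features cannot be standardized: {names}")
    Z = (space.X - mu) / sd
    return space.replace(
        Z,
        {"step": "standardize", "sd_convention": "sample (ddof=1)",
         "means": mu.tolist(), "sds": sd.tolist()},
    )


def functional_connectivity_features(bolds: list[BoldRecord]) -> ScoreSpace:
    """Upper-triangle pairwise Pearson correlations of regional time courses."""
    if not bolds:
        raise ValueError("no records supplied")
    regions = bolds[0].region_names
    r = len(regions)
    pairs = [(i, j) for i in range(r) for j in range(i + 1, r)]
    rows = []
    for k, rec in enumerate(bolds):
        if rec.region_names != regions:
            raise ValueError(f"record {k} has a different region set")
        sd = rec.y.std(axis=0)
        if np.any(sd == 0):
            flat = [regions[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"constant time series in record {k}: {flat}")
        corr = np.corrcoef(rec.y.T)
        rows.append([corr[i, j] for i, j in pairs])
    return ScoreSpace(
        X=np.asarray(rows),
        feature_names=tuple(f"fc: {regions[i]}~{regions[j]}" for i, j in pairs),
        subject_ids=tuple(f"sub-{i:03d}" for i in range(len(bolds))),
        provenance="functional_connectivity",
    )


def regional_activity_features(
    voxel_betas: list[dict[str, np.ndarray]],
) -> ScoreSpace:
    """Per-region mean and sample SD of voxelwise effect estimates.

    `voxel_betas` holds, per subject, a mapping region -> vector of voxelwise
    GLM effect estimates. Three regions yield six features.
    """
    if not voxel_betas:
        raise ValueError("no subjects supplied")
    regions = list(voxel_betas[0].keys())
    rows = []
    for k, sub in enumerate(voxel_betas):
        if list(sub.keys()) != regions:
            raise ValueError(f"subject {k} has a different region set")
        feats = []
        for reg in regions:
            b = np.asarray(sub[reg], float)
            if b.size < 2:
                raise ValueError(f"region {reg!r} needs at least 2 voxels")
            feats.extend([b.mean(), b.std(ddof=1)])
        rows.append(feats)
    names = []
    for reg in regions:
        names.extend([f"act-mean: {reg}", f"act-sd: {reg}"])
    return ScoreSpace(
        X=np.asarray(rows),
        feature_names=tuple(names),
        subject_ids=tuple(f"sub-{i:03d}" for i in range(len(voxel_betas))),
        provenance="regional_activity",
    )


class ConfoundRegressor:
    """sklearn-style transformer removing confound effects feature-wise."""

    def __init__(self):
        pass

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X: np.ndarray, confounds: np.ndarray) -> "ConfoundRegressor":
        X = np.asarray(X, float)
        C = np.column_stack([np.ones(len(X)), np.asarray(confounds, float)])
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("confound matrix is rank deficient")
        self.design_ = C
        self.coef_, *_ = np.linalg.lstsq(C, X, rcond=None)
        return self

    def transform(self, X: np.ndarray, confounds: np.ndarray) -> np.ndarray:
        C = np.column_stack([np.ones(len(X)), np.asarray(confounds, float)])
        return np.asarray(X, float) - C @ self.coef_

    def fit_transform(self, X: np.ndarray, confounds: np.ndarray) -> np.ndarray:
        return self.fit(X, confounds).transform(X, confounds)


class SampleStandardScaler:
    """Zero-mean, unit sample-SD (ddof=1) scaler (sklearn uses ddof=0)."""

    def __init__(self):
        pass

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X: np.ndarray, y=None) -> "SampleStandardScaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise ValueError("constant columns cannot be standardized")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
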