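"""Variational-Laplace inversion of the forward model.

Model inversion maximises a free-energy bound to the log model evidence
ln p(y|m) under a fixed-form Gaussian posterior q(theta) = N(mu, Sigma)
(the Laplace assumption). The scheme is Gauss-Newton ascent on the log-joint
with Levenberg-style damping, alternating with a damped Newton update of the
per-region noise log-precisions. Steps are accepted only if they increase the
free energy, so the recorded free-energy trace is non-decreasing by
construction.

Free energy (Laplace form):

    F = ln p(y | mu) + ln p(mu) + 1/2 ln|Sigma| + d/2 ln(2*pi)

with Sigma the inverse Gauss-Newton curvature at mu. In the degenerate case
of a linear observation map with fixed noise precision this equals the exact
log evidence and the fixed point is the exact conjugate posterior, which the
test suite verifies against the closed form.

Parameterisation: neuronal coupling parameters are estimated in raw units
(Hz); haemodynamic parameters and noise precisions are estimated as
log-scalings of their default values (positivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .design import StimulusDesign
from .forward import DivergenceError, integrate_bold, integrate_neuronal, simulate_batch
from .network import (
    BoldRecord,
    HemodynamicParams,
    NetworkSpec,
    NeuronalParams,
    _HEMO_DEFAULTS,
    default_hemodynamics,
)

__all__ = [
    "PriorSpec",
    "PosteriorFit",
    "default_priors",
    "variational_laplace",
    "invert",
    "predicted_response",
    "variance_explained",
    "DCMInverter",
]

_HEMO_ORDER = (
    "signal_decay",
    "autoregulation",
    "transit_time",
    "stiffness",
    "oxygen_extraction",
)


@dataclass
class PriorSpec:
    """Gaussian prior over the concatenated parameter vector.

    Layout: neuronal parameters (raw units), then per-region haemodynamic
    log-scalings (5 per region), then per-region noise log-precisions.
    """

    mean: np.ndarray
    cov: np.ndarray
    transforms: tuple[str, ...]
    names: tuple[str, ...]
    n_neuronal: int
    n_regions: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        d = self.mean.size
        if self.cov.shape != (d, d):
            raise ValueError("prior covariance must be square and match the mean")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("prior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) <= 0):
            raise ValueError("prior covariance must be positive definite")

    @property
    def n_model(self) -> int:
        """Parameters entering the observation map (all but noise precisions)."""
        return self.mean.size - self.n_regions


def default_priors(spec: NetworkSpec) -> PriorSpec:
    """Zero-mean shrinkage priors on coupling; physiological priors elsewhere.

    Off-diagonal A, B and C entries: N(0, 1/16). A-diagonal (self-inhibition):
    N(-1, 1/256). Haemodynamic log-scalings: N(0, 0.0156) around the published
    balloon-model values. Noise log-precisions: N(0, 1).
    """
    names = list(spec.free_parameter_names())
    means = []
    variances = []
    for name in names:
        if name.startswith("A") and name.endswith("self"):
            means.append(-1.0)
            variances.append(1.0 / 256.0)
        else:
            means.append(0.0)
            variances.append(1.0 / 16.0)
    n_neuronal = len(names)
    transforms = ["identity"] * n_neuronal
    for region in spec.region_names:
        for h in _HEMO_ORDER:
            names.append(f"hemo[{h}]: {region}")
            means.append(0.0)
            variances.append(0.0156)
            transforms.append("log")
    for region in spec.region_names:
        names.append(f"noise_log_precision: {region}")
        means.append(0.0)
        variances.append(1.0)
        transforms.append("log")
    return PriorSpec(
        mean=np.array(means),
        cov=np.diag(variances),
        transforms=tuple(transforms),
        names=tuple(names),
        n_neuronal=n_neuronal,
        n_regions=spec.n_regions,
    )


@dataclass
class PosteriorFit:
    """Gaussian posterior over model parameters plus fit diagnostics."""

    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    free_energy: float
    noise_log_precision: np.ndarray
    free_energy_trace: np.ndarray
    n_iterations: int
    converged: bool
    r2_per_region: np.ndarray
    residual_sd_per_region: np.ndarray
    parameter_names: tuple[str, ...]
    n_neuronal: int
    predicted: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.posterior_cov, float)
        if not np.allclose(c, c.T, atol=1e-8):
            raise ValueError("posterior covariance must be symmetric")
        if self.converged and not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite for a converged fit")

    @property
    def neuronal_means(self) -> np.ndarray:
        """Posterior means of the neuronal coupling parameters (Hz)."""
        return self.posterior_mean[: self.n_neuronal]

    @property
    def neuronal_names(self) -> tuple[str, ...]:
        return self.parameter_names[: self.n_neuronal]

    def interpretable_means(self) -> dict[str, float]:
        """Posterior means with log transforms undone (haemodynamic scalings
        reported as multiplicative factors, noise as standard deviations)."""
        out: dict[str, float] = {}
        for name, value in zip(self.parameter_names, self.posterior_mean):
            out[name] = float(np.exp(value)) if name.startswith("hemo[") else float(value)
        for k, lam in enumerate(self.noise_log_precision):
            out[f"noise_sd[region {k}]"] = float(np.exp(-0.5 * lam))
        return out


def _weighted_curvature(J: np.ndarray, pi: np.ndarray) -> np.ndarray:
    # J: (n, R, d), pi: (R,)
    return np.einsum("nrd,r,nre->de", J, pi, J, optimize=True)


def variational_laplace(
    predict: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    *,
    fixed_precision: np.ndarray | float | None = None,
    noise_prior_mean: float = 0.0,
    noise_prior_var: float = 1.0,
    max_iter: int = 128,
    tol: float = 1e-2,
    fd_step: float = 1e-4,
    seed: int | None = None,
    init_jitter: float = 0.0,
) -> dict:
    """Gauss-Newton/Levenberg maximisation of the Laplace free energy.

    `predict` maps a (P, d) batch of parameter vectors to (P, n, R)
    predictions; `y` is the (n, R) data matrix. If `fixed_precision` is given
    the noise precision is held fixed (per region), otherwise per-region noise
    log-precisions are updated by damped Newton steps with a Gaussian prior.
    """
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    n, R = y.shape
    theta0 = np.asarray(prior_mean, float).copy()
    d = theta0.size
    Pi0 = np.linalg.inv(np.asarray(prior_cov, float))
    sign0, logdet_prior = np.linalg.slogdet(prior_cov)

    theta = theta0.copy()
    if init_jitter > 0:
        rng = np.random.default_rng(seed)
        theta = theta + init_jitter * np.sqrt(np.diag(prior_cov)) * rng.standard_normal(d)

    if fixed_precision is not None:
        lam = np.log(np.broadcast_to(np.asarray(fixed_precision, float), (R,))).copy()
    else:
        lam = np.full(R, float(noise_prior_mean))

    def evaluate(theta_c, lam_c):
        """Return (F, residual, sse, J, H) at a candidate point, or None on divergence."""
        batch = np.tile(theta_c, (d + 1, 1))
        steps = fd_step * (np.abs(theta_c) + 1.0)
        batch[1:] += np.diag(steps)
        try:
            preds = predict(batch)
        except DivergenceError:
            return None
        if not np.all(np.isfinite(preds)):
            return None
        g0 = preds[0]
        J = (preds[1:] - g0[None]) / steps[:, None, None]  # (d, n, R)
        J = np.moveaxis(J, 0, -1)  # (n, R, d)
        e = y - g0
        sse = np.sum(e**2, axis=0)
        return e, sse, J

    def free_energy(theta_c, lam_c, sse, H):
        pi = np.exp(lam_c)
        ll = float(np.sum(0.5 * n * lam_c - 0.5 * pi * sse)) - 0.5 * n * R * np.log(2 * np.pi)
        dev = theta_c - theta0
        lp = -0.5 * dev @ Pi0 @ dev - 0.5 * (d * np.log(2 * np.pi) + logdet_prior)
        sgn, logdet_H = np.linalg.slogdet(H)
        if sgn <= 0:
            return -np.inf
        F = ll + lp - 0.5 * logdet_H + 0.5 * d * np.log(2 * np.pi)
        if fixed_precision is None:
            # Laplace treatment of the noise log-precisions.
            curv = 0.5 * pi * sse + 1.0 / noise_prior_var
            F += float(
                np.sum(
                    -0.5 * (lam_c - noise_prior_mean) ** 2 / noise_prior_var
                    - 0.5 * np.log(2 * np.pi * noise_prior_var)
                    - 0.5 * np.log(curv)
                    + 0.5 * np.log(2 * np.pi)
                )
            )
        return F

    state = evaluate(theta, lam)
    if state is None:
        raise DivergenceError("forward model diverged at the initial point")
    e, sse, J = state
    pi = np.exp(lam)
    H = _weighted_curvature(J, pi) + Pi0
    F = free_energy(theta, lam, sse, H)
    trace = [F]
    mu_damp = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        improved = False
        # --- Gauss-Newton step on theta ---
        grad = np.einsum("nrd,r,nr->d", J, pi, e, optimize=True) - Pi0 @ (theta - theta0)
        for _retry in range(9):
            Hd = H + mu_damp * np.diag(np.diag(H))
            try:
                delta = np.linalg.solve(Hd, grad)
            except np.linalg.LinAlgError:
                mu_damp = max(4.0, mu_damp * 4.0)
                continue
            cand = theta + delta
            st = evaluate(cand, lam)
            if st is not None:
                e_c, sse_c, J_c = st
                H_c = _weighted_curvature(J_c, pi) + Pi0
                F_c = free_energy(cand, lam, sse_c, H_c)
                if np.isfinite(F_c) and F_c >= F:
                    theta, e, sse, J, H, F = cand, e_c, sse_c, J_c, H_c, F_c
                    mu_damp = mu_damp / 4.0 if mu_damp > 1e-8 else 0.0
                    improved = True
                    break
            mu_damp = max(4.0, mu_damp * 4.0)
        # --- Newton step on noise log-precisions ---
        if fixed_precision is None:
            g_lam = 0.5 * n - 0.5 * np.exp(lam) * sse - (lam - noise_prior_mean) / noise_prior_var
            h_lam = -0.5 * np.exp(lam) * sse - 1.0 / noise_prior_var
            step = -g_lam / h_lam
            scale = 1.0
            for _retry in range(6):
                lam_c = lam + scale * step
                pi_c = np.exp(lam_c)
                H_c = _weighted_curvature(J, pi_c) + Pi0
                F_c = free_energy(theta, lam_c, sse, H_c)
                if np.isfinite(F_c) and F_c >= F:
                    lam, pi, H, F = lam_c, pi_c, H_c, F_c
                    improved = True
                    break
                scale *= 0.5
        trace.append(F)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        if not improved:
            break

    Sigma = np.linalg.inv(H)
    Sigma = 0.5 * (Sigma + Sigma.T)
    sstot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sstot > 0, 1.0 - sse / sstot, np.nan)
    return {
        "mean": theta,
        "cov": Sigma,
        "free_energy": F,
        "trace": np.array(trace),
        "noise_log_precision": lam,
        "n_iterations": it,
        "converged": converged,
        "r2_per_region": r2,
        "residual_sd_per_region": np.sqrt(sse / n),
        "predicted": y - e,
    }


def _make_predictor(spec: NetworkSpec, design: StimulusDesign, priors: PriorSpec):
    """Closure mapping (P, d_model) parameter batches to BOLD predictions."""
    r = spec.n_regions
    a_t, a_s = [], []
    for s in range(r):
        for t in range(r):
            if spec.a_mask[t, s]:
                a_t.append(t)
                a_s.append(s)
    b_j, b_t, b_s = [], [], []
    for j, m in enumerate(spec.b_masks):
        for s in range(r):
            for t in range(r):
                if m[t, s]:
                    b_j.append(j)
                    b_t.append(t)
                    b_s.append(s)
    c_j, c_t = [], []
    for j in range(spec.n_inputs):
        for t in range(r):
            if spec.c_mask[t, j]:
                c_j.append(j)
                c_t.append(t)
    nA, nB, nC = len(a_t), len(b_t), len(c_t)
    n_neuronal = nA + nB + nC
    defaults = np.array([_HEMO_DEFAULTS[h] for h in _HEMO_ORDER])

    def predict(batch: np.ndarray) -> np.ndarray:
        P = batch.shape[0]
        A = np.zeros((P, r, r))
        A[:, a_t, a_s] = batch[:, :nA]
        B = np.zeros((P, spec.n_inputs, r, r))
        B[:, b_j, b_t, b_s] = batch[:, nA : nA + nB]
        C = np.zeros((P, r, spec.n_inputs))
        C[:, c_t, c_j] = batch[:, nA + nB : n_neuronal]
        z = batch[:, n_neuronal:].reshape(P, r, 5)
        scaled = defaults[None, None, :] * np.exp(z)
        hemo = {h: scaled[:, :, k] for k, h in enumerate(_HEMO_ORDER)}
        return simulate_batch(A, B, C, hemo, design)

    return predict


def invert(
    bold: BoldRecord,
    design: StimulusDesign,
    spec: NetworkSpec,
    priors: PriorSpec | None = None,
    options: dict | None = None,
) -> PosteriorFit:
    """Invert the DCM for one subject: Gaussian posterior plus free energy."""
    if priors is None:
        priors = default_priors(spec)
    opts = {"max_iter": 128, "tol": 1e-2, "fd_step": 1e-4, "seed": None, "init_jitter": 0.0}
    if options:
        opts.update(options)
    if bold.y.shape[1] != spec.n_regions:
        raise ValueError("BOLD region count does not match the network spec")
    if bold.y.shape[0] != design.n_scans:
        raise ValueError("BOLD scan count does not match the design")
    d_model = priors.n_model
    predict = _make_predictor(spec, design, priors)
    res = variational_laplace(
        predict,
        bold.y,
        priors.mean[:d_model],
        priors.cov[:d_model, :d_model],
        noise_prior_mean=float(priors.mean[d_model:][0]),
        noise_prior_var=float(np.diag(priors.cov)[d_model:][0]),
        **opts,
    )
    if not res["converged"] and not np.isfinite(res["free_energy"]):
        warnings.warn("inversion failed to reach a finite free energy")
    return PosteriorFit(
        posterior_mean=res["mean"],
        posterior_cov=res["cov"],
        free_energy=res["free_energy"],
        noise_log_precision=res["noise_log_precision"],
        free_energy_trace=res["trace"],
        n_iterations=res["n_iterations"],
        converged=res["converged"],
        r2_per_region=res["r2_per_region"],
        residual_sd_per_region=res["residual_sd_per_region"],
        parameter_names=priors.names[:d_model],
        n_neuronal=priors.n_neuronal,
        predicted=res["predicted"],
    )


def predicted_response(
    fit: PosteriorFit, design: StimulusDesign, spec: NetworkSpec
) -> BoldRecord:
    """Forward simulation at the posterior mean."""
    if not np.all(np.isfinite(fit.posterior_mean)):
        raise ValueError("posterior mean contains non-finite values")
    params = NeuronalParams.from_vector(fit.neuronal_means, spec)
    z = fit.posterior_mean[fit.n_neuronal :].reshape(spec.n_regions, 5)
    defaults = np.array([_HEMO_DEFAULTS[h] for h in _HEMO_ORDER])
    scaled = defaults[None, :] * np.exp(z)
    hemo = HemodynamicParams(
        signal_decay=scaled[:, 0],
        autoregulation=scaled[:, 1],
        transit_time=scaled[:, 2],
        stiffness=np.clip(scaled[:, 3], 1e-6, 1 - 1e-9),
        oxygen_extraction=np.clip(scaled[:, 4], 1e-6, 1 - 1e-9),
    )
    traj = integrate_neuronal(params, design)
    rec = integrate_bold(traj, hemo, design)
    return BoldRecord(y=rec.y, TR=design.TR, region_names=spec.region_names)


def variance_explained(fit: PosteriorFit, bold: BoldRecord):
    """Per-region and pooled R^2 of the fit's prediction against the data."""
    if fit.predicted is None:
        raise ValueError("fit carries no stored prediction")
    y = bold.y
    e = y - fit.predicted
    sstot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    ssres = np.sum(e**2, axis=0)
    if np.any(sstot == 0):
        warnings.warn("zero-variance region: R^2 undefined there")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_region = np.where(sstot > 0, 1.0 - ssres / sstot, np.nan)
    overall = 1.0 - ssres.sum() / sstot.sum() if sstot.sum() > 0 else np.nan
    return per_region, float(overall)


class DCMInverter:
    """Estimator-style wrapper: configure once, `fit` per subject.

    Fitted attributes follow the trailing-underscore convention:
    ``posterior_mean_``, ``posterior_cov_``, ``free_energy_``, ``fit_``.
    """

    def __init__(self, spec: NetworkSpec, design: StimulusDesign,
                 priors: PriorSpec | None = None, **options):
        self.spec = spec
        self.design = design
        self.priors = priors
        self.options = options

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec, "design": self.design, "priors": self.priors,
                **self.options}

    def set_params(self, **params) -> "DCMInverter":
        for k, v in params.items():
            if k in ("spec", "design", "priors"):
                setattr(self, k, v)
            else:
                self.options[k] = v
        return self

    def fit(self, bold: BoldRecord) -> "DCMInverter":
        self.fit_ = invert(bold, self.design, self.spec, self.priors, self.options)
        self.posterior_mean_ = self.fit_.posterior_mean
        self.posterior_cov_ = self.fit_.posterior_cov
        self.free_energy_ = self.fit_.free_energy
        return self

    def predict(self) -> BoldRecord:
        return predicted_response(self.fit_, self.design, self.spec)
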