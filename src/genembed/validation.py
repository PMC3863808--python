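"""Validation statistics for clustering solutions and classifiers.

Categorical external variables: purity and its chance-corrected counterpart,
balanced purity. With clusters Omega = (omega_1, ..., omega_K) and external
classes C = (c_1, ..., c_J),

    purity = (1/n) * sum_k max_j |omega_k ∩ c_j|

and, with xi the fraction of subjects in the largest class,

    bp = (1 - 1/J) * (purity - xi) / (1 - xi) + 1/J

so that perfect agreement scores 1 and a composition-proportional (random)
assignment scores 1/J regardless of class imbalance.

Classifier performance is summarised as balanced accuracy (mean of class-wise
accuracies) with Bayesian significance via the posterior infraliminal
probability: the probability, under independent flat-prior beta-binomial
posteriors for the class-wise accuracies, that the balanced accuracy is at or
below chance.

Continuous external variables are tested with a one-way ANOVA across
clusters, or a multiple linear regression of the external score on the
feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LabelledPartition",
    "BinaryConfusion",
    "purity",
    "balanced_purity",
    "balanced_accuracy",
    "infraliminal_probability",
    "posterior_model_probability",
    "anova_external",
    "regress_external",
    "discriminative_params",
    "wald_compare",
    "set_agreement",
]


@dataclass
class LabelledPartition:
    """A cluster assignment paired with an external categorical variable."""

    cluster_assignments: np.ndarray
    external_classes: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.cluster_assignments)
        c = np.asarray(self.external_classes)
        if a.size == 0 or a.shape != c.shape:
            raise ValueError("assignments and classes must be non-empty and aligned")
        self.cluster_assignments = a
        self.external_classes = c

    @property
    def n(self) -> int:
        return self.cluster_assignments.size

    @property
    def K_classes(self) -> int:
        return np.unique(self.external_classes).size

    @property
    def xi(self) -> float:
        """Degree of imbalance: fraction of subjects in the largest class."""
        _, counts = np.unique(self.external_classes, return_counts=True)
        return counts.max() / self.n


@dataclass
class BinaryConfusion:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for v in (self.tp, self.fn, self.tn, self.fp):
            if v < 0 or int(v) != v:
                raise ValueError("confusion counts must be non-negative integers")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise ValueError("both classes must be non-empty")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def purity(partition: LabelledPartition) -> float:
    """Fraction of subjects matching the majority class of their cluster."""
    total = 0
    for k in np.unique(partition.cluster_assignments):
        mask = partition.cluster_assignments == k
        _, counts = np.unique(partition.external_classes[mask], return_counts=True)
        total += counts.max()
    return total / partition.n


def balanced_purity(partition: LabelledPartition, literal_form: bool = False) -> float:
    """Chance-corrected purity: 1 for perfect agreement, 1/K for a
    composition-proportional assignment.

    ``literal_form`` switches to the variant that uses 1/n instead of
    1/K_classes in both constants (provided for comparison; it does not
    satisfy the 1/K chance-level anchors).
    """
    if partition.K_classes < 2:
        raise ValueError("balanced purity needs at least two external classes")
    xi = partition.xi
    if xi >= 1.0:
        raise ValueError("single-class external variable (xi = 1)")
    p = purity(partition)
    c = 1.0 / partition.n if literal_form else 1.0 / partition.K_classes
    return (1.0 - c) * (p - xi) / (1.0 - xi) + c


def balanced_accuracy(confusion: BinaryConfusion) -> float:
    """Mean of sensitivity and specificity."""
    sens = confusion.tp / confusion.n_pos
    spec = confusion.tn / confusion.n_neg
    return 0.5 * (sens + spec)


def infraliminal_probability(
    confusion: BinaryConfusion, grid_size: int = 4096
) -> float:
    """P(balanced accuracy <= 1/2) under a flat-prior beta-binomial posterior.

    Class-wise accuracies get independent Beta(k+1, n-k+1) posteriors; the
    probability that their mean is at or below 0.5 is computed by numerical
    convolution on a fixed grid.
    """
    a1 = stats.beta(confusion.tp + 1, confusion.n_pos - confusion.tp + 1)
    a2 = stats.beta(confusion.tn + 1, confusion.n_neg - confusion.tn + 1)
    grid = np.linspace(0.0, 1.0, grid_size)
    # P(A1 + A2 <= 1) = int f1(a) F2(1 - a) da
    integrand = a1.pdf(grid) * a2.cdf(1.0 - grid)
    return float(np.trapezoid(integrand, grid))


def posterior_model_probability(log_bayes_factor: float) -> float:
    """Posterior probability of the favoured model under equal model priors."""
    if not np.isfinite(log_bayes_factor):
        raise ValueError("log Bayes factor must be finite")
    return float(1.0 / (1.0 + np.exp(-log_bayes_factor)))


def anova_external(assignments: np.ndarray, values: np.ndarray):
    """One-way ANOVA of a continuous external variable across clusters.

    Returns (F, (df_between, df_within), p).
    """
    assignments = np.asarray(assignments)
    values = np.asarray(values, float)
    groups = [values[assignments == k] for k in np.unique(assignments)]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 clusters with >= 1 value each")
    if not any(len(g) >= 2 for g in groups):
        raise ValueError("at least one cluster needs >= 2 values")
    n = values.size
    K = len(groups)
    if np.all(values == values[0]):
        warnings.warn("all values identical: F undefined")
        return np.nan, (K - 1, n - K), np.nan
    F, p = stats.f_oneway(*groups)
    return float(F), (K - 1, n - K), float(p)


def regress_external(features: np.ndarray, values: np.ndarray):
    """OLS of an external score on a feature matrix (with intercept).

    Returns (R^2, F, (df_model, df_resid), p) where F is the overall test of
    the d slope coefficients on (d, n - d - 1) degrees of freedom.
    """
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(features, float))
    y = np.asarray(values, float)
    n, d = X.shape
    if n <= d + 1:
        raise ValueError("need n > d + 1 observations")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("feature matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    return (
        float(res.rsquared),
        float(res.fvalue),
        (int(res.df_model), int(res.df_resid)),
        float(res.f_pvalue),
    )


def discriminative_params(
    X: np.ndarray, binary_labels: np.ndarray, alpha: float = 0.05
):
    """Pooled-variance two-sample t-tests per feature, Bonferroni-corrected.

    Returns (t_values, raw_p_values, significant_flags); features with zero
    pooled variance get NaN statistics and a False flag.
    """
    X = np.atleast_2d(np.asarray(X, float))
    labels = np.asarray(binary_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    g1 = X[labels == classes[0]]
    g2 = X[labels == classes[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need >= 2 subjects")
    d = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g1, g2, equal_var=True)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn("zero pooled variance in some features; flagged NaN")
    flags = np.where(np.isfinite(p), p < alpha / d, False)
    return t, p, flags


def wald_compare(correct1: int, n1: int, correct2: int, n2: int):
    """Unpaired two-proportion Wald test. Returns (z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1 = correct1 / n1
    p2 = correct2 / n2
    se2 = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if se2 == 0:
        warnings.warn("degenerate proportions: Wald SE undefined")
        return np.nan, np.nan
    z = (p1 - p2) / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def set_agreement(indicator_a: np.ndarray, indicator_b: np.ndarray):
    """Balanced accuracy of one binary indicator predicting another.

    Treats `indicator_a` as a prediction of `indicator_b`; returns
    (balanced_accuracy, infraliminal_probability).
    """
    a = np.asarray(indicator_a).astype(bool)
    b = np.asarray(indicator_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("indicators must cover the same subjects")
    if b.all() or not b.any():
        raise ValueError("target indicator is single-valued")
    conf = BinaryConfusion(
        tp=int(np.sum(a & b)),
        fn=int(np.sum(~a & b)),
        tn=int(np.sum(~a & ~b)),
        fp=int(np.sum(a & ~b)),
    )
    return balanced_accuracy(conf), infraliminal_probability(conf)
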