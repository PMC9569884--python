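"""Multivariate evaluation of marker panels.

Given a standardized marker x sample matrix and the binary outcome, this
module reproduces a classical evaluation battery for small matched
cohorts:

* correlation-matrix PCA (eigenvalues sum to the number of markers) with
  Horn's parallel analysis for component retention;
* binary logistic regression on the first two PC scores;
* complete-linkage hierarchical clustering on 1 - Pearson correlation
  between sample profiles, cut at two clusters;
* Euclidean K-means with k = 2;
* two-class linear discriminant analysis with pooled covariance, Wilks'
  lambda and Bartlett's chi-square approximation.

Cluster/classification quality is reported as misassignment counts per
sampling period, mirroring how pre-diagnosis periods closest to onset are
expected to separate best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

from .io import SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "EvaluationReport",
    "standardize",
    "variance_proportions",
    "pca",
    "parallel_analysis",
    "pc_regression",
    "hierarchical_two_clusters",
    "kmeans_two_clusters",
    "lda_evaluate",
]


def standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-marker z-scores across all samples (mean 0, SD 1, denominator n-1)."""
    sd = values.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        raise ValueError(
            f"zero-variance marker(s) cannot be standardized: {list(values.index[zero])}"
        )
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


def variance_proportions(eigenvalues: np.ndarray, n_variables: int) -> np.ndarray:
    """Proportion of variance per PC under the correlation-matrix convention:
    eigenvalue / number of variables."""
    return np.asarray(eigenvalues, dtype=float) / n_variables


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    proportion_of_variance: np.ndarray
    cumulative_proportion: np.ndarray
    loadings: pd.DataFrame  # marker x PC
    scores: pd.DataFrame  # sample x PC
    n_retained_parallel: int | None = None


@dataclass
class EvaluationReport:
    method: str
    assignments: pd.Series  # predicted condition per sample
    misassigned_total: int
    misassigned_by_period: dict[str, int]
    wilks_lambda: float | None = None
    chi_square_p: float | None = None


def pca(z: pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the marker correlation matrix.

    ``z`` is a standardized marker x sample frame.  Scores are the
    projections of the sample profiles on the eigenvectors; each
    eigenvector's sign is fixed so its largest-magnitude loading is
    positive.  Trailing zero eigenvalues (rank deficiency when markers
    outnumber samples) are retained as zeros.
    """
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("pca requires at least 2 markers and 2 samples")
    n = z.shape[1]
    corr = (z.to_numpy() @ z.to_numpy().T) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    prop = variance_proportions(eigval, z.shape[0])
    pcs = [f"PC{k + 1}" for k in range(len(eigval))]
    return PCAResult(
        eigenvalues=eigval,
        proportion_of_variance=prop,
        cumulative_proportion=np.cumsum(prop),
        loadings=pd.DataFrame(eigvec, index=z.index, columns=pcs),
        scores=pd.DataFrame(z.to_numpy().T @ eigvec, index=z.columns, columns=pcs),
    )


def parallel_analysis(
    z: pd.DataFrame,
    n_iterations: int = 1000,
    percentile: float = 95.0,
    seed: int | None = None,
) -> int:
    """Horn's parallel analysis: number of leading PCs whose eigenvalue
    exceeds the per-rank percentile of eigenvalues from same-shaped
    independent standard-normal data.

    Retention stops at the first non-exceeding component (leading-run
    rule), so a large later eigenvalue cannot resurrect retention.
    """
    if n_iterations < 100:
        logger.warning(
            "parallel analysis with %d iterations is unstable; >= 100 recommended",
            n_iterations,
        )
    p, n = z.shape
    observed = pca(z).eigenvalues
    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_iterations, p))
    for it in range(n_iterations):
        sim = rng.standard_normal((p, n))
        sim = (sim - sim.mean(axis=1, keepdims=True)) / sim.std(axis=1, ddof=1, keepdims=True)
        corr = (sim @ sim.T) / (n - 1)
        vals = np.linalg.eigvalsh(corr)
        null_eigs[it] = vals[::-1]
    thresholds = np.percentile(null_eigs, percentile, axis=0)
    n_retained = 0
    for obs, thr in zip(observed, thresholds):
        if obs > thr:
            n_retained += 1
        else:
            break
    return n_retained


def _misassignment_report(
    method: str, predicted_case: np.ndarray, samples: SampleSheet
) -> EvaluationReport:
    truth = samples.is_case
    wrong = predicted_case != truth
    periods = samples.periods
    by_period = {
        str(p): int(wrong[periods == p].sum()) for p in sorted(set(periods))
    }
    labels = np.where(predicted_case, "NEC", "control")
    return EvaluationReport(
        method=method,
        assignments=pd.Series(labels, index=samples.sample_ids),
        misassigned_total=int(wrong.sum()),
        misassigned_by_period=by_period,
    )


def pc_regression(scores: pd.DataFrame, samples: SampleSheet) -> EvaluationReport:
    """Logistic regression of the outcome on the first two PC scores.

    A small ridge penalty keeps the fit defined under complete separation;
    classification threshold is probability 0.5.
    """
    X = scores.iloc[:, :2].to_numpy()
    y = samples.is_case.astype(int)
    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
    model.fit(X, y)
    predicted = model.predict_proba(X)[:, 1] >= 0.5
    return _misassignment_report("pc_regression", predicted, samples)


def _majority_map(cluster_ids: np.ndarray, samples: SampleSheet) -> np.ndarray:
    """Map the 2-cluster solution onto conditions, minimizing misassignments.

    Equivalent to majority voting per cluster; when both mappings tie, the
    first is kept, which charges the errors to the smaller class.
    """
    truth = samples.is_case
    option_a = cluster_ids == 1  # cluster 1 -> NEC
    option_b = cluster_ids == 2
    errors_a = int((option_a != truth).sum())
    errors_b = int((option_b != truth).sum())
    return option_a if errors_a <= errors_b else option_b


def hierarchical_two_clusters(z: pd.DataFrame, samples: SampleSheet) -> EvaluationReport:
    """Complete-linkage clustering of samples on 1 - Pearson r, cut at 2."""
    if z.shape[1] < 3:
        raise ValueError("hierarchical clustering requires at least 3 samples")
    profiles = z.to_numpy().T
    if np.any(profiles.std(axis=1) == 0):
        raise ValueError("constant sample profile: correlation distance undefined")
    corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    merge = linkage(squareform(dist, checks=False), method="complete")
    clusters = fcluster(merge, t=2, criterion="maxclust")
    predicted = _majority_map(clusters, samples)
    return _misassignment_report("hierarchical", predicted, samples)


def kmeans_two_clusters(
    z: pd.DataFrame, samples: SampleSheet, seed: int | None = None, n_restarts: int = 10
) -> EvaluationReport:
    """Euclidean K-means (k = 2), best of ``n_restarts`` by within-cluster SS."""
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    clusters = km.fit_predict(z.to_numpy().T) + 1
    predicted = _majority_map(clusters, samples)
    return _misassignment_report("kmeans", predicted, samples)


def lda_evaluate(z: pd.DataFrame, samples: SampleSheet) -> EvaluationReport:
    """Two-class LDA with pooled covariance, resubstitution error and Wilks' lambda.

    Wilks' lambda is 1/(1 + lambda_1) with lambda_1 the single discriminant
    eigenvalue of W^-1 B; its significance uses Bartlett's approximation
    -(n - 1 - (p + g)/2) ln(lambda) on p(g - 1) degrees of freedom.  The
    within-class scatter is inverted by pseudo-inverse when markers
    outnumber samples.
    """
    X = z.to_numpy().T
    y = samples.is_case
    n, p = X.shape
    g = 2
    X1, X0 = X[y], X[~y]
    if len(X1) < 2 or len(X0) < 2:
        raise ValueError("each class needs at least 2 samples")
    m1, m0 = X1.mean(axis=0), X0.mean(axis=0)
    Sw = (X1 - m1).T @ (X1 - m1) + (X0 - m0).T @ (X0 - m0)
    if p >= n - g:
        logger.info("LDA scatter is singular (p=%d >= n-g=%d): pseudo-inverse", p, n - g)
        Sw_inv = np.linalg.pinv(Sw)
    else:
        Sw_inv = np.linalg.inv(Sw)
    d = m1 - m0
    lam1 = (len(X1) * len(X0) / n) * float(d @ Sw_inv @ d)
    wilks = 1.0 / (1.0 + lam1)
    chi2_stat = -(n - 1 - (p + g) / 2.0) * np.log(wilks)
    chi2_p = float(stats.chi2.sf(chi2_stat, df=p * (g - 1)))
    w = Sw_inv @ d
    proj = X @ w
    threshold = 0.5 * (proj[y].mean() + proj[~y].mean())
    predicted = proj > threshold if proj[y].mean() > proj[~y].mean() else proj < threshold
    report = _misassignment_report("lda", predicted, samples)
    report.wilks_lambda = wilks
    report.chi_square_p = chi2_p
    return report
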