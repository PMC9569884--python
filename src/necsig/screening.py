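"""Marker screening cascade for matched case-control quantification matrices.

The screen mirrors a conservative DIA biomarker-discovery recipe:

1. keep protein groups with < 10% missing values across runs
   (>= 38 quantified of 42 in the full cohort);
2. impute missing values as zeros (missingness is treated as absence or
   very low abundance, i.e. MNAR);
3. keep groups whose folded ROC AUC against the outcome is >= 0.7;
4. drop groups whose imputed zeros concentrate in a single class
   (>= 4 within NEC or within control) — such AUCs are imputation
   artifacts rather than quantitative signal;
5. drop groups lacking at least one precursor with >= 35 quantified
   values (weak precursor-level support);
6. cap redundant protein groups sharing a protein/gene entry at two,
   keeping the highest-AUC representatives.

Per-marker statistics (folded AUC and direction, fold-change ratio,
Mann-Whitney p, Benjamini-Krieger-Yekutieli two-stage q) are computed for
every group surviving step 1; the later gates are recorded per group in
``passed_filters`` rather than silently removing rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PrecursorMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningThresholds",
    "MarkerStats",
    "filter_missingness",
    "impute_zeros",
    "folded_auc",
    "mann_whitney_p",
    "bky_fdr",
    "fold_change_ratio",
    "screen_markers",
    "candidate_set",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    """Gates of the screening cascade (defaults are the study's)."""

    max_missing_fraction: float = 0.10
    auc_min: float = 0.70
    imputed_zero_class_max: int = 4
    min_precursor_quantified: int = 35
    redundancy_cap: int = 2


class FoldedAuc(NamedTuple):
    auc: float
    direction: str


@dataclass
class MarkerStats:
    """Screening record for one protein group."""

    protein_id: str
    direction: str
    auc: float
    fold_change: float
    p_value: float
    q_value: float
    n_quantified: int
    n_imputed_nec: int
    n_imputed_control: int
    passed_auc: bool
    passed_zero_bias: bool
    passed_precursor: bool
    passed_redundancy: bool

    @property
    def passed(self) -> bool:
        return (
            self.passed_auc
            and self.passed_zero_bias
            and self.passed_precursor
            and self.passed_redundancy
        )


def missingness_quantified_threshold(n_samples: int, max_missing_fraction: float = 0.10) -> int:
    """Smallest quantified count satisfying missing/n < max_missing_fraction.

    The bound is strict, so a row missing exactly the fraction is dropped
    (42 samples at 10% -> at most 4 missing, i.e. >= 38 quantified).  A
    tiny tolerance guards the integer arithmetic against float rounding.
    """
    max_missing = math.ceil(max_missing_fraction * n_samples - 1e-9) - 1
    return n_samples - max_missing


def filter_missingness(
    matrix: ExpressionMatrix, max_missing_fraction: float = 0.10
) -> ExpressionMatrix:
    """Keep rows whose missing fraction is strictly below the bound."""
    n = matrix.n_samples
    min_quant = missingness_quantified_threshold(n, max_missing_fraction)
    keep = (~matrix.missing_mask).sum(axis=1) >= min_quant
    logger.info(
        "missingness filter: kept %d of %d protein groups (quantified >= %d of %d)",
        int(keep.sum()),
        matrix.n_groups,
        missingness_quantified_threshold(n, max_missing_fraction),
        n,
    )
    return matrix.subset_rows(np.flatnonzero(keep))


def impute_zeros(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace missing cells by 0.0, retaining the mask for bookkeeping."""
    values = matrix.values.copy()
    values[matrix.missing_mask] = 0.0
    return ExpressionMatrix(
        protein_ids=matrix.protein_ids,
        gene_symbols=matrix.gene_symbols,
        sample_ids=list(matrix.sample_ids),
        values=values,
        missing_mask=matrix.missing_mask.copy(),
        annotations=matrix.annotations,
    )


def folded_auc(values: np.ndarray, is_case: np.ndarray) -> FoldedAuc:
    """Folded ROC AUC of one marker with the orientation carried separately.

    The raw AUC is P(case > control) + 0.5 P(tie), computed from the
    rank-sum statistic with case as the positive class; the returned AUC is
    max(raw, 1 - raw) and the direction is "up" when raw >= 0.5.
    """
    values = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    n1 = int(is_case.sum())
    n0 = len(is_case) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("folded_auc requires both classes to be non-empty")
    ranks = stats.rankdata(values)
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    raw = u / (n1 * n0)
    if raw >= 0.5:
        return FoldedAuc(auc=raw, direction="up")
    return FoldedAuc(auc=1.0 - raw, direction="down")


def mann_whitney_p(values: np.ndarray, is_case: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for combined n <= 12 without ties,
    normal approximation with tie correction otherwise."""
    values = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    x, y = values[is_case], values[~is_case]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney_p requires both classes to be non-empty")
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(values) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bky_fdr(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Krieger-Yekutieli two-stage step-up adjusted q-values.

    Stage 1 runs Benjamini-Hochberg at alpha/(1+alpha) to estimate the
    number of true nulls m0; stage 2 rescales the step-up accordingly.  The
    returned q-values are specific to ``alpha`` and satisfy ``q <= alpha``
    exactly for the hypotheses the two-stage procedure rejects.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_tsbky")
    return q


def fold_change_ratio(values: np.ndarray, is_case: np.ndarray) -> float:
    """mean(case) / mean(control) on the zero-imputed values; inf if the
    control mean is zero."""
    values = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    mean_ctrl = values[~is_case].mean()
    mean_case = values[is_case].mean()
    if mean_ctrl == 0:
        logger.warning("control mean is zero: fold change flagged infinite")
        return math.inf
    return mean_case / mean_ctrl


def _redundancy_filter(
    stats_list: list[MarkerStats],
    gene_by_id: dict[str, str],
    cap: int,
) -> None:
    """Cap protein groups sharing any gene entry, keeping the highest AUC.

    Ties break by smaller p then lexicographic id.  Only groups that passed
    the earlier gates compete; losers get ``passed_redundancy = False``.
    """
    contenders = [s for s in stats_list if s.passed_auc and s.passed_zero_bias and s.passed_precursor]
    by_token: dict[str, list[MarkerStats]] = {}
    for s in contenders:
        for token in str(gene_by_id.get(s.protein_id, "")).split(";"):
            token = token.strip()
            if token:
                by_token.setdefault(token, []).append(s)
    dropped: set[str] = set()
    for token, members in sorted(by_token.items()):
        if len(members) <= cap:
            continue
        members = sorted(members, key=lambda s: (-s.auc, s.p_value, s.protein_id))
        for s in members[cap:]:
            dropped.add(s.protein_id)
            logger.debug(
                "redundancy cap: dropping %s (shares entry %s)", s.protein_id, token
            )
    for s in stats_list:
        if s.protein_id in dropped:
            s.passed_redundancy = False


def screen_markers(
    pg: ExpressionMatrix,
    pr: PrecursorMatrix | None,
    samples: SampleSheet,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> list[MarkerStats]:
    """Run the full screening cascade and return per-group statistics.

    The returned list covers every protein group surviving the missingness
    filter, sorted by protein id; the candidate marker set is the subset
    with all ``passed_*`` flags true (see :func:`candidate_set`).  When
    ``pr`` is None the precursor-support gate passes trivially.
    """
    if list(pg.sample_ids) != samples.sample_ids:
        raise ValueError("protein matrix sample order does not match the sample sheet")
    is_case = samples.is_case

    kept = filter_missingness(pg, thresholds.max_missing_fraction)
    imputed = impute_zeros(kept)
    best_prec = pr.max_quantified_by_protein() if pr is not None else None

    results: list[MarkerStats] = []
    order = np.argsort(kept.protein_ids)
    for i in order:
        vals = imputed.values[i]
        mask = imputed.missing_mask[i]
        auc, direction = folded_auc(vals, is_case)
        n_imp_nec = int(mask[is_case].sum())
        n_imp_ctrl = int(mask[~is_case].sum())
        if best_prec is None:
            prec_ok = True
        else:
            prec_ok = best_prec.get(kept.protein_ids[i], 0) >= thresholds.min_precursor_quantified
        results.append(
            MarkerStats(
                protein_id=str(kept.protein_ids[i]),
                direction=direction,
                auc=float(auc),
                fold_change=fold_change_ratio(vals, is_case),
                p_value=mann_whitney_p(vals, is_case),
                q_value=np.nan,
                n_quantified=int((~mask).sum()),
                n_imputed_nec=n_imp_nec,
                n_imputed_control=n_imp_ctrl,
                passed_auc=auc >= thresholds.auc_min,
                passed_zero_bias=max(n_imp_nec, n_imp_ctrl) < thresholds.imputed_zero_class_max,
                passed_precursor=prec_ok,
                passed_redundancy=True,
            )
        )
    q = bky_fdr([s.p_value for s in results])
    for s, qv in zip(results, q):
        s.q_value = float(qv)
    gene_by_id = dict(zip(kept.protein_ids, kept.gene_symbols))
    _redundancy_filter(results, gene_by_id, thresholds.redundancy_cap)
    n_pass = sum(s.passed for s in results)
    logger.info(
        "screen: %d candidate markers of %d groups past the missingness filter",
        n_pass,
        len(results),
    )
    return results


def candidate_set(stats_list: Sequence[MarkerStats]) -> list[MarkerStats]:
    """Markers passing every gate of the cascade."""
    return [s for s in stats_list if s.passed]
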