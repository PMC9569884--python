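"""Composite disease-signature scoring.

Three layers, all built on the same cohort-wide standardization:

* Rankit normal scores Phi^-1((rank - 0.5)/n) per marker, the bounded
  normalization used for heatmap display (range +/-2.26 at n = 42);
* the per-sample relative score: mean z over up markers plus (-1) times
  the mean z over down markers — positive scores indicate a case-like
  profile;
* inference on the scores: a two-tailed paired t test per matched pair
  (pairing the direction-adjusted marker z-values of the case sample with
  its matched control, pooled across periods) and a one-way ANOVA with
  Dunnett many-to-one comparisons of each pre-diagnosis period against
  the pooled control group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSheet
from .panels import MarkerPanel

logger = logging.getLogger(__name__)

__all__ = [
    "rankit_normalize",
    "rankit_matrix",
    "relative_score",
    "paired_t_by_pair",
    "dunnett_by_period",
    "PeriodComparison",
]


def rankit_normalize(values: np.ndarray) -> np.ndarray:
    """Rankit normal scores of one marker across n samples.

    Ranks (average ranks for ties) map through the Hazen plotting position
    r -> Phi^-1((r - 0.5)/n), bounding scores at +/- Phi^-1((n - 0.5)/n).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("rankit_normalize requires at least one value")
    ranks = stats.rankdata(values)
    return stats.norm.ppf((ranks - 0.5) / n)


def rankit_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Rankit normalization of a marker x sample frame."""
    out = np.vstack([rankit_normalize(row) for row in values.to_numpy()])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def relative_score(z: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Per-sample signature scores from a standardized marker frame.

    Returns a frame indexed by sample with columns ``mean_z_up``,
    ``mean_z_down`` and ``relative_score = mean_z_up - mean_z_down``.
    """
    if not panel.up_ids or not panel.down_ids:
        raise ValueError("relative_score requires both panel arms to be non-empty")
    missing = [m for m in panel.ids if m not in z.index]
    if missing:
        raise KeyError(f"panel marker(s) absent from matrix: {missing}")
    mean_up = z.loc[panel.up_ids].mean(axis=0)
    mean_down = z.loc[panel.down_ids].mean(axis=0)
    return pd.DataFrame(
        {
            "mean_z_up": mean_up,
            "mean_z_down": mean_down,
            "relative_score": mean_up - mean_down,
        }
    )


def paired_t_by_pair(
    z: pd.DataFrame, panel: MarkerPanel, samples: SampleSheet
) -> pd.DataFrame:
    """Two-tailed paired t test per matched pair on direction-adjusted z-values.

    For each pair, the case sample's direction-adjusted marker z-values
    (down markers multiplied by -1) are paired with its matched control's
    at the same period, pooled across the pair's periods (36 markers x 3
    periods = 108 paired differences in the full design).  All-zero
    differences are reported as t = 0, p = 1 with a degenerate flag.
    """
    sign = pd.Series(
        {m: -1.0 if d == "down" else 1.0 for m, d in panel.directions.items()}
    )
    adjusted = z.loc[panel.ids].mul(sign.loc[panel.ids], axis=0)
    frame = samples.to_frame().set_index("sample_id")
    rows = []
    for pair in sorted(set(samples.pair_ids)):
        sub = frame[frame["pair_id"] == pair]
        case_by_period = sub[sub["condition"] == "NEC"]["period"]
        ctrl_by_period = sub[sub["condition"] == "control"]["period"]
        periods = sorted(set(case_by_period) & set(ctrl_by_period))
        if not periods:
            raise ValueError(f"pair {pair} lacks matched case/control periods")
        case_vec, ctrl_vec = [], []
        for period in periods:
            cid = case_by_period.index[case_by_period == period][0]
            kid = ctrl_by_period.index[ctrl_by_period == period][0]
            case_vec.append(adjusted[cid].to_numpy())
            ctrl_vec.append(adjusted[kid].to_numpy())
        case_vec = np.concatenate(case_vec)
        ctrl_vec = np.concatenate(ctrl_vec)
        diffs = case_vec - ctrl_vec
        if np.all(diffs == 0):
            t_stat, p_val, degenerate = 0.0, 1.0, True
        else:
            res = stats.ttest_rel(case_vec, ctrl_vec)
            t_stat, p_val, degenerate = float(res.statistic), float(res.pvalue), False
        rows.append(
            {
                "pair_id": pair,
                "t": t_stat,
                "p_value": p_val,
                "n_paired": len(diffs),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PeriodComparison:
    """One-way ANOVA across {pooled control, case period groups} with
    Dunnett-adjusted many-to-one p-values per period."""

    f_statistic: float
    anova_p: float
    periods: list[str]
    adjusted_p: dict[str, float]
    group_means: dict[str, float]


def dunnett_by_period(
    scores: pd.Series, samples: SampleSheet, seed: int | None = None
) -> PeriodComparison:
    """Compare each case period's scores against the pooled control group.

    ``scores`` is a per-sample series (typically the relative score).  The
    control group pools all control samples across periods; each case
    period forms one comparison group.  Dunnett's adjustment uses the
    multivariate-t distribution (seeded for reproducibility).
    """
    scores = scores.loc[samples.sample_ids]
    is_case = samples.is_case
    periods = sorted(set(samples.periods))
    control = scores.to_numpy()[~is_case]
    case_groups = [
        scores.to_numpy()[is_case & (samples.periods == p)] for p in periods
    ]
    if len(control) < 2 or any(len(gr) < 2 for gr in case_groups):
        raise ValueError("every comparison group needs at least 2 samples")
    f_stat, anova_p = stats.f_oneway(control, *case_groups)
    res = stats.dunnett(
        *case_groups,
        control=control,
        random_state=np.random.default_rng(seed),
    )
    means = {"control": float(control.mean())}
    means.update({p: float(gr.mean()) for p, gr in zip(periods, case_groups)})
    return PeriodComparison(
        f_statistic=float(f_stat),
        anova_p=float(anova_p),
        periods=periods,
        adjusted_p={p: float(pv) for p, pv in zip(periods, res.pvalue)},
        group_means=means,
    )
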