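"""Nested marker-panel construction via communal ROC curves.

A panel is a balanced, direction-partitioned marker subset (e.g. 18 up +
18 down).  Candidate impact is judged arm-wise through the "communal"
ROC: the folded AUC of a composite score built from the arm's markers.
The composite of a marker set is the per-sample mean of per-marker
z-scores, with down-marker z multiplied by -1, so the communal AUC and
the downstream relative score share one standardization.

Selection per arm: seed with the best-individual-AUC marker, then greedy
forward steps maximizing the arm's communal AUC until the arm size is
reached.  Panels are requested in descending sizes; each smaller panel is
selected the same way but restricted to its parent's members, yielding a
nested lineage.  Because sizes are fixed a priori, a greedy step that
decreases the communal AUC is still taken (and logged) when every
remaining extension hurts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screening import MarkerStats, folded_auc

logger = logging.getLogger(__name__)

__all__ = ["MarkerPanel", "composite_score", "communal_auc", "select_nested_panels"]


@dataclass
class MarkerPanel:
    """Balanced marker subset with its nesting lineage and communal AUCs."""

    up_ids: list[str]
    down_ids: list[str]
    parent: "MarkerPanel | None" = None
    communal_auc_up: float = np.nan
    communal_auc_down: float = np.nan
    communal_auc_combined: float = np.nan

    @property
    def size(self) -> int:
        return len(self.up_ids) + len(self.down_ids)

    @property
    def ids(self) -> list[str]:
        return list(self.up_ids) + list(self.down_ids)

    @property
    def directions(self) -> dict[str, str]:
        d = {m: "up" for m in self.up_ids}
        d.update({m: "down" for m in self.down_ids})
        return d


def _zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        dropped = list(frame.index[zero_var])
        warnings.warn(f"excluding zero-variance marker(s) from composite: {dropped}")
        frame = frame.loc[~zero_var]
        sd = sd.loc[~zero_var]
    return frame.sub(frame.mean(axis=1), axis=0).div(sd, axis=0)


def composite_score(
    values: pd.DataFrame, ids: Sequence[str], directions: Mapping[str, str]
) -> pd.Series:
    """Per-sample mean of direction-adjusted marker z-scores.

    ``values`` is a protein x sample abundance frame (zero-imputed);
    down-marker z-scores enter with a flipped sign.  Zero-variance markers
    are excluded with a warning; an all-excluded set yields zeros.
    """
    if len(ids) == 0:
        raise ValueError("composite_score requires at least one marker")
    missing = [m for m in ids if m not in values.index]
    if missing:
        raise KeyError(f"marker(s) absent from matrix: {missing}")
    z = _zscore_rows(values.loc[list(ids)])
    if z.empty:
        return pd.Series(0.0, index=values.columns)
    sign = pd.Series({m: -1.0 if directions[m] == "down" else 1.0 for m in z.index})
    return z.mul(sign, axis=0).mean(axis=0)


def communal_auc(
    values: pd.DataFrame,
    ids: Sequence[str],
    directions: Mapping[str, str],
    is_case: np.ndarray,
) -> float:
    """Folded AUC of the composite score against the outcome."""
    score = composite_score(values, ids, directions)
    return folded_auc(score.to_numpy(), is_case).auc


def _greedy_arm(
    values: pd.DataFrame,
    candidates: list[MarkerStats],
    direction: str,
    arm_size: int,
    is_case: np.ndarray,
) -> list[str]:
    """Seed with the best individual AUC, then grow by communal-AUC impact."""
    if len(candidates) < arm_size:
        raise ValueError(
            f"insufficient {direction} candidates: need {arm_size}, have {len(candidates)}"
        )
    stats_by_id = {s.protein_id: s for s in candidates}
    # deterministic candidate order: individual AUC desc, p asc, id asc
    ordered = sorted(candidates, key=lambda s: (-s.auc, s.p_value, s.protein_id))
    chosen = [ordered[0].protein_id]
    remaining = [s.protein_id for s in ordered[1:]]
    directions = {s.protein_id: direction for s in candidates}
    current_auc = communal_auc(values, chosen, directions, is_case)
    while len(chosen) < arm_size:
        best_id, best_auc = None, -np.inf
        for cand in remaining:
            auc = communal_auc(values, chosen + [cand], directions, is_case)
            # strict > keeps the earlier (better individual AUC / p / id) on ties
            if auc > best_auc:
                best_id, best_auc = cand, auc
        if best_auc < current_auc:
            logger.info(
                "greedy step decreased the %s-arm communal AUC (%.4f -> %.4f) "
                "while filling the requested size",
                direction,
                current_auc,
                best_auc,
            )
        chosen.append(best_id)
        remaining.remove(best_id)
        current_auc = best_auc
    return chosen


def select_nested_panels(
    stats_list: Sequence[MarkerStats],
    values: pd.DataFrame,
    is_case: np.ndarray,
    sizes: Sequence[int] = (36, 20, 14),
) -> list[MarkerPanel]:
    """Build nested balanced panels of the given descending even sizes.

    ``stats_list`` supplies the candidate markers (only those passing the
    full screen are used) and their individual AUCs; ``values`` is the
    protein x sample abundance frame the composites are scored on.
    """
    sizes = list(sizes)
    if any(s % 2 for s in sizes):
        raise ValueError("panel sizes must be even (balanced up/down arms)")
    if sizes != sorted(sizes, reverse=True):
        raise ValueError("panel sizes must be descending")
    candidates = [s for s in stats_list if s.passed]
    arms = {
        "up": [s for s in candidates if s.direction == "up"],
        "down": [s for s in candidates if s.direction == "down"],
    }
    panels: list[MarkerPanel] = []
    parent: MarkerPanel | None = None
    for size in sizes:
        half = size // 2
        pools = arms if parent is None else {
            d: [s for s in arms[d] if s.protein_id in set(getattr(parent, f"{d}_ids"))]
            for d in ("up", "down")
        }
        up = _greedy_arm(values, pools["up"], "up", half, is_case)
        down = _greedy_arm(values, pools["down"], "down", half, is_case)
        panel = MarkerPanel(up_ids=up, down_ids=down, parent=parent)
        dirs = panel.directions
        panel.communal_auc_up = communal_auc(values, up, dirs, is_case)
        panel.communal_auc_down = communal_auc(values, down, dirs, is_case)
        panel.communal_auc_combined = communal_auc(values, panel.ids, dirs, is_case)
        panels.append(panel)
        parent = panel
    return panels


def panels_to_frame(panels: Sequence[MarkerPanel]) -> pd.DataFrame:
    """Long-format table of panel membership for writing to disk."""
    rows = []
    for panel in panels:
        for direction, ids in (("up", panel.up_ids), ("down", panel.down_ids)):
            for rank, pid in enumerate(ids):
                rows.append(
                    {
                        "panel_size": panel.size,
                        "direction": direction,
                        "rank": rank,
                        "protein_id": pid,
                        "communal_auc_up": panel.communal_auc_up,
                        "communal_auc_down": panel.communal_auc_down,
                        "communal_auc_combined": panel.communal_auc_combined,
                    }
                )
    return pd.DataFrame(rows)


def panels_from_frame(frame: pd.DataFrame) -> list[MarkerPanel]:
    """Rebuild panels (largest to smallest) from :func:`panels_to_frame` output."""
    panels = []
    parent = None
    for size in sorted(frame["panel_size"].unique(), reverse=True):
        sub = frame[frame["panel_size"] == size].sort_values("rank")
        panel = MarkerPanel(
            up_ids=list(sub[sub["direction"] == "up"]["protein_id"]),
            down_ids=list(sub[sub["direction"] == "down"]["protein_id"]),
            parent=parent,
            communal_auc_up=float(sub["communal_auc_up"].iloc[0]),
            communal_auc_down=float(sub["communal_auc_down"].iloc[0]),
            communal_auc_combined=float(sub["communal_auc_combined"].iloc[0]),
        )
        panels.append(panel)
        parent = panel
    return panels
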