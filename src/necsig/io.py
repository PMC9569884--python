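"""Reading and writing of DIA-NN-style quantification matrices and sample sheets.

DIA-NN emits two wide TSV tables per experiment: a protein-group matrix
(``pg_matrix``) with one abundance column per run, and a precursor matrix
(``pr_matrix``) keyed by precursor with a parent protein-group column.
Annotation columns (``Protein.Group``, ``Genes``, ...) precede the run
columns.  Empty or non-numeric abundance cells mean the precursor/protein
was not quantified in that run; a literal ``0`` is read as a quantified
zero (downstream screening, not the reader, performs zero imputation).

Sample metadata lives in a small CSV with columns ``sample_id``,
``condition`` (NEC or control), ``pair_id`` and ``period``; the sheet, not
the file column order, fixes the sample order used everywhere downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: annotation column names of the DIA-NN matrix convention, lower-cased
_PG_ANNOTATION = (
    "protein.group",
    "protein.ids",
    "protein.names",
    "genes",
    "first.protein.description",
)
_PR_ANNOTATION = _PG_ANNOTATION + (
    "precursor.id",
    "modified.sequence",
    "stripped.sequence",
    "precursor.charge",
    "proteotypic",
)

CONDITIONS = ("NEC", "control")


class CohortIOError(ValueError):
    """Raised when a quantification matrix or sample sheet is malformed."""


@dataclass(frozen=True)
class SampleAnnotation:
    """One run: its outcome, matched-pair membership and sampling period."""

    sample_id: str
    condition: str
    pair_id: int
    period: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise CohortIOError(
                f"sample {self.sample_id!r}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )


class SampleSheet:
    """Ordered collection of :class:`SampleAnnotation` records.

    A complete matched cohort has every (pair, condition, period)
    combination exactly once (e.g. 7 pairs x 2 conditions x 3 periods = 42
    runs); partial sheets are allowed but each combination may appear at
    most once.
    """

    def __init__(self, annotations: Iterable[SampleAnnotation]):
        self.annotations: list[SampleAnnotation] = list(annotations)
        if not self.annotations:
            raise CohortIOError("sample sheet is empty")
        ids = [a.sample_id for a in self.annotations]
        if len(set(ids)) != len(ids):
            raise CohortIOError("duplicated sample_id in sample sheet")
        combos = [(a.pair_id, a.condition, a.period) for a in self.annotations]
        if len(set(combos)) != len(combos):
            raise CohortIOError(
                "duplicated (pair_id, condition, period) combination in sample sheet"
            )

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotations]

    @property
    def conditions(self) -> np.ndarray:
        return np.array([a.condition for a in self.annotations])

    @property
    def is_case(self) -> np.ndarray:
        """Boolean outcome vector, True for NEC runs."""
        return self.conditions == "NEC"

    @property
    def pair_ids(self) -> np.ndarray:
        return np.array([a.pair_id for a in self.annotations])

    @property
    def periods(self) -> np.ndarray:
        return np.array([a.period for a in self.annotations])

    def is_complete(self) -> bool:
        pairs = sorted(set(a.pair_id for a in self.annotations))
        periods = sorted(set(a.period for a in self.annotations))
        return len(self) == len(pairs) * 2 * len(periods)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "condition": self.conditions,
                "pair_id": self.pair_ids,
                "period": self.periods,
            }
        )


@dataclass
class ExpressionMatrix:
    """Protein-group x sample abundance table with an explicit missingness mask.

    ``values`` holds linear-scale normalized intensities with ``NaN`` at
    masked positions; ``missing_mask`` is the authoritative record of which
    cells were not quantified.
    """

    protein_ids: np.ndarray
    gene_symbols: np.ndarray
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_groups, n_samples = self.values.shape
        if self.missing_mask.shape != self.values.shape:
            raise CohortIOError("values and missing_mask dimensions differ")
        if len(self.protein_ids) != n_groups or len(self.gene_symbols) != n_groups:
            raise CohortIOError("annotation length does not match value rows")
        if len(self.sample_ids) != n_samples:
            raise CohortIOError("sample_ids length does not match value columns")
        if len(set(self.protein_ids)) != n_groups:
            raise CohortIOError("duplicated protein-group id")
        present = self.values[~self.missing_mask]
        if present.size and (np.isnan(present).any() or (present < 0).any()):
            raise CohortIOError("non-missing abundance values must be finite and >= 0")

    @property
    def n_groups(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def n_quantified(self) -> np.ndarray:
        """Quantified-value count per protein group."""
        return (~self.missing_mask).sum(axis=1)

    def subset_rows(self, row_index: np.ndarray) -> "ExpressionMatrix":
        ann = self.annotations.iloc[row_index].reset_index(drop=True) if self.annotations is not None else None
        return ExpressionMatrix(
            protein_ids=self.protein_ids[row_index],
            gene_symbols=self.gene_symbols[row_index],
            sample_ids=list(self.sample_ids),
            values=self.values[row_index],
            missing_mask=self.missing_mask[row_index],
            annotations=ann,
        )

    def imputed_values(self) -> np.ndarray:
        """Values with missing cells replaced by zero (MNAR convention)."""
        out = self.values.copy()
        out[self.missing_mask] = 0.0
        return out

    def to_frame(self, imputed: bool = False) -> pd.DataFrame:
        vals = self.imputed_values() if imputed else self.values
        return pd.DataFrame(vals, index=pd.Index(self.protein_ids, name="protein_id"), columns=self.sample_ids)


@dataclass
class PrecursorMatrix:
    """Precursor x sample abundance table with parent protein-group links."""

    precursor_ids: np.ndarray
    parent_protein_ids: np.ndarray
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    orphan_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.precursor_ids = np.asarray(self.precursor_ids, dtype=object)
        self.parent_protein_ids = np.asarray(self.parent_protein_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise CohortIOError("values and missing_mask dimensions differ")
        if len(set(self.precursor_ids)) != len(self.precursor_ids):
            raise CohortIOError("duplicated precursor id")
        if self.orphan_mask is None:
            self.orphan_mask = np.zeros(len(self.precursor_ids), dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def n_quantified(self) -> np.ndarray:
        return (~self.missing_mask).sum(axis=1)

    def max_quantified_by_protein(self) -> dict[str, int]:
        """Best per-precursor quantified count for each parent protein group."""
        counts = self.n_quantified()
        best: dict[str, int] = {}
        for parent, c in zip(self.parent_protein_ids, counts):
            if best.get(parent, -1) < c:
                best[parent] = int(c)
        return best


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read the cohort sample sheet CSV (sample_id, condition, pair_id, period)."""
    table = pd.read_csv(path, dtype={"sample_id": str, "condition": str, "period": str})
    required = {"sample_id", "condition", "pair_id", "period"}
    missing = required - set(table.columns)
    if missing:
        raise CohortIOError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    return SampleSheet(
        SampleAnnotation(
            sample_id=row.sample_id,
            condition=row.condition,
            pair_id=int(row.pair_id),
            period=row.period,
        )
        for row in table.itertuples()
    )


def _split_columns(columns: Sequence[str], known_annotation: tuple[str, ...], samples: SampleSheet):
    """Partition header columns into annotation vs run columns, case-insensitively."""
    wanted = set(samples.sample_ids)
    ann_cols, run_cols = [], {}
    for col in columns:
        if col.lower() in known_annotation:
            ann_cols.append(col)
        elif col in wanted:
            run_cols[col] = col
        else:
            logger.debug("ignoring unrecognized column %r", col)
    missing_runs = [s for s in samples.sample_ids if s not in run_cols]
    if missing_runs:
        raise CohortIOError(
            f"run column(s) missing for annotated sample(s): {missing_runs}"
        )
    return ann_cols, [run_cols[s] for s in samples.sample_ids]


def _find_column(ann_cols: Sequence[str], name: str) -> str | None:
    for col in ann_cols:
        if col.lower() == name:
            return col
    return None


def _parse_cell(token) -> float:
    # correctly-rounded parse; empty/non-numeric tokens become NaN (missing)
    try:
        return float(token)
    except (TypeError, ValueError):
        return math.nan


def _numeric_block(table: pd.DataFrame, run_cols: Sequence[str]):
    values = table[run_cols].map(_parse_cell).to_numpy(dtype=float)
    mask = np.isnan(values)
    return values, mask


def read_pg_matrix(path: str | Path, samples: SampleSheet) -> ExpressionMatrix:
    """Read a DIA-NN protein-group matrix restricted to the sheet's runs.

    The returned matrix contains exactly the sheet's samples, in sheet
    order.  Empty and non-numeric cells become missing; duplicated
    protein-group ids and absent run columns are hard errors.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    ann_cols, run_cols = _split_columns(table.columns, _PG_ANNOTATION, samples)
    id_col = _find_column(ann_cols, "protein.group")
    if id_col is None:
        raise CohortIOError(f"{path}: no Protein.Group column found")
    gene_col = _find_column(ann_cols, "genes")
    values, mask = _numeric_block(table, run_cols)
    genes = (
        table[gene_col].fillna("").to_numpy(dtype=object)
        if gene_col is not None
        else np.array([""] * len(table), dtype=object)
    )
    return ExpressionMatrix(
        protein_ids=table[id_col].to_numpy(dtype=object),
        gene_symbols=genes,
        sample_ids=samples.sample_ids,
        values=values,
        missing_mask=mask,
        annotations=table[ann_cols].copy(),
    )


def read_pr_matrix(
    path: str | Path, samples: SampleSheet, pg: ExpressionMatrix | None = None
) -> PrecursorMatrix:
    """Read a DIA-NN precursor matrix; flag precursors whose parent is absent from ``pg``."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    ann_cols, run_cols = _split_columns(table.columns, _PR_ANNOTATION, samples)
    id_col = _find_column(ann_cols, "precursor.id")
    parent_col = _find_column(ann_cols, "protein.group")
    if id_col is None or parent_col is None:
        raise CohortIOError(f"{path}: Precursor.Id and Protein.Group columns are required")
    values, mask = _numeric_block(table, run_cols)
    parents = table[parent_col].to_numpy(dtype=object)
    orphan = np.zeros(len(table), dtype=bool)
    if pg is not None:
        known = set(pg.protein_ids)
        orphan = np.array([p not in known for p in parents])
        if orphan.any():
            logger.warning(
                "%d precursor(s) have parents absent from the protein-group matrix",
                int(orphan.sum()),
            )
    return PrecursorMatrix(
        precursor_ids=table[id_col].to_numpy(dtype=object),
        parent_protein_ids=parents,
        sample_ids=samples.sample_ids,
        values=values,
        missing_mask=mask,
        orphan_mask=orphan,
    )


def _matrix_frame(ids_block: Mapping[str, Sequence], values: np.ndarray, mask: np.ndarray, sample_ids: Sequence[str]) -> pd.DataFrame:
    frame = pd.DataFrame(dict(ids_block))
    vals = values.astype(object)
    vals[mask] = ""
    for j, sid in enumerate(sample_ids):
        frame[sid] = [v if v == "" else repr(float(v)) for v in vals[:, j]]
    return frame


def write_pg_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an :class:`ExpressionMatrix` back to DIA-NN pg_matrix layout."""
    frame = _matrix_frame(
        {
            "Protein.Group": matrix.protein_ids,
            "Genes": matrix.gene_symbols,
        },
        matrix.values,
        matrix.missing_mask,
        matrix.sample_ids,
    )
    frame.to_csv(path, sep="\t", index=False)


def write_pr_matrix(matrix: PrecursorMatrix, path: str | Path) -> None:
    frame = _matrix_frame(
        {
            "Protein.Group": matrix.parent_protein_ids,
            "Precursor.Id": matrix.precursor_ids,
        },
        matrix.values,
        matrix.missing_mask,
        matrix.sample_ids,
    )
    frame.to_csv(path, sep="\t", index=False)


def write_sample_sheet(samples: SampleSheet, path: str | Path) -> None:
    samples.to_frame().to_csv(path, index=False)


def write_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records (dataclasses, dicts or a DataFrame) as a TSV.

    Column order is stable (first record's field order, or ``columns``);
    floats keep full precision so the table is losslessly re-readable.  An
    empty record list yields a header-only file (pass ``columns`` to name
    the header fields).
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = list(records)
        dicts = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                dicts.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                dicts.append(dict(r))
        frame = pd.DataFrame(dicts, columns=columns if (columns or not dicts) else None)
    frame.to_csv(path, sep="\t", index=False)
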