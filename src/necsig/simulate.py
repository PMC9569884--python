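"""Synthetic matched case-control cohort generator.

Emulates the statistical structure of a stool DIA proteomics study of
necrotizing enterocolitis (NEC): matched NEC/control pairs sampled over
three pre-diagnosis periods, a log-normal protein abundance model with
per-subject random effects, planted up- and down-regulated marker
proteins, abundance-dependent (MNAR) dropout, and precursor-level support
with variable precursor counts per protein group.

Model per protein i, sample s:

    log2 x_is = mu_i + u_subject(s) + beta_i * 1[condition(s) = NEC] + eps_is

with beta_i = +/- log2(effect_fold) for planted markers and 0 otherwise,
u ~ N(0, sigma_subject) per subject (14 subjects in the default cohort;
matched pairs share period structure but not u), eps ~ N(0, sigma_noise).
Each observation is missing with probability
``expit(dropout_steepness * (dropout_midpoint - log2 x))`` so dropout
concentrates at low abundance.  Precursor observations inherit the parent
per-sample signal plus a precursor-specific offset and small independent
noise, with independent dropout under the same logistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    ExpressionMatrix,
    PrecursorMatrix,
    SampleAnnotation,
    SampleSheet,
    write_pg_matrix,
    write_pr_matrix,
    write_sample_sheet,
)

__all__ = ["CohortConfig", "Cohort", "generate_cohort", "write_cohort"]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    The defaults mirror the study design this generator stands in for:
    7 matched pairs x 2 conditions x 3 periods = 42 runs, ~1100 quantified
    protein groups of which 40 + 40 are planted markers at 3-fold effect,
    ~15 precursors per protein (1-100).  Abundances are on a log2 scale of
    arbitrary normalized-intensity units.
    """

    n_pairs: int = 7
    periods: tuple[str, ...] = ("A", "B", "C")
    n_proteins: int = 1100
    n_up_markers: int = 40
    n_down_markers: int = 40
    effect_fold: float = 3.0
    #: baseline log2 abundance distribution over proteins
    baseline_log2_mean: float = 14.0
    sigma_protein: float = 2.0
    #: planted markers are drawn from the reliably quantified upper
    #: abundance range, as observed candidate markers are
    marker_log2_mean: float = 17.5
    marker_log2_sd: float = 0.8
    sigma_subject: float = 0.3
    sigma_noise: float = 0.4
    #: MNAR logistic dropout: P(missing) = expit(steepness * (midpoint - log2 x))
    dropout_midpoint: float = 12.2
    dropout_steepness: float = 1.0
    precursors_mean: float = 15.0
    precursors_max: int = 100
    #: per-precursor log2 offset relative to the parent protein signal
    precursor_log2_offset: float = -2.0
    precursor_log2_sd: float = 1.5
    precursor_noise_sd: float = 0.2
    #: fraction of protein groups annotated with a second (shared) gene,
    #: emulating multi-gene DIA-NN protein groups
    frac_multi_gene: float = 0.15
    #: optional systematic per-period drift (log2 units per period step);
    #: zero by default — periods are treated as repeated observations
    period_drift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_up_markers + self.n_down_markers > self.n_proteins:
            raise ValueError("more planted markers than proteins")
        if self.effect_fold <= 0:
            raise ValueError("effect_fold must be > 0")
        for name in ("sigma_protein", "sigma_subject", "sigma_noise",
                     "marker_log2_sd", "precursor_log2_sd", "precursor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1 <= self.precursors_mean <= self.precursors_max):
            raise ValueError("precursors_mean must lie in [1, precursors_max]")
        if self.n_pairs < 1 or not self.periods:
            raise ValueError("need at least one pair and one period")
        if not 0 <= self.frac_multi_gene <= 1:
            raise ValueError("frac_multi_gene must lie in [0, 1]")


class Cohort(NamedTuple):
    pg: ExpressionMatrix
    pr: PrecursorMatrix
    samples: SampleSheet
    truth: pd.DataFrame  # columns: protein_id, direction


def _sample_sheet(config: CohortConfig) -> SampleSheet:
    annotations = []
    for pair in range(1, config.n_pairs + 1):
        for condition, prefix in (("NEC", "N"), ("control", "C")):
            for period in config.periods:
                annotations.append(
                    SampleAnnotation(
                        sample_id=f"{prefix}{pair}{period}",
                        condition=condition,
                        pair_id=pair,
                        period=period,
                    )
                )
    return SampleSheet(annotations)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one cohort: pg matrix, pr matrix, sample sheet and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_sheet(config)
    n_samples = len(samples)
    n_prot = config.n_proteins

    # subject random effects: one per (pair, condition)
    subject_key = [(a.pair_id, a.condition) for a in samples]
    subjects = sorted(set(subject_key))
    u = dict(zip(subjects, rng.normal(0.0, config.sigma_subject, len(subjects))))
    u_per_sample = np.array([u[k] for k in subject_key])

    period_index = {p: i for i, p in enumerate(config.periods)}
    drift_per_sample = config.period_drift * np.array(
        [period_index[a.period] for a in samples], dtype=float
    )

    # protein baselines; planted markers sit in the well-quantified range
    mu = rng.normal(config.baseline_log2_mean, config.sigma_protein, n_prot)
    n_markers = config.n_up_markers + config.n_down_markers
    marker_idx = rng.choice(n_prot, size=n_markers, replace=False)
    mu[marker_idx] = rng.normal(config.marker_log2_mean, config.marker_log2_sd, n_markers)
    beta = np.zeros(n_prot)
    log_fold = np.log2(config.effect_fold)
    up_idx = marker_idx[: config.n_up_markers]
    down_idx = marker_idx[config.n_up_markers :]
    beta[up_idx] = log_fold
    beta[down_idx] = -log_fold

    is_case = samples.is_case.astype(float)
    log2x = (
        mu[:, None]
        + u_per_sample[None, :]
        + drift_per_sample[None, :]
        + beta[:, None] * is_case[None, :]
        + rng.normal(0.0, config.sigma_noise, (n_prot, n_samples))
    )
    p_missing = expit(config.dropout_steepness * (config.dropout_midpoint - log2x))
    missing = rng.random((n_prot, n_samples)) < p_missing
    values = np.power(2.0, log2x)
    values[missing] = np.nan

    protein_ids = np.array([f"PG{i:04d}" for i in range(n_prot)], dtype=object)
    genes = np.array([f"GENE{i:04d}" for i in range(n_prot)], dtype=object)
    n_multi = int(round(config.frac_multi_gene * n_prot))
    if n_multi:
        multi_rows = rng.choice(n_prot, size=n_multi, replace=False)
        partners = rng.integers(0, n_prot, size=n_multi)
        for row, partner in zip(multi_rows, partners):
            if partner != row:
                genes[row] = f"GENE{row:04d};GENE{partner:04d}"

    pg = ExpressionMatrix(
        protein_ids=protein_ids,
        gene_symbols=genes,
        sample_ids=samples.sample_ids,
        values=values,
        missing_mask=missing,
    )

    # precursor support: ~Geometric(1/mean) counts clipped to [1, max]
    counts = np.minimum(
        rng.geometric(1.0 / config.precursors_mean, n_prot), config.precursors_max
    )
    parent_rows = np.repeat(np.arange(n_prot), counts)
    n_prec = len(parent_rows)
    offsets = rng.normal(config.precursor_log2_offset, config.precursor_log2_sd, n_prec)
    prec_log2 = (
        log2x[parent_rows]
        + offsets[:, None]
        + rng.normal(0.0, config.precursor_noise_sd, (n_prec, n_samples))
    )
    prec_p_missing = expit(
        config.dropout_steepness * (config.dropout_midpoint - prec_log2)
    )
    prec_missing = rng.random((n_prec, n_samples)) < prec_p_missing
    prec_values = np.power(2.0, prec_log2)
    prec_values[prec_missing] = np.nan

    within = np.concatenate([np.arange(c) for c in counts])
    precursor_ids = np.array(
        [f"{protein_ids[r]}.pr{j}" for r, j in zip(parent_rows, within)], dtype=object
    )
    pr = PrecursorMatrix(
        precursor_ids=precursor_ids,
        parent_protein_ids=protein_ids[parent_rows],
        sample_ids=samples.sample_ids,
        values=prec_values,
        missing_mask=prec_missing,
    )

    truth = pd.DataFrame(
        {
            "protein_id": np.concatenate([protein_ids[up_idx], protein_ids[down_idx]]),
            "direction": ["up"] * len(up_idx) + ["down"] * len(down_idx),
        }
    ).sort_values("protein_id", ignore_index=True)
    return Cohort(pg=pg, pr=pr, samples=samples, truth=truth)


def write_cohort(cohort: Cohort, directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write pg_matrix.tsv, pr_matrix.tsv and samples.csv readable by :mod:`necsig.io`."""
    directory = Path(directory)
    paths = {
        "pg_matrix": directory / "pg_matrix.tsv",
        "pr_matrix": directory / "pr_matrix.tsv",
        "samples": directory / "samples.csv",
        "truth": directory / "truth.tsv",
    }
    if directory.exists() and not overwrite:
        clashes = [p for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(
                f"refusing to overwrite existing cohort files in {directory} "
                "(pass overwrite=True)"
            )
    directory.mkdir(parents=True, exist_ok=True)
    write_pg_matrix(cohort.pg, paths["pg_matrix"])
    write_pr_matrix(cohort.pr, paths["pr_matrix"])
    write_sample_sheet(cohort.samples, paths["samples"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
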