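"""Expression quantification, replicate QC and differential expression.

This module holds the expression-level primitives of the pipeline:

* TPM (transcripts per million) normalisation of a feature x sample count
  table,
* correlation-based screening of biological replicates, which flags and
  removes degraded replicates before any expression statistic is computed,
* two-condition differential expression with the decision rule
  ``|fold change| >= 2 and P <= 0.05``,
* relative RT-qPCR quantification by the 2^-ddCt rule.

The differential test is Welch's t on log2(TPM+1); fold changes are ratios
of pseudocounted condition means on the TPM scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_tpm",
    "ExpressionMatrix",
    "QCResult",
    "sample_qc",
    "differential_expression",
    "QpcrMeasurement",
    "ddct_relative_expression",
]

#: the two fermentation time points compared throughout the pipeline
CONDITIONS = ("G2", "G8")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length-normalised TPM from a feature x sample count table.

    ``tpm[f, s] = 1e6 * (counts[f, s] / length[f]) / sum_g (counts[g, s] / length[g])``

    Parameters
    ----------
    counts
        Non-negative reals, features in rows, samples in columns.
    lengths
        Feature lengths in bp, indexed like ``counts``; must be > 0.

    Returns
    -------
    DataFrame of TPM values whose columns each sum to 1e6, except for
    all-zero samples, which stay all-zero and trigger a warning.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing lengths for features: {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:5]
        raise ValueError(f"feature lengths must be > 0; offending: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    rate = counts.astype(float).div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        warnings.warn(
            f"all-zero samples produce all-zero TPM: {list(denom.index[denom == 0])}",
            stacklevel=2,
        )
    tpm = rate.div(denom.where(denom > 0), axis=1) * 1.0e6
    return tpm.fillna(0.0)


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance table with a counts and a TPM layer.

    ``conditions`` maps each sample id to its condition label (G2/G8).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    conditions: pd.Series
    tpm: pd.DataFrame = field(repr=False, default=None)

    @classmethod
    def from_counts(
        cls, counts: pd.DataFrame, lengths: pd.Series, conditions: pd.Series
    ) -> "ExpressionMatrix":
        conditions = conditions.reindex(counts.columns)
        if conditions.isna().any():
            missing = list(conditions.index[conditions.isna()])
            raise ValueError(f"missing condition labels for samples: {missing}")
        tpm = compute_tpm(counts, lengths)
        return cls(counts, lengths.reindex(counts.index), conditions, tpm)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def log_tpm(self) -> pd.DataFrame:
        """log2(TPM + 1), the scale used for QC, tests and correlations."""
        return np.log2(self.tpm + 1.0)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


@dataclass
class QCResult:
    """Outcome of replicate screening: retained/excluded ids and diagnostics."""

    retained: list[str]
    excluded: list[tuple[str, float]]  # (sample id, offending median r)
    correlations: pd.DataFrame  # full pairwise Pearson matrix on log2(TPM+1)

    @property
    def excluded_ids(self) -> list[str]:
        return [s for s, _ in self.excluded]


def sample_qc(matrix: ExpressionMatrix, min_median_r: float = 0.9) -> QCResult:
    """Flag degraded replicates by within-condition correlation.

    Pairwise Pearson r is computed on log2(TPM+1) over all features. A sample
    is degraded when the median of its correlations against same-condition
    replicates falls below ``min_median_r``. Exclusion is greedy worst-first:
    the sample with the lowest offending median is removed and medians are
    recomputed, so that one degraded replicate cannot drag its healthy peers
    below the threshold (with triplicates the median over two peers is their
    mean, which a single bad replicate would otherwise contaminate).

    Raises
    ------
    ValueError
        If fewer than two samples per condition enter, or if an exclusion
        would leave a condition with fewer than two samples (downstream
        correlations need df >= 1).
    """
    counts = matrix.conditions.value_counts()
    if (counts < 2).any():
        raise ValueError(f"need >=2 samples per condition, have {dict(counts)}")
    logt = matrix.log_tpm
    corr = logt.corr(method="pearson")
    active = list(matrix.sample_ids)
    excluded: list[tuple[str, float]] = []
    while True:
        medians: dict[str, float] = {}
        for s in active:
            peers = [
                p
                for p in active
                if p != s and matrix.conditions[p] == matrix.conditions[s]
            ]
            medians[s] = float(np.median([corr.loc[s, p] for p in peers]))
        worst = min(medians, key=lambda s: medians[s])
        if medians[worst] >= min_median_r:
            break
        cond = matrix.conditions[worst]
        n_left = sum(1 for s in active if matrix.conditions[s] == cond) - 1
        if n_left < 2:
            raise ValueError(
                f"excluding {worst!r} (median r {medians[worst]:.3f}) would leave "
                f"condition {cond!r} with {n_left} sample(s)"
            )
        excluded.append((worst, medians[worst]))
        active.remove(worst)
    return QCResult(retained=active, excluded=excluded, correlations=corr)


def differential_expression(
    matrix: ExpressionMatrix,
    retained: list[str] | None = None,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    pseudocount: float = 1.0,
    baseline: str = "G2",
    contrast: str = "G8",
) -> pd.DataFrame:
    """Two-condition differential expression on retained samples.

    Per feature: ``log2fc = log2((mean TPM contrast + pc) / (mean TPM baseline
    + pc))`` with pseudocount ``pc`` (1 TPM by default), and a two-sided
    Welch t-test on log2(TPM+1). A feature is significant when
    ``|log2fc| >= log2(fc_min)`` and ``p <= p_max`` (thresholds inclusive).

    Returns a DataFrame indexed by feature with columns ``log2fc``,
    ``p_value`` and ``significant``.
    """
    if retained is None:
        retained = matrix.sample_ids
    a = [s for s in retained if matrix.conditions[s] == baseline]
    b = [s for s in retained if matrix.conditions[s] == contrast]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >=2 retained samples per condition, have {len(a)} {baseline} "
            f"and {len(b)} {contrast}"
        )
    tpm = matrix.tpm
    log2fc = np.log2(
        (tpm[b].mean(axis=1) + pseudocount) / (tpm[a].mean(axis=1) + pseudocount)
    )
    logt = matrix.log_tpm
    with warnings.catch_warnings():
        # zero-variance features yield nan t statistics; resolved below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            logt[b].to_numpy(), logt[a].to_numpy(), axis=1, equal_var=False
        )
    diff = logt[b].mean(axis=1).to_numpy() - logt[a].mean(axis=1).to_numpy()
    p = np.where(np.isnan(p), np.where(diff == 0.0, 1.0, 0.0), p)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "significant": (np.abs(log2fc) >= np.log2(fc_min)) & (p <= p_max),
        },
        index=tpm.index,
    )
    return out


@dataclass(frozen=True)
class QpcrMeasurement:
    """One RT-qPCR contrast: target and reference gene Ct in case and control."""

    ct_target_case: float
    ct_reference_case: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_case",
            "ct_reference_case",
            "ct_target_control",
            "ct_reference_control",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


def ddct_relative_expression(m: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt rule.

    ``ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,control - Ct_ref,control)``
    and the fold ratio is ``2 ** -ddCt``.
    """
    ddct = (m.ct_target_case - m.ct_reference_case) - (
        m.ct_target_control - m.ct_reference_control
    )
    return float(2.0 ** (-ddct))
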