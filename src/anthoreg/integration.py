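"""Transcriptome-metabolome correlation integration.

The final inference step: Pearson correlations (with exact Student-t
p-values on n-2 degrees of freedom) link differentially expressed lncRNAs
to their candidate target genes and to metabolite abundances, and a
two-step decision rule nominates regulator candidates:

1. the lncRNA's assigned target gene must belong to the curated anthocyanin
   pathway gene set and the lncRNA-gene correlation must pass
   ``|r| >= 0.7 and p <= 0.05``;
2. the lncRNA must additionally correlate (same gate) with at least one
   anthocyanin-class compound.

All correlations run over the QC-retained samples on log2 scales; the
inferred regulation sign (positive/negative) is the sign of the
lncRNA-gene correlation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .oplsda import MetaboliteTable
from .target_assignment import TargetPair

__all__ = [
    "CorrelationRecord",
    "RegulatorCandidate",
    "pearson_p_from_r",
    "pearson_with_p",
    "correlation_bubble_table",
    "find_regulators",
]


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson coefficient under the exact t-transform.

    ``t = r * sqrt((n-2) / (1-r^2))`` referred to Student's t with n-2
    degrees of freedom; |r| = 1 maps to p = 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    ar = min(abs(r), 1.0)
    if ar >= 1.0:
        return 0.0
    t = ar * math.sqrt((n - 2) / (1.0 - ar * ar))
    return float(2.0 * stats.t.sf(t, df=n - 2))


@dataclass(frozen=True)
class CorrelationRecord:
    """One correlated pair with its sample size, p-value and gate outcome."""

    id_a: str
    id_b: str
    kind: str  # "lncrna-gene" | "lncrna-metabolite" | "gene-metabolite" | ...
    r: float
    n: int
    p_value: float
    passes: bool
    degenerate: bool = False

    @property
    def df(self) -> int:
        return self.n - 2


def pearson_with_p(
    x,
    y,
    id_a: str = "x",
    id_b: str = "y",
    kind: str = "pair",
    r_min: float = 0.7,
    p_max: float = 0.05,
) -> CorrelationRecord:
    """Pearson r with exact p and the ``|r| >= r_min and p <= p_max`` gate.

    Constant input produces a degenerate record (r and p are nan, never
    passes) rather than an exception, so batch screens can proceed.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = xa.size
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if xa.std() == 0 or ya.std() == 0:
        return CorrelationRecord(
            id_a=id_a, id_b=id_b, kind=kind, r=float("nan"), n=n,
            p_value=float("nan"), passes=False, degenerate=True,
        )
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    p = pearson_p_from_r(r, n)
    return CorrelationRecord(
        id_a=id_a, id_b=id_b, kind=kind, r=r, n=n, p_value=p,
        passes=(abs(r) >= r_min) and (p <= p_max),
    )


def _corr_matrix_with_p(a: pd.DataFrame, b: pd.DataFrame):
    """All-pairs Pearson r and exact p between rows of two aligned tables."""
    n = a.shape[1]
    az = a.to_numpy(dtype=float)
    bz = b.to_numpy(dtype=float)
    az = az - az.mean(axis=1, keepdims=True)
    bz = bz - bz.mean(axis=1, keepdims=True)
    asd = az.std(axis=1)
    bsd = bz.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / n / np.outer(asd, bsd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def correlation_bubble_table(
    a: pd.DataFrame,
    b: pd.DataFrame,
    p_max: float = 0.05,
    kind: str = "pair",
    classes_b: pd.Series | None = None,
) -> pd.DataFrame:
    """All-pairs correlation table filtered to ``p <= p_max``.

    ``a`` and ``b`` are entity x sample tables over an identical sample set
    (e.g. pathway genes/lncRNAs against anthocyanin compounds); the output
    feeds bubble/correlogram plots. Degenerate (constant) rows never pass.
    """
    if list(a.columns) != list(b.columns):
        raise ValueError("a and b must share an identical, ordered sample set")
    if a.shape[1] < 3:
        raise ValueError("need >= 3 shared samples")
    r, p = _corr_matrix_with_p(a, b)
    rows = []
    for i, ia in enumerate(a.index):
        for j, jb in enumerate(b.index):
            if np.isnan(r[i, j]) or p[i, j] > p_max:
                continue
            rows.append(
                {
                    "id_a": ia,
                    "id_b": jb,
                    "kind": kind,
                    "r": r[i, j],
                    "n": a.shape[1],
                    "p_value": p[i, j],
                }
            )
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "kind", "r", "n", "p_value"])
    if classes_b is not None and len(out):
        out["class_b"] = classes_b.reindex(out["id_b"]).to_numpy()
    return out


@dataclass
class RegulatorCandidate:
    """A lncRNA nominated as a regulator of an anthocyanin pathway gene."""

    lncrna_id: str
    gene_id: str
    gene_symbol: str
    mode: str  # cis | trans
    position: str  # Up-N / Down-N / Overlap ("" for trans)
    gene_correlation: CorrelationRecord
    metabolite_correlations: list[CorrelationRecord] = field(default_factory=list)

    @property
    def sign(self) -> str:
        return "positive" if self.gene_correlation.r > 0 else "negative"


def find_regulators(
    log_expression: pd.DataFrame,
    lncrna_ids: Iterable[str],
    target_pairs: Iterable[TargetPair],
    de_results: pd.DataFrame,
    anthocyanin_genes: Mapping[str, str],
    metabolites: MetaboliteTable,
    r_min: float = 0.7,
    p_max: float = 0.05,
    anthocyanin_class: str = "anthocyanin",
) -> list[RegulatorCandidate]:
    """Apply the two-step anthocyanin-regulator filter.

    Parameters
    ----------
    log_expression
        feature x sample log2(TPM+1) table restricted to the QC-retained
        samples; both lncRNAs and genes must be present.
    lncrna_ids
        transcripts accepted by the lncRNA filter cascade.
    target_pairs
        candidate (lncRNA, gene) pairs from cis/trans assignment.
    de_results
        differential-expression table (``significant`` column); only
        differentially expressed lncRNAs are considered.
    anthocyanin_genes
        gene id -> pathway role symbol (e.g. UGTs_1, DFR_1) for the curated
        anthocyanin gene set.
    metabolites
        compound x sample abundances; the retained expression samples must
        all be present (matched by sample id), otherwise an error lists the
        discrepancy. Metabolite values are correlated on log2 scale with a
        half-minimum pseudocount.

    Returns candidates sorted by |lncRNA-gene r| descending.
    """
    samples = list(log_expression.columns)
    missing = [s for s in samples if s not in metabolites.abundances.columns]
    if missing:
        raise ValueError(
            f"retained samples absent from the metabolite table: {missing}"
        )
    lnc_set = set(lncrna_ids)
    de_lnc = {
        f for f in lnc_set
        if f in de_results.index and bool(de_results.loc[f, "significant"])
    }
    ab = metabolites.abundances[samples]
    nonzero = ab.to_numpy()[ab.to_numpy() > 0]
    pc = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    log_met = np.log2(ab + pc)
    anthos = metabolites.compounds_of_class(anthocyanin_class)

    candidates: list[RegulatorCandidate] = []
    for pair in target_pairs:
        if pair.lncrna_id not in de_lnc or pair.gene_id not in anthocyanin_genes:
            continue
        for fid in (pair.lncrna_id, pair.gene_id):
            if fid not in log_expression.index:
                raise ValueError(f"feature {fid!r} missing from expression table")
        rec = pearson_with_p(
            log_expression.loc[pair.lncrna_id, samples],
            log_expression.loc[pair.gene_id, samples],
            id_a=pair.lncrna_id,
            id_b=pair.gene_id,
            kind="lncrna-gene",
            r_min=r_min,
            p_max=p_max,
        )
        if not rec.passes:
            continue
        supports = []
        for met in anthos:
            m_rec = pearson_with_p(
                log_expression.loc[pair.lncrna_id, samples],
                log_met.loc[met],
                id_a=pair.lncrna_id,
                id_b=met,
                kind="lncrna-metabolite",
                r_min=r_min,
                p_max=p_max,
            )
            if m_rec.passes:
                supports.append(m_rec)
        if not supports:
            continue
        candidates.append(
            RegulatorCandidate(
                lncrna_id=pair.lncrna_id,
                gene_id=pair.gene_id,
                gene_symbol=anthocyanin_genes[pair.gene_id],
                mode=pair.mode,
                position=pair.position,
                gene_correlation=rec,
                metabolite_correlations=supports,
            )
        )
    candidates.sort(key=lambda c: -abs(c.gene_correlation.r))
    return candidates
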