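"""End-to-end orchestration of the regulator-discovery chain.

``run_pipeline`` wires the stages together on an in-memory bundle:

counts -> TPM -> replicate QC -> differential expression -> lncRNA filter
cascade -> cis (optionally trans) target assignment -> OPLS-DA metabolite
screen -> doubly-thresholded correlation integration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integration import RegulatorCandidate, find_regulators
from .lncrna_discovery import FilterTrace, classify_lncrnas
from .oplsda import OplsdaModel, fit_oplsda, screen_metabolites
from .quantification import ExpressionMatrix, QCResult, differential_expression, sample_qc
from .synthetic_data import SimulatedBundle
from .target_assignment import TargetPair, cis_targets_all, trans_targets

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All intermediate and final outputs of one pipeline run."""

    matrix: ExpressionMatrix
    qc: QCResult
    de: pd.DataFrame
    traces: list[FilterTrace]
    lncrna_ids: list[str]
    target_pairs: list[TargetPair]
    oplsda_model: OplsdaModel
    metabolite_screen: pd.DataFrame
    candidates: list[RegulatorCandidate] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_samples_retained": len(self.qc.retained),
            "samples_excluded": self.qc.excluded_ids,
            "n_de_features": int(self.de["significant"].sum()),
            "n_lncrnas": len(self.lncrna_ids),
            "n_target_pairs": len(self.target_pairs),
            "oplsda_r2y": self.oplsda_model.r2y,
            "oplsda_q2y": self.oplsda_model.q2y,
            "n_differential_metabolites": int(self.metabolite_screen["selected"].sum()),
            "n_regulator_candidates": len(self.candidates),
        }


def run_pipeline(
    bundle: SimulatedBundle,
    min_median_r: float = 0.9,
    window: int = 100_000,
    r_min: float = 0.7,
    p_max: float = 0.05,
    n_ortho: int = 1,
    include_trans: bool = False,
    trans_window_len: int = 50,
    trans_ndg_cutoff: float = -0.1,
) -> PipelineResult:
    """Run the full inference chain on a bundle and return every stage."""
    matrix = ExpressionMatrix.from_counts(bundle.counts, bundle.lengths, bundle.conditions)
    qc = sample_qc(matrix, min_median_r=min_median_r)
    de = differential_expression(matrix, retained=qc.retained)

    traces = classify_lncrnas(
        bundle.transcripts, matrix.tpm, bundle.calls, retained_samples=qc.retained
    )
    lncrna_ids = [t.transcript_id for t in traces if t.verdict == "lncRNA"]

    models = {t.id: t for t in bundle.transcripts}
    genes = bundle.gene_models
    pairs = cis_targets_all((models[l] for l in lncrna_ids), genes, window=window)
    if include_trans:
        gene_seqs = {g.id: bundle.sequences[g.id] for g in genes}
        for lid in lncrna_ids:
            pairs.extend(
                trans_targets(
                    lid, bundle.sequences[lid], gene_seqs,
                    window_len=trans_window_len, ndg_cutoff=trans_ndg_cutoff,
                )
            )

    met = bundle.metabolites
    nonzero = met.abundances.to_numpy()[met.abundances.to_numpy() > 0]
    pc = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    X = np.log2(met.abundances.T + pc)  # samples x compounds
    model = fit_oplsda(X, met.conditions.to_numpy(), n_ortho=n_ortho)
    screen = screen_metabolites(met, model)

    log_expr = matrix.log_tpm[qc.retained]
    candidates = find_regulators(
        log_expr,
        lncrna_ids,
        pairs,
        de,
        bundle.anthocyanin_genes,
        met,
        r_min=r_min,
        p_max=p_max,
    )
    return PipelineResult(
        matrix=matrix,
        qc=qc,
        de=de,
        traces=traces,
        lncrna_ids=lncrna_ids,
        target_pairs=pairs,
        oplsda_model=model,
        metabolite_screen=screen,
        candidates=candidates,
    )
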