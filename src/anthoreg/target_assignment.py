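"""Candidate target-gene assignment for lncRNAs.

Two modes:

* **cis** -- a coding gene is a cis candidate when it lies on the same contig
  within a genomic window (default 100 kb, boundary inclusive) of the lncRNA,
  measured edge-to-edge between the two genomic spans (overlap = distance 0).
  The reported offset is signed by the lncRNA's strand: a gene upstream of
  the lncRNA gets a negative offset formatted ``Up-N``, downstream
  ``Down-N`` (thousands separators, e.g. ``Up-37,447``).

* **trans** -- a simplified antiparallel RNA-RNA hybridization score. A
  window of fixed length slides over both sequences; each aligned base pair
  contributes an additive energy (GC = -3, AU = -2, GU = -1, mismatch = +1,
  arbitrary units) and the normalized free energy ndG is the best (most
  negative) window sum divided by the window length. Pairs with
  ``ndG <= cutoff`` are reported. This keeps the normalized-energy decision
  structure of thermodynamic duplex predictors while remaining a fully
  specified, enumerable score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .lncrna_discovery import TranscriptModel

__all__ = [
    "TargetPair",
    "cis_targets",
    "cis_targets_all",
    "trans_targets",
    "hybridization_ndg",
    "format_offset",
    "parse_offset",
]


@dataclass(frozen=True)
class TargetPair:
    """One (lncRNA, gene) candidate with its mode-specific evidence."""

    lncrna_id: str
    gene_id: str
    mode: str  # "cis" | "trans"
    offset: int | None = None  # signed bp, cis only; negative = upstream
    ndg: float | None = None  # normalized binding energy, trans only

    @property
    def position(self) -> str:
        if self.mode != "cis" or self.offset is None:
            return ""
        return format_offset(self.offset)


def format_offset(offset: int) -> str:
    """Render a signed cis offset as ``Up-N`` / ``Down-N`` / ``Overlap``."""
    if offset == 0:
        return "Overlap"
    if offset < 0:
        return f"Up-{-offset:,}"
    return f"Down-{offset:,}"


def parse_offset(position: str) -> int:
    """Inverse of :func:`format_offset`."""
    if position == "Overlap":
        return 0
    for prefix, sign in (("Up-", -1), ("Down-", 1)):
        if position.startswith(prefix):
            return sign * int(position[len(prefix) :].replace(",", ""))
    raise ValueError(f"unparseable position string: {position!r}")


def _signed_offset(lncrna: TranscriptModel, gene: TranscriptModel) -> int | None:
    """Edge-to-edge distance signed by the lncRNA's strand orientation.

    Returns None when the features are on different contigs. Unstranded
    lncRNAs are treated as + strand with a warning.
    """
    if lncrna.contig != gene.contig:
        return None
    lstart, lend = lncrna.span
    gstart, gend = gene.span
    if gend < lstart:
        distance, gene_is_left = lstart - gend, True
    elif gstart > lend:
        distance, gene_is_left = gstart - lend, False
    else:
        return 0
    strand = lncrna.strand
    if strand == ".":
        warnings.warn(
            f"{lncrna.id}: unstranded lncRNA treated as + strand", stacklevel=2
        )
        strand = "+"
    upstream = gene_is_left if strand == "+" else not gene_is_left
    return -distance if upstream else distance


def cis_targets(
    lncrna: TranscriptModel,
    genes: Iterable[TranscriptModel],
    window: int = 100_000,
) -> list[TargetPair]:
    """Cis candidates of one lncRNA: same contig, edge distance <= window."""
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    pairs = []
    for gene in genes:
        if gene.id == lncrna.id:
            continue
        offset = _signed_offset(lncrna, gene)
        if offset is None or abs(offset) > window:
            continue
        pairs.append(
            TargetPair(lncrna_id=lncrna.id, gene_id=gene.id, mode="cis", offset=offset)
        )
    return pairs


def cis_targets_all(
    lncrnas: Iterable[TranscriptModel],
    genes: Iterable[TranscriptModel],
    window: int = 100_000,
) -> list[TargetPair]:
    genes = list(genes)
    out: list[TargetPair] = []
    for lnc in lncrnas:
        out.extend(cis_targets(lnc, genes, window=window))
    return out


# additive per-pair energies, indexed by encoded base (A=0, C=1, G=2, T/U=3)
_PAIR_ENERGY = np.full((4, 4), 1.0)
_PAIR_ENERGY[0, 3] = _PAIR_ENERGY[3, 0] = -2.0  # A:U
_PAIR_ENERGY[2, 1] = _PAIR_ENERGY[1, 2] = -3.0  # G:C
_PAIR_ENERGY[2, 3] = _PAIR_ENERGY[3, 2] = -1.0  # G:U wobble

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _encode(seq: str, what: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_ENCODE[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"{what}: invalid alphabet character {exc.args[0]!r}") from None


def hybridization_ndg(
    lncrna_seq: str, gene_seq: str, window_len: int = 50
) -> float:
    """Best normalized antiparallel hybridization energy over all windows.

    For every pair of windows (one on the lncRNA read 5'->3', one on the
    gene read 3'->5') the aligned base energies are summed; ndG is the
    minimum window sum divided by ``window_len``.
    """
    x = _encode(lncrna_seq, "lncrna_seq")
    y = _encode(gene_seq, "gene_seq")
    w = int(window_len)
    if w < 1:
        raise ValueError("window_len must be >= 1")
    if len(x) < w or len(y) < w:
        raise ValueError(
            f"sequences must be >= window_len ({w}); got {len(x)} and {len(y)}"
        )
    # energy of lncRNA base i against gene base j, gene axis reversed so an
    # antiparallel window becomes a diagonal run
    energy = _PAIR_ENERGY[np.ix_(x, y[::-1])]
    n, m = energy.shape
    acc = np.zeros((n - w + 1, m - w + 1))
    for k in range(w):
        acc += energy[k : k + n - w + 1, k : k + m - w + 1]
    return float(acc.min()) / w


def trans_targets(
    lncrna_id: str,
    lncrna_seq: str,
    gene_seqs: Mapping[str, str],
    window_len: int = 50,
    ndg_cutoff: float = -0.1,
) -> list[TargetPair]:
    """Trans candidates of one lncRNA: genes whose best ndG <= cutoff."""
    pairs = []
    for gene_id, gene_seq in gene_seqs.items():
        ndg = hybridization_ndg(lncrna_seq, gene_seq, window_len=window_len)
        if ndg <= ndg_cutoff:
            pairs.append(
                TargetPair(lncrna_id=lncrna_id, gene_id=gene_id, mode="trans", ndg=ndg)
            )
    return pairs
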