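"""Reading and writing the pipeline's on-disk formats.

A simulated bundle round-trips through plain-text files: GFF3 annotation,
FASTA transcript sequences, TSV matrices (counts+lengths, predictor calls,
domain flags, metabolite abundances, pathway gene list, sample conditions)
and a ground-truth JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .lncrna_discovery import TranscriptModel
from .oplsda import MetaboliteTable
from .synthetic_data import GroundTruth, SimulatedBundle, SimulationConfig

__all__ = [
    "write_gff3",
    "read_transcripts_gff3",
    "write_bundle",
    "read_bundle",
]

_FLOAT_FMT = "%.10g"


def write_gff3(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write gene/transcript/exon features, 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    for t in transcripts:
        start, end = t.span
        biotype = "protein_coding" if t.is_known_coding else "noncoding"
        attrs = f"ID=gene:{t.id};biotype={biotype}"
        lines.append(
            f"{t.contig}\tanthoreg\tgene\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{t.contig}\tanthoreg\ttranscript\t{start}\t{end}\t.\t{t.strand}\t.\t"
            f"ID={t.id};Parent=gene:{t.id};biotype={biotype}"
        )
        for i, (es, ee) in enumerate(t.exons):
            lines.append(
                f"{t.contig}\tanthoreg\texon\t{es}\t{ee}\t.\t{t.strand}\t.\t"
                f"ID={t.id}.exon{i + 1};Parent={t.id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_transcripts_gff3(
    path: str | Path, domain_flags: pd.Series | None = None
) -> list[TranscriptModel]:
    """Rebuild transcript models from a GFF3 written by :func:`write_gff3`."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for tr in db.features_of_type("transcript"):
        exons = sorted(
            (e.start, e.end) for e in db.children(tr, featuretype="exon")
        )
        biotype = tr.attributes.get("biotype", ["noncoding"])[0]
        tid = tr.id
        has_domain = bool(domain_flags.get(tid, False)) if domain_flags is not None else False
        out.append(
            TranscriptModel(
                id=tid,
                contig=tr.seqid,
                strand=tr.strand,
                exons=tuple(exons),
                is_known_coding=(biotype == "protein_coding"),
                has_known_domain=has_domain,
            )
        )
    return out


def write_bundle(bundle: SimulatedBundle, out_dir: str | Path) -> Path:
    """Serialize a simulated bundle to a directory of text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gff3(bundle.transcripts, out / "annotation.gff3")
    records = [
        SeqRecord(Seq(seq), id=fid, description="")
        for fid, seq in bundle.sequences.items()
    ]
    SeqIO.write(records, out / "transcripts.fa", "fasta")
    counts = bundle.counts.copy()
    counts.insert(0, "length", bundle.lengths)
    counts.to_csv(out / "counts.tsv", sep="\t", index_label="transcript_id")
    bundle.calls.to_csv(out / "predictor_calls.tsv", sep="\t", index_label="transcript_id")
    domains = pd.Series(
        {t.id: int(t.has_known_domain) for t in bundle.transcripts}, name="has_domain"
    )
    domains.to_csv(out / "domains.tsv", sep="\t", index_label="transcript_id")
    bundle.conditions.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
    met = bundle.metabolites.abundances.copy()
    met.insert(0, "compound_class", bundle.metabolites.classes)
    met.to_csv(
        out / "metabolites.tsv", sep="\t", index_label="compound_id",
        float_format=_FLOAT_FMT,
    )
    pd.Series(bundle.anthocyanin_genes, name="gene_symbol").to_csv(
        out / "anthocyanin_genes.tsv", sep="\t", index_label="gene_id"
    )
    (out / "ground_truth.json").write_text(
        json.dumps(bundle.truth.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    (out / "config.json").write_text(
        json.dumps(
            {k: v for k, v in bundle.config.__dict__.items()}, indent=1, sort_keys=True
        )
        + "\n"
    )
    return out


def read_bundle(in_dir: str | Path) -> SimulatedBundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    d = Path(in_dir)
    domains = pd.read_csv(d / "domains.tsv", sep="\t", index_col=0)["has_domain"].astype(bool)
    transcripts = read_transcripts_gff3(d / "annotation.gff3", domain_flags=domains)
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(d / "transcripts.fa"), "fasta")
    }
    table = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    lengths = table["length"]
    counts = table.drop(columns="length")
    calls = pd.read_csv(d / "predictor_calls.tsv", sep="\t", index_col=0)
    conditions = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0)["condition"]
    met = pd.read_csv(d / "metabolites.tsv", sep="\t", index_col=0)
    metabolites = MetaboliteTable(
        abundances=met.drop(columns="compound_class"),
        classes=met["compound_class"],
        conditions=conditions.copy(),
    )
    anth = pd.read_csv(d / "anthocyanin_genes.tsv", sep="\t", index_col=0)["gene_symbol"]
    truth = GroundTruth.from_dict(json.loads((d / "ground_truth.json").read_text()))
    config_d = json.loads((d / "config.json").read_text())
    order = {t.id: i for i, t in enumerate(transcripts)}
    return SimulatedBundle(
        config=SimulationConfig(**config_d),
        transcripts=sorted(transcripts, key=lambda t: order[t.id]),
        sequences=sequences,
        counts=counts,
        lengths=lengths,
        conditions=conditions,
        calls=calls,
        metabolites=metabolites,
        anthocyanin_genes=dict(anth),
        truth=truth,
    )
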