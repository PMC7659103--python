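"""File ingest/export for the standard formats the pipeline touches.

FASTA goes through Biopython, GFF3 through gffutils (in-memory DB); the
remaining artifacts are plain TSV/JSON written with stable ordering so
that fixed-seed runs are byte-identical.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ExpressionDesign, GeneModel, QpcrMeasurement, Sample


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, records: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

def write_gff3(path: str | os.PathLike, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            tid = m.transcript_id or f"{m.gene_id}.1"
            fh.write(
                f"{m.chromosome}\tmybkit\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chromosome}\tmybkit\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chromosome}\tmybkit\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
                fh.write(
                    f"{m.chromosome}\tmybkit\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={tid}.cds{i};Parent={tid}\n"
                )


def read_gff3(
    path: str | os.PathLike,
    cds: Mapping[str, str] | None = None,
    proteins: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Load gene models; optionally attach CDS/protein sequences keyed by
    transcript id (falling back to gene id)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        tid = mrnas[0].id if mrnas else f"{gene.id}.1"
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        if not exons:
            exons = [(gene.start, gene.end)]
        def _lookup(table: Mapping[str, str] | None) -> str:
            if not table:
                return ""
            return table.get(tid) or table.get(gene.id) or ""
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=sorted(exons),
                transcript_id=tid,
                cds_sequence=_lookup(cds),
                protein_sequence=_lookup(proteins),
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.start, m.gene_id))
    return models


# ---------------------------------------------------------------- expression / design / qPCR

def write_expression_tsv(path: str | os.PathLike, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design_tsv(path: str | os.PathLike, design: ExpressionDesign) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "condition": s.condition,
            "timepoint": s.timepoint,
            "replicate": s.replicate,
        }
        for s in design.samples
    ]
    df = pd.DataFrame(rows)
    df["contrasts"] = ""
    if rows:
        df.loc[0, "contrasts"] = ";".join(f"{t}~{c}" for t, c in design.contrasts)
    df.to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | os.PathLike) -> ExpressionDesign:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    samples = [
        Sample(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            timepoint=str(r.timepoint),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
    contrasts: list[tuple[str, str]] = []
    if "contrasts" in df.columns and len(df) and df.loc[0, "contrasts"]:
        for item in str(df.loc[0, "contrasts"]).split(";"):
            t, c = item.split("~")
            contrasts.append((t, c))
    return ExpressionDesign(samples=samples, contrasts=contrasts)


def read_ct_tsv(path: str | os.PathLike) -> list[QpcrMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        QpcrMeasurement(
            sample=str(r["sample"]),
            target_ct=float(r.target_ct),
            reference_ct=float(r.reference_ct),
            group=str(r.group),
        )
        for _, r in df.iterrows()
    ]


def read_motif_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Motif dictionary TSV: name <tab> IUPAC pattern [<tab> note]."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("name", "motif_name"):
                continue
            out[parts[0]] = parts[1].upper()
    return out


# ---------------------------------------------------------------- JSON

def write_json(path: str | os.PathLike, obj: object) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
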