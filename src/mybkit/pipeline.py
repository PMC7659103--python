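"""End-to-end orchestration: simulate -> identify -> annotate -> duplications
-> Ka/Ks -> tree -> expression -> report.

Every stage reads its inputs from disk and writes plain-text outputs back
to the run directory, so any stage can be re-run in isolation; fixed seeds
make reruns byte-identical.  Stage defaults mirror the standard literature criteria
(coverage 0.8, identity 80/90, E-value 1e-10, span 600 kb, |log2FC| > 1,
alpha 0.05, 1000 bootstrap replicates, 1500 bp promoters).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, duplication, expression as xpr, family
from . import io as mio
from .evolution import bootstrap_support, codon_align, ng86_kaks, pad_align, to_newick
from .models import ProteinRecord
from .simulate import (
    DEFAULT_MOTIFS,
    DEFAULT_REPEAT_CONSENSUS,
    SyntheticGenomeConfig,
    default_stress_design,
    generate_expression,
    generate_genome,
)

log = logging.getLogger("mybkit")


@dataclass
class PipelineConfig:
    # inputs (generated in place when simulate=True)
    genome_fasta: str = "genome.fasta"
    gff3: str = "annotations.gff3"
    cds_fasta: str = "cds.fasta"
    protein_fasta: str = "proteins.fasta"
    expression_tsv: str = "expression.tsv"
    design_tsv: str = "design.tsv"
    ct_tsv: str = ""
    motif_tsv: str = ""
    # family identification
    prefix: str = "TaMYB"
    repeat_consensus: str = ""
    pssm_noise: float = 0.1
    bit_threshold: float = family.DEFAULT_BIT_THRESHOLD
    min_separation: int = family.DEFAULT_MIN_SEPARATION
    # duplication criteria
    tandem_coverage: float = 0.8
    tandem_identity: float = 80.0
    segmental_identity: float = 90.0
    max_evalue: float = 1e-10
    min_score: float = 50.0
    min_span: int = 600_000
    min_anchors: int = 2
    # expression screening
    fc_threshold: float = 1.0
    alpha: float = 0.05
    n_clusters: int = 5
    # phylogeny
    bootstraps: int = 1000
    # promoters
    promoter_length: int = 1500
    # simulation
    simulate: bool = False
    seed: int = 1
    sim: dict = field(default_factory=dict)  # SyntheticGenomeConfig overrides

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name, value in raw.items():
            default = getattr(cls(), name)
            if isinstance(default, tuple) and isinstance(value, list):
                setattr(cfg, name, tuple(value))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _consensus(cfg: PipelineConfig) -> str:
    return cfg.repeat_consensus or DEFAULT_REPEAT_CONSENSUS


# ------------------------------------------------------------------ stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    overrides = dict(cfg.sim)
    overrides.setdefault("seed", cfg.seed)
    for key in ("tandem_cluster_size", "segmental_run", "linker_range"):
        if key in overrides and isinstance(overrides[key], list):
            overrides[key] = tuple(overrides[key])
    gcfg = SyntheticGenomeConfig(**overrides)
    if cfg.repeat_consensus:
        gcfg.repeat_consensus = cfg.repeat_consensus
    bundle, truth = generate_genome(gcfg)
    bundle.write(outdir)
    design = default_stress_design()
    genes = sorted(truth.genes)
    matrix, xtruth = generate_expression(genes, design, seed=gcfg.seed + 1)
    truth.expression = xtruth.expression
    truth.save(outdir / "truth.json")
    mio.write_expression_tsv(outdir / "expression.tsv", matrix)
    mio.write_design_tsv(outdir / "design.tsv", design)
    log.info("simulate: %d genes on %d chromosomes", len(truth.genes), len(bundle.chromosomes))


def _load_models(cfg: PipelineConfig, outdir: Path):
    cds = mio.read_fasta(outdir / cfg.cds_fasta)
    proteins = mio.read_fasta(outdir / cfg.protein_fasta)
    return mio.read_gff3(outdir / cfg.gff3, cds=cds, proteins=proteins)


def stage_identify(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    models = _load_models(cfg, outdir)
    records = [
        ProteinRecord(m.transcript_id, m.gene_id, m.protein_sequence)
        for m in models
        if m.protein_sequence
    ]
    reps = family.dedupe_transcripts(records, models)
    pssm = family.build_pssm(_consensus(cfg), noise=cfg.pssm_noise)
    archs = family.classify_proteome(
        reps, pssm, cfg.bit_threshold, cfg.min_separation
    )
    by_id = {m.gene_id: m for m in models}
    members = [
        (gid, arch.family_class, by_id[gid].chromosome, by_id[gid].start)
        for gid, arch in sorted(archs.items())
        if arch.family_class != "none"
    ]
    named = family.assign_names(members, prefix=cfg.prefix)
    rows = []
    for fm in named:
        m = by_id[fm.gene_id]
        arch = archs[fm.gene_id]
        rows.append(
            {
                "gene_id": fm.gene_id,
                "name": fm.assigned_name,
                "family_class": fm.family_class,
                "chromosome": m.chromosome,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "repeats": ";".join(f"{a}-{b}" for a, b in arch.repeats),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "name", "family_class", "chromosome",
            "start", "end", "strand", "repeats",
        ],
    )
    table.to_csv(outdir / "family.tsv", sep="\t", index=False)
    log.info("identify: %d family members", len(table))
    return table


def _family_table(outdir: Path) -> pd.DataFrame:
    path = outdir / "family.tsv"
    if not path.exists():
        raise FileNotFoundError(f"family table missing: {path} (run identify first)")
    return pd.read_csv(path, sep="\t")


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> None:
    models = _load_models(cfg, outdir)
    fam = set(_family_table(outdir).gene_id)
    chromosomes = mio.read_fasta(outdir / cfg.genome_fasta)
    motif_dict = (
        mio.read_motif_tsv(outdir / cfg.motif_tsv)
        if cfg.motif_tsv
        else dict(DEFAULT_MOTIFS)
    )
    prop_rows, motif_rows = [], []
    for m in sorted(models, key=lambda m: m.gene_id):
        if m.gene_id not in fam or not m.protein_sequence:
            continue
        seq = m.protein_sequence
        prop_rows.append(
            {
                "gene_id": m.gene_id,
                "length": len(seq),
                "pI": round(annotation.isoelectric_point(seq), 3),
                "mw_kda": round(annotation.molecular_weight(seq), 5),
                "n_introns": annotation.count_introns(m),
            }
        )
        promoter = annotation.extract_promoter(chromosomes, m, cfg.promoter_length)
        for occ in annotation.scan_motifs(
            promoter.sequence, motif_dict, both_strands=True, gene_id=m.gene_id
        ):
            motif_rows.append(
                {
                    "gene_id": occ.gene_id,
                    "motif": occ.motif_name,
                    "strand": occ.strand,
                    "offset": occ.offset,
                    "promoter_truncated": promoter.truncated,
                }
            )
    pd.DataFrame(prop_rows).to_csv(outdir / "properties.tsv", sep="\t", index=False)
    pd.DataFrame(
        motif_rows, columns=["gene_id", "motif", "strand", "offset", "promoter_truncated"]
    ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    log.info("annotate: %d proteins, %d motif occurrences", len(prop_rows), len(motif_rows))


def stage_duplication(cfg: PipelineConfig, outdir: Path) -> None:
    models = _load_models(cfg, outdir)
    fam = set(_family_table(outdir).gene_id)
    by_id = {m.gene_id: m for m in models}

    # tandem: CDS alignments of family genes adjacent in gene order
    pos = duplication._positional_index(models)
    by_chrom: dict[str, list[str]] = {}
    for gid, (chrom, rank) in pos.items():
        by_chrom.setdefault(chrom, []).append(gid)
    cds_hits = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: pos[g][1])
        for a, b in zip(genes, genes[1:]):
            if a in fam and b in fam:
                cds_hits.append(
                    duplication.pairwise_align(
                        by_id[a].cds_sequence, by_id[b].cds_sequence, id_a=a, id_b=b
                    )
                )
    clusters = duplication.call_tandem(
        cds_hits, models, fam,
        coverage=cfg.tandem_coverage, min_identity=cfg.tandem_identity,
        max_evalue=cfg.max_evalue, min_score=cfg.min_score,
    )

    # segmental + homolog groups: protein alignments of prefiltered pairs
    prot = {g: by_id[g].protein_sequence for g in sorted(fam)}
    prot_hits = [
        duplication.pairwise_align(prot[a], prot[b], id_a=a, id_b=b)
        for a, b in duplication.candidate_pairs(prot)
    ]
    blocks = duplication.call_segmental(
        prot_hits, models, fam,
        min_span=cfg.min_span, min_identity=cfg.segmental_identity,
        min_anchors=cfg.min_anchors, max_evalue=cfg.max_evalue,
        min_score=cfg.min_score,
    )
    groups, fraction = duplication.find_homolog_groups(prot_hits, models, fam)

    pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "chromosome": c.chromosome,
                "n_members": len(c.members),
                "members": ";".join(c.members),
            }
            for c in clusters
        ],
        columns=["cluster_id", "chromosome", "n_members", "members"],
    ).to_csv(outdir / "tandem.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "chrom_a": b.chrom_a, "start_a": b.start_a, "end_a": b.end_a,
                "chrom_b": b.chrom_b, "start_b": b.start_b, "end_b": b.end_b,
                "n_anchors": len(b.anchors),
                "anchors": ";".join(f"{x},{y}" for x, y in b.anchors),
                "mean_identity": round(b.mean_identity, 2),
            }
            for b in blocks
        ],
        columns=[
            "block_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b",
            "end_b", "n_anchors", "anchors", "mean_identity",
        ],
    ).to_csv(outdir / "segmental.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "completeness": g.completeness,
                "members": ";".join(f"{k}:{v}" for k, v in sorted(g.members.items())),
            }
            for g in groups
        ],
        columns=["group_id", "completeness", "members"],
    ).to_csv(outdir / "homolog_groups.tsv", sep="\t", index=False)
    with open(outdir / "duplication_summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"tandem_clusters\t{len(clusters)}\n")
        fh.write(f"segmental_blocks\t{len(blocks)}\n")
        fh.write(f"homolog_groups\t{len(groups)}\n")
        fh.write(f"fraction_complete_triads\t{fraction:.4f}\n")

    # BED6 tracks
    with open(outdir / "tandem.bed", "w") as fh:
        for c in clusters:
            for gid in c.members:
                m = by_id[gid]
                fh.write(
                    f"{m.chromosome}\t{m.start - 1}\t{m.end}\t{c.cluster_id}:{gid}\t0\t{m.strand}\n"
                )
    with open(outdir / "segmental.bed", "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom_a}\t{b.start_a - 1}\t{b.end_a}\t{b.block_id}_A\t0\t+\n")
            fh.write(f"{b.chrom_b}\t{b.start_b - 1}\t{b.end_b}\t{b.block_id}_B\t0\t+\n")
    log.info(
        "duplication: %d tandem clusters, %d segmental blocks, %.2f complete triads",
        len(clusters), len(blocks), fraction,
    )


def stage_kaks(cfg: PipelineConfig, outdir: Path) -> None:
    models = _load_models(cfg, outdir)
    by_id = {m.gene_id: m for m in models}
    pairs: list[tuple[str, str]] = []
    tandem = pd.read_csv(outdir / "tandem.tsv", sep="\t")
    for members in tandem.get("members", pd.Series(dtype=str)):
        ms = str(members).split(";")
        pairs.extend(zip(ms, ms[1:]))
    seg = pd.read_csv(outdir / "segmental.tsv", sep="\t")
    for anchors in seg.get("anchors", pd.Series(dtype=str)):
        for item in str(anchors).split(";"):
            if "," in item:
                a, b = item.split(",")
                pairs.append((a, b))
    rows = []
    aligner = duplication._make_aligner("global", is_nucleotide=False)
    for a, b in pairs:
        aln = aligner.align(by_id[a].protein_sequence, by_id[b].protein_sequence)[0]
        ca = codon_align(
            by_id[a].cds_sequence, by_id[b].cds_sequence,
            (str(aln[0]), str(aln[1])), ids=(a, b),
        )
        res = ng86_kaks(ca, pair_id=f"{a}|{b}")
        rows.append(
            {
                "pair": res.pair_id, "S": round(res.S, 2), "N": round(res.N, 2),
                "Sd": round(res.Sd, 2), "Nd": round(res.Nd, 2),
                "Ka": "NA" if res.Ka is None else round(res.Ka, 4),
                "Ks": "NA" if res.Ks is None else round(res.Ks, 4),
                "ratio": "NA" if res.ratio is None else round(res.ratio, 4),
                "label": res.selection_label,
            }
        )
    pd.DataFrame(
        rows, columns=["pair", "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio", "label"]
    ).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
    log.info("kaks: %d duplicate pairs", len(rows))


def stage_tree(cfg: PipelineConfig, outdir: Path) -> None:
    models = _load_models(cfg, outdir)
    fam = _family_table(outdir)
    by_id = {m.gene_id: m for m in models}
    seqs = {
        str(r.gene_id): by_id[str(r.gene_id)].protein_sequence
        for r in fam.itertuples()
        if str(r.gene_id) in by_id
    }
    if len(seqs) < 3:
        (outdir / "tree.nwk").write_text(";\n")
        log.warning("tree: fewer than 3 family members, skipping")
        return
    aligned = pad_align(seqs)
    tree = bootstrap_support(aligned, n_replicates=cfg.bootstraps, seed=cfg.seed)
    (outdir / "tree.nwk").write_text(to_newick(tree) + "\n")
    log.info("tree: %d taxa, %d bootstrap replicates", len(seqs), cfg.bootstraps)


def stage_expression(cfg: PipelineConfig, outdir: Path) -> None:
    xpath = outdir / cfg.expression_tsv
    if not xpath.exists():
        log.warning("expression: %s missing, skipping", xpath)
        return
    matrix = mio.read_expression_tsv(xpath)
    design = mio.read_design_tsv(outdir / cfg.design_tsv)
    z = xpr.zscore_normalize(matrix)
    z.values.to_csv(outdir / "zscore.tsv", sep="\t", index_label="gene_id",
                    float_format="%.6g")
    calls = []
    for contrast in design.contrasts:
        calls.extend(
            xpr.screen_differential(
                matrix, design, contrast,
                fc_threshold=cfg.fc_threshold, alpha=cfg.alpha,
            )
        )
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id, "contrast": c.contrast,
                "log2fc": round(c.log2fc, 4), "p_value": f"{c.p_value:.4g}",
                "status": c.status,
            }
            for c in calls
        ]
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    xpr.summarize_calls(calls).to_csv(
        outdir / "expression_summary.tsv", sep="\t", index_label="contrast"
    )
    k = min(cfg.n_clusters, max(1, len(matrix) - len(z.flagged)))
    labels = xpr.hierarchical_cluster(z, k)
    pd.DataFrame(
        sorted(labels.items()), columns=["gene_id", "cluster"]
    ).to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False)
    if cfg.ct_tsv and (outdir / cfg.ct_tsv).exists():
        measurements = mio.read_ct_tsv(outdir / cfg.ct_tsv)
        rel = xpr.ddct(measurements)
        pd.DataFrame(
            sorted(rel.items()), columns=["sample", "relative_expression"]
        ).to_csv(outdir / "ddct.tsv", sep="\t", index=False)
    log.info("expression: %d calls over %d contrasts", len(calls), len(design.contrasts))


# ------------------------------------------------------------------ report


def _report(cfg: PipelineConfig, outdir: Path) -> dict:
    report: dict = {
        "config": cfg.to_dict(),
        "versions": {
            "mybkit": "0.1.0",
            "python": ".".join(map(str, sys.version_info[:3])),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {},
        "warnings": [],
    }
    counts = report["counts"]
    fam_path = outdir / "family.tsv"
    if fam_path.exists():
        fam = pd.read_csv(fam_path, sep="\t")
        counts["family_total"] = int(len(fam))
        counts["per_class"] = {
            k: int(v) for k, v in fam.family_class.value_counts().sort_index().items()
        }
        counts["per_chromosome"] = {
            k: int(v) for k, v in fam.chromosome.value_counts().sort_index().items()
        }
    if (outdir / "duplication_summary.tsv").exists():
        dup = pd.read_csv(outdir / "duplication_summary.tsv", sep="\t")
        for r in dup.itertuples():
            value = float(r.value)
            counts[str(r.metric)] = value if "fraction" in str(r.metric) else int(value)
    if (outdir / "kaks.tsv").exists():
        kaks = pd.read_csv(outdir / "kaks.tsv", sep="\t")
        counts["kaks_labels"] = (
            {k: int(v) for k, v in kaks.label.value_counts().sort_index().items()}
            if len(kaks)
            else {}
        )
    if (outdir / "expression_summary.tsv").exists():
        summ = pd.read_csv(outdir / "expression_summary.tsv", sep="\t", index_col=0)
        counts["expression"] = {
            str(ct): {c: int(summ.loc[ct, c]) for c in summ.columns}
            for ct in summ.index
        }
    return report


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        stage_simulate(cfg, outdir)
    missing = [
        str(outdir / p)
        for p in (cfg.genome_fasta, cfg.gff3, cfg.cds_fasta, cfg.protein_fasta)
        if not (outdir / p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    stage_identify(cfg, outdir)
    stage_annotate(cfg, outdir)
    stage_duplication(cfg, outdir)
    stage_kaks(cfg, outdir)
    stage_tree(cfg, outdir)
    stage_expression(cfg, outdir)
    report = _report(cfg, outdir)
    mio.write_json(outdir / "report.json", report)
    lines = ["mybkit run report", "================="]
    for key, value in sorted(report["counts"].items()):
        lines.append(f"{key}: {value}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
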