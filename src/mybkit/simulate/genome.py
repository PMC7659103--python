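"""Synthetic genomes with planted repeat architectures, tandem clusters,
collinear duplicated blocks, cross-subgenome homolog triads and promoter
motifs — all recorded in a serializable truth record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .. import io as mio
from ..codons import synonymous_codons
from ..models import GeneModel
from .divergence import simulate_codon_divergence

# 52-residue repeat consensus used when the caller supplies none; the
# regularly spaced tryptophans mimic the helix-turn-helix repeat layout.
DEFAULT_REPEAT_CONSENSUS = "LKRGPWTTEEDEILVDYIKKHGEGNWNAVQKHTGLARCGKSCRLRWANHLRP"

DEFAULT_MOTIFS: dict[str, str] = {
    "MBS": "CAACTG",
    "ABRE": "ACGTGGC",
    "HSE": "AGAANNTTCT",
    "TCA": "CCATCTTTTT",
    "TGA": "AACGAC",
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CLASS_REPEATS = {"1R": 1, "2R": 2, "3R": 3, "4R": 4}

# per-branch divergence targets used when deriving unit members
_TANDEM_RATES = (0.03, 0.01)  # (ks, ka)
_TRIAD_RATES = (0.15, 0.04)
_SEGMENTAL_RATES = (0.05, 0.015)


class CapacityError(ValueError):
    """Configured gene content does not fit on the chromosomes."""


@dataclass
class SyntheticGenomeConfig:
    n_subgenomes: int = 3
    chromosomes_per_subgenome: int = 7
    chromosome_length: int = 150_000
    n_family_genes: int = 60
    n_background_genes: int = 120
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"1R": 0.15, "2R": 0.55, "3R": 0.2, "4R": 0.1}
    )
    n_tandem_clusters: int = 2
    tandem_cluster_size: tuple[int, int] = (2, 4)
    n_segmental_blocks: int = 1
    segmental_run: tuple[int, int] = (3, 5)
    segmental_span: int = 25_000
    repeat_consensus: str = DEFAULT_REPEAT_CONSENSUS
    repeat_noise: float = 0.05
    homoeolog_fraction: float = 0.5
    linker_range: tuple[int, int] = (5, 10)
    min_intergenic: int = 200
    motif_dictionary: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    n_motif_promoters: int = 5
    seed: int = 0

    def validate(self) -> None:
        if len(self.repeat_consensus) != 52:
            raise ValueError("repeat_consensus must be exactly 52 residues")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if set(self.class_mix) - set(_CLASS_REPEATS):
            raise ValueError(f"unknown classes in mix: {set(self.class_mix) - set(_CLASS_REPEATS)}")
        for name in (
            "n_subgenomes",
            "chromosomes_per_subgenome",
            "chromosome_length",
            "n_family_genes",
            "n_background_genes",
            "n_tandem_clusters",
            "n_segmental_blocks",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.repeat_noise <= 1:
            raise ValueError("repeat_noise must be in [0, 1]")
        if not 0 <= self.homoeolog_fraction <= 1:
            raise ValueError("homoeolog_fraction must be in [0, 1]")

    @property
    def subgenome_labels(self) -> str:
        return "ABD" if self.n_subgenomes == 3 else "ABCDEFGHIJ"[: self.n_subgenomes]

    @property
    def chromosome_names(self) -> list[str]:
        return [
            f"{num}{letter}"
            for num in range(1, self.chromosomes_per_subgenome + 1)
            for letter in self.subgenome_labels
        ]


@dataclass
class TruthRecord:
    """Planted ground truth; serializes to/from JSON."""

    genes: dict[str, dict] = field(default_factory=dict)
    tandem_clusters: list[list[str]] = field(default_factory=list)
    segmental_blocks: list[dict] = field(default_factory=list)
    triads: list[list[str]] = field(default_factory=list)
    pair_divergence: dict[str, dict] = field(default_factory=dict)
    motifs: list[dict] = field(default_factory=list)
    expression: dict[str, dict] = field(default_factory=dict)

    def family_genes(self) -> dict[str, str]:
        return {
            g: info["family_class"]
            for g, info in self.genes.items()
            if info["family_class"] != "none"
        }

    def save(self, path: str | os.PathLike) -> None:
        mio.write_json(path, asdict(self))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TruthRecord":
        d = mio.read_json(path)
        return cls(**{k: d.get(k, v) for k, v in asdict(cls()).items()})


@dataclass
class GenomeBundle:
    chromosomes: dict[str, str]
    models: list[GeneModel]
    cds: dict[str, str]  # transcript id -> CDS
    proteins: dict[str, str]  # transcript id -> protein

    def write(self, outdir: str | os.PathLike) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_fasta(out / "genome.fasta", self.chromosomes)
        mio.write_fasta(out / "cds.fasta", self.cds)
        mio.write_fasta(out / "proteins.fasta", self.proteins)
        mio.write_gff3(out / "annotations.gff3", self.models)


# ------------------------------------------------------------------ sequence helpers

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode()


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def _noisy_repeat(rng: np.random.Generator, consensus: str, noise: float) -> str:
    if noise <= 0:
        return consensus
    out = list(consensus)
    for i in range(len(out)):
        if rng.random() < noise:
            alt = AA20[rng.integers(0, 20)]
            while alt == out[i]:
                alt = AA20[rng.integers(0, 20)]
            out[i] = alt
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    parts = []
    for aa in protein:
        options = synonymous_codons(aa)
        parts.append(options[rng.integers(len(options))])
    return "".join(parts)


def _family_protein(
    rng: np.random.Generator, cfg: SyntheticGenomeConfig, n_repeats: int
) -> tuple[str, list[tuple[int, int]]]:
    """Protein with ``n_repeats`` noised consensus copies; returns the
    protein and 1-based inclusive repeat intervals."""
    lo, hi = cfg.linker_range
    parts = ["M" + _random_protein(rng, int(rng.integers(4, 21)))]
    pos = len(parts[0])
    intervals = []
    for k in range(n_repeats):
        if k:
            linker = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            parts.append(linker)
            pos += len(linker)
        rep = _noisy_repeat(rng, cfg.repeat_consensus, cfg.repeat_noise)
        parts.append(rep)
        intervals.append((pos + 1, pos + len(rep)))
        pos += len(rep)
    parts.append(_random_protein(rng, int(rng.integers(10, 51))))
    return "".join(parts), intervals


# ------------------------------------------------------------------ gene structure


def _exon_lengths(rng: np.random.Generator, cds_len: int) -> list[int]:
    max_exons = max(1, min(12, cds_len // 30))
    weights = np.array([3.0, 4, 4, 3, 2, 1.5, 1, 0.7, 0.5, 0.3, 0.2, 0.2][:max_exons])
    n = int(rng.choice(np.arange(1, max_exons + 1), p=weights / weights.sum()))
    if n == 1:
        return [cds_len]
    base = 15
    extra = rng.multinomial(cds_len - base * n, [1.0 / n] * n)
    return [base + int(e) for e in extra]


@dataclass
class _GeneSpec:
    gene_id: str
    family_class: str
    protein: str
    cds: str
    repeats: list[tuple[int, int]]
    strand: str = "+"
    # filled at assembly time
    genomic: str = ""
    rel_exons: list[tuple[int, int]] = field(default_factory=list)


def _assemble_gene(rng: np.random.Generator, spec: _GeneSpec) -> None:
    """Build the genomic segment (introns inserted, strand applied) and
    0-based relative exon intervals."""
    exon_lens = _exon_lengths(rng, len(spec.cds))
    introns = [_random_dna(rng, int(rng.integers(60, 301))) for _ in exon_lens[:-1]]
    pieces = []
    sense_exons = []
    cursor = 0
    off = 0
    for i, el in enumerate(exon_lens):
        pieces.append(spec.cds[cursor : cursor + el])
        sense_exons.append((off, off + el - 1))
        cursor += el
        off += el
        if i < len(introns):
            pieces.append(introns[i])
            off += len(introns[i])
    sense = "".join(pieces)
    if spec.strand == "+":
        spec.genomic = sense
        spec.rel_exons = sense_exons
    else:
        L = len(sense)
        spec.genomic = revcomp(sense)
        spec.rel_exons = sorted((L - 1 - b, L - 1 - a) for a, b in sense_exons)


# ------------------------------------------------------------------ generator


@dataclass
class _Unit:
    """Genes that must be placed consecutively on one chromosome."""

    chrom: str
    genes: list[_GeneSpec]
    gaps: list[int]  # internal gaps, len == len(genes) - 1
    strand: str | None = None  # fixed strand (segmental copies), else random


def _pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def generate_genome(
    config: SyntheticGenomeConfig,
) -> tuple[GenomeBundle, TruthRecord]:
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = TruthRecord()

    classes = sorted(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])

    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"G{counter[0]:04d}"

    def draw_class() -> str:
        return classes[int(rng.choice(len(classes), p=probs))]

    def derive(ancestor_cds: str, rates: tuple[float, float], cls: str,
               repeats: list[tuple[int, int]]) -> _GeneSpec:
        ks, ka = rates
        cds = simulate_codon_divergence(ancestor_cds, ks, ka, int(rng.integers(2**31)))
        if cfg.repeat_noise == 0 and repeats:
            # zero-noise contract: planted repeats stay exact consensus copies,
            # so divergence is confined to codons outside the repeat intervals
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            for a, b in repeats:
                for ri in range(a - 1, b):
                    codons[ri] = ancestor_cds[ri * 3 : ri * 3 + 3]
            cds = "".join(codons)
        from ..codons import translate

        return _GeneSpec(new_id(), cls, translate(cds), cds, list(repeats))

    chrom_names = cfg.chromosome_names
    if not chrom_names:
        raise CapacityError("no chromosomes configured")

    def random_chrom() -> str:
        return chrom_names[int(rng.integers(len(chrom_names)))]

    # ---- budget family genes across planted structures
    n_triads = int(cfg.homoeolog_fraction * cfg.n_family_genes // 3)
    tandem_sizes = [
        int(rng.integers(cfg.tandem_cluster_size[0], cfg.tandem_cluster_size[1] + 1))
        for _ in range(cfg.n_tandem_clusters)
    ]
    seg_runs = [
        int(rng.integers(cfg.segmental_run[0], cfg.segmental_run[1] + 1))
        for _ in range(cfg.n_segmental_blocks)
    ]
    used = 3 * n_triads + sum(tandem_sizes) + 2 * sum(seg_runs)
    n_singles = cfg.n_family_genes - used
    if n_singles < 0:
        raise CapacityError(
            f"planted structures need {used} family genes but only "
            f"{cfg.n_family_genes} are configured"
        )

    units: list[_Unit] = []

    # triads: one copy per subgenome on the same chromosome number
    for _ in range(n_triads):
        cls = draw_class()
        protein, reps = _family_protein(rng, cfg, _CLASS_REPEATS[cls])
        anc = _back_translate(rng, protein)
        num = int(rng.integers(1, cfg.chromosomes_per_subgenome + 1))
        members = []
        for letter in cfg.subgenome_labels:
            spec = derive(anc, _TRIAD_RATES, cls, reps)
            units.append(_Unit(f"{num}{letter}", [spec], []))
            members.append(spec)
        truth.triads.append([m.gene_id for m in members])
        ks2, ka2 = 2 * _TRIAD_RATES[0], 2 * _TRIAD_RATES[1]
        for i in range(3):
            for j in range(i + 1, 3):
                truth.pair_divergence[_pair_key(members[i].gene_id, members[j].gene_id)] = {
                    "ka": ka2, "ks": ks2
                }

    # tandem clusters: consecutive near-identical copies on one chromosome
    for size in tandem_sizes:
        cls = draw_class()
        protein, reps = _family_protein(rng, cfg, _CLASS_REPEATS[cls])
        anc = _back_translate(rng, protein)
        members = [derive(anc, _TANDEM_RATES, cls, reps) for _ in range(size)]
        gaps = [int(rng.integers(cfg.min_intergenic, cfg.min_intergenic + 300))
                for _ in range(size - 1)]
        units.append(_Unit(random_chrom(), members, gaps))
        truth.tandem_clusters.append([m.gene_id for m in members])
        for i in range(size - 1):
            truth.pair_divergence[_pair_key(members[i].gene_id, members[i + 1].gene_id)] = {
                "ka": 2 * _TANDEM_RATES[1], "ks": 2 * _TANDEM_RATES[0]
            }

    # segmental blocks: a run of family genes copied to another chromosome
    # of the same subgenome, gaps padded so the run spans ~segmental_span
    for run in seg_runs:
        letter = cfg.subgenome_labels[int(rng.integers(len(cfg.subgenome_labels)))]
        if cfg.chromosomes_per_subgenome < 2:
            raise CapacityError("segmental blocks need >= 2 chromosomes per subgenome")
        num_a, num_b = rng.choice(
            np.arange(1, cfg.chromosomes_per_subgenome + 1), size=2, replace=False
        )
        src, dst = [], []
        for _ in range(run):
            cls = draw_class()
            protein, reps = _family_protein(rng, cfg, _CLASS_REPEATS[cls])
            anc = _back_translate(rng, protein)
            src.append(derive(anc, (0.0, 0.0), cls, reps))
            dst.append(derive(anc, _SEGMENTAL_RATES, cls, reps))
        gene_len_est = sum(len(s.cds) * 2 for s in src) // max(run, 1)
        pad = max(
            cfg.min_intergenic,
            (cfg.segmental_span - run * gene_len_est) // max(run - 1, 1),
        )
        seg_strand = "+" if rng.random() < 0.5 else "-"
        for members, num in ((src, num_a), (dst, num_b)):
            gaps = [pad] * (run - 1)
            units.append(_Unit(f"{int(num)}{letter}", members, gaps, strand=seg_strand))
        truth.segmental_blocks.append(
            {
                "a_members": [s.gene_id for s in src],
                "b_members": [s.gene_id for s in dst],
                "chrom_a": f"{int(num_a)}{letter}",
                "chrom_b": f"{int(num_b)}{letter}",
            }
        )
        for s, d in zip(src, dst):
            truth.pair_divergence[_pair_key(s.gene_id, d.gene_id)] = {
                "ka": _SEGMENTAL_RATES[1], "ks": _SEGMENTAL_RATES[0]
            }

    # remaining family genes and the background
    for _ in range(n_singles):
        cls = draw_class()
        protein, reps = _family_protein(rng, cfg, _CLASS_REPEATS[cls])
        spec = _GeneSpec(new_id(), cls, protein, _back_translate(rng, protein), reps)
        units.append(_Unit(random_chrom(), [spec], []))
    for _ in range(cfg.n_background_genes):
        protein = "M" + _random_protein(rng, int(rng.integers(79, 300)))
        spec = _GeneSpec(new_id(), "none", protein, _back_translate(rng, protein), [])
        units.append(_Unit(random_chrom(), [spec], []))

    # ---- strands and genomic assembly
    for unit in units:
        strand = unit.strand or ("+" if rng.random() < 0.5 else "-")
        for spec in unit.genes:
            spec.strand = strand
            _assemble_gene(rng, spec)

    # ---- placement per chromosome
    by_chrom: dict[str, list[_Unit]] = {c: [] for c in chrom_names}
    for unit in units:
        by_chrom[unit.chrom].append(unit)

    chromosomes: dict[str, str] = {}
    models: list[GeneModel] = []
    placed: dict[str, list[tuple[int, int, str]]] = {}  # chrom -> (start, end, gid)

    for chrom in chrom_names:
        chrom_units = by_chrom[chrom]
        order = rng.permutation(len(chrom_units))
        chrom_units = [chrom_units[i] for i in order]
        footprints = [
            sum(len(g.genomic) for g in u.genes) + sum(u.gaps) for u in chrom_units
        ]
        n_units = len(chrom_units)
        free = cfg.chromosome_length - sum(footprints) - (n_units + 1) * cfg.min_intergenic
        if free < 0:
            raise CapacityError(
                f"chromosome {chrom} of length {cfg.chromosome_length} cannot hold "
                f"{sum(len(u.genes) for u in chrom_units)} genes"
            )
        extra = (
            rng.multinomial(free, [1.0 / (n_units + 1)] * (n_units + 1))
            if n_units
            else np.array([free])
        )
        pieces: list[str] = []
        pos = 0  # 0-based cursor
        placed[chrom] = []
        for ui, unit in enumerate(chrom_units):
            gap = cfg.min_intergenic + int(extra[ui])
            pieces.append(_random_dna(rng, gap))
            pos += gap
            for gi, spec in enumerate(unit.genes):
                if gi:
                    igap = unit.gaps[gi - 1]
                    pieces.append(_random_dna(rng, igap))
                    pos += igap
                start1 = pos + 1
                pieces.append(spec.genomic)
                pos += len(spec.genomic)
                end1 = pos
                exons = [(start1 + a, start1 + b) for a, b in spec.rel_exons]
                tid = f"{spec.gene_id}.1"
                models.append(
                    GeneModel(
                        gene_id=spec.gene_id,
                        chromosome=chrom,
                        start=start1,
                        end=end1,
                        strand=spec.strand,
                        exons=exons,
                        cds_sequence=spec.cds,
                        protein_sequence=spec.protein,
                        transcript_id=tid,
                    )
                )
                placed[chrom].append((start1, end1, spec.gene_id))
                truth.genes[spec.gene_id] = {
                    "family_class": spec.family_class,
                    "repeats": [list(r) for r in spec.repeats],
                    "chromosome": chrom,
                    "start": start1,
                    "end": end1,
                    "strand": spec.strand,
                    "n_exons": len(exons),
                }
        tail = cfg.chromosome_length - pos - cfg.min_intergenic - int(extra[-1])
        pieces.append(_random_dna(rng, cfg.min_intergenic + int(extra[-1]) + max(tail, 0)))
        chromosomes[chrom] = "".join(pieces)[: cfg.chromosome_length]

    _plant_motifs(rng, cfg, chromosomes, placed, truth)

    models.sort(key=lambda m: (m.chromosome, m.start))
    bundle = GenomeBundle(
        chromosomes=chromosomes,
        models=models,
        cds={m.transcript_id: m.cds_sequence for m in models},
        proteins={m.transcript_id: m.protein_sequence for m in models},
    )
    return bundle, truth


def _instantiate_iupac(rng: np.random.Generator, pattern: str) -> str:
    from ..annotation import IUPAC_CODES

    out = []
    for ch in pattern:
        choices = IUPAC_CODES[ch]
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _plant_motifs(
    rng: np.random.Generator,
    cfg: SyntheticGenomeConfig,
    chromosomes: dict[str, str],
    placed: dict[str, list[tuple[int, int, str]]],
    truth: TruthRecord,
) -> None:
    """Write motif instances into promoter windows of family genes whose
    upstream gap is fully intergenic and untruncated."""
    if not cfg.motif_dictionary or cfg.n_motif_promoters <= 0:
        return
    family = {g for g, info in truth.genes.items() if info["family_class"] != "none"}
    candidates: list[tuple[str, str, int]] = []  # (gene, chrom, avail)
    for chrom in sorted(placed):
        genes = sorted(placed[chrom])
        for i, (start, end, gid) in enumerate(genes):
            if gid not in family:
                continue
            info = truth.genes[gid]
            if info["strand"] == "+":
                prev_end = genes[i - 1][1] if i else 0
                avail = start - prev_end - 1
                if start > 1500 and avail >= 120:
                    candidates.append((gid, chrom, min(avail - 20, 1500)))
            else:
                next_start = genes[i + 1][0] if i + 1 < len(genes) else len(chromosomes[chrom]) + 1
                avail = next_start - end - 1
                if end + 1500 <= len(chromosomes[chrom]) and avail >= 120:
                    candidates.append((gid, chrom, min(avail - 20, 1500)))
    if not candidates:
        return
    pick = rng.permutation(len(candidates))[: cfg.n_motif_promoters]
    names = sorted(cfg.motif_dictionary)
    bufs = {c: bytearray(chromosomes[c], "ascii") for c in {candidates[i][1] for i in pick}}
    for ci in sorted(pick):
        gid, chrom, window = candidates[ci]
        info = truth.genes[gid]
        n_here = int(rng.integers(1, 4))
        taken: list[tuple[int, int]] = []
        for _ in range(n_here):
            name = names[int(rng.integers(len(names)))]
            instance = _instantiate_iupac(rng, cfg.motif_dictionary[name])
            L = len(instance)
            for _try in range(30):
                d = int(rng.integers(5, window - L - 5))
                if all(d + L <= a or d >= b for a, b in taken):
                    break
            else:
                continue
            taken.append((d, d + L))
            mstrand = "+" if rng.random() < 0.5 else "-"
            if info["strand"] == "+":
                a0 = info["start"] - d - L - 1  # 0-based genomic start
                payload = instance if mstrand == "+" else revcomp(instance)
            else:
                a0 = info["end"] + d  # 0-based
                payload = revcomp(instance) if mstrand == "+" else instance
            bufs[chrom][a0 : a0 + L] = payload.encode()
            offset = 1500 - d - L + 1  # 1-based from the promoter 5' end
            truth.motifs.append(
                {
                    "gene_id": gid,
                    "motif_name": name,
                    "strand": mstrand,
                    "offset": offset,
                }
            )
    for chrom, buf in bufs.items():
        chromosomes[chrom] = buf.decode()
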