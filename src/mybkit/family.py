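"""Repeat-architecture detection, subfamily classification and naming.

The detector scores every window of a protein against a log-odds position
score matrix built from the repeat consensus and a per-position
substitution-noise model, merges nearby hits into repeats, and maps the
merged repeat count onto the 1R/2R/3R/4R subfamily classes.
"""

from __future__ import annotations

import math
import os
from collections import defaultdict

import numpy as np

from .models import (
    DomainHit,
    FamilyMember,
    GeneModel,
    ProteinRecord,
    RepeatArchitecture,
    chromosome_sort_key,
)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: default acceptance score; calibrated so that the per-window hit rate on
#: uniform-composition random proteins is far below 1e-3
#: (see scripts/calibrate_threshold.py)
DEFAULT_BIT_THRESHOLD = 40.0

DEFAULT_MIN_SEPARATION = 5

CLASS_BY_COUNT = {1: "1R", 2: "2R", 3: "3R", 4: "4R"}


def build_pssm(
    consensus: str, noise: float = 0.1, pseudocount: float = 0.01
) -> np.ndarray:
    """(width, 21) log2-odds matrix vs a uniform background.

    Column model: consensus residue with probability 1-noise, any other
    residue with probability noise/19, plus a flat pseudocount.  The extra
    21st row scores the ambiguity code X as 0 bits.
    """
    width = len(consensus)
    pssm = np.zeros((width, 21))
    for i, aa in enumerate(consensus):
        if aa not in _AA_INDEX:
            raise ValueError(f"consensus residue {aa!r} is not a standard amino acid")
        p = np.full(20, noise / 19.0)
        p[_AA_INDEX[aa]] = 1.0 - noise
        p = (p + pseudocount) / (1.0 + 20 * pseudocount)
        pssm[i, :20] = np.log2(p / 0.05)
    return pssm


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX.get(aa, 20) for aa in sequence), dtype=np.int64)


def scan_repeats(
    protein: ProteinRecord,
    pssm: np.ndarray,
    bit_threshold: float = DEFAULT_BIT_THRESHOLD,
) -> list[DomainHit]:
    """All windows scoring >= ``bit_threshold`` bits, overlapping allowed."""
    width = pssm.shape[0]
    seq = protein.sequence
    if len(seq) < width:
        return []
    idx = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(idx, width)
    scores = pssm[np.arange(width), windows].sum(axis=1)
    hits = []
    for off in np.nonzero(scores >= bit_threshold)[0] if math.isfinite(bit_threshold) else range(len(scores)):
        hits.append(
            DomainHit(
                protein_id=protein.protein_id,
                start=int(off) + 1,
                end=int(off) + width,
                score=float(scores[off]),
            )
        )
    return hits


def ingest_domtblout(path: str | os.PathLike) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table, taking envelope coordinates and the
    independent E-value of each domain row."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise ValueError(f"{path}:{lineno}: expected >=22 columns, got {len(parts)}")
            try:
                target = parts[0]
                ievalue = float(parts[12])
                score = float(parts[13])
                env_from = int(parts[19])
                env_to = int(parts[20])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if env_to < env_from:
                raise ValueError(
                    f"{path}:{lineno}: envelope end {env_to} < start {env_from}"
                )
            hits.append(DomainHit(target, env_from, env_to, score, ievalue))
    return hits


def merge_hits(
    hits: list[DomainHit],
    min_separation: int = DEFAULT_MIN_SEPARATION,
    gene_id: str = "",
) -> RepeatArchitecture:
    """Merge overlapping hits (or hits separated by < ``min_separation``
    residues) into repeats; idempotent."""
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    if not gene_id and pids:
        gene_id = next(iter(pids))
    merged: list[list[int]] = []
    for h in sorted(hits, key=lambda h: (h.start, h.end)):
        if merged and h.start - merged[-1][1] - 1 < min_separation:
            merged[-1][1] = max(merged[-1][1], h.end)
        else:
            merged.append([h.start, h.end])
    arch = RepeatArchitecture(gene_id=gene_id, repeats=[(a, b) for a, b in merged])
    arch.family_class = classify_family(arch)
    return arch


def classify_family(arch: RepeatArchitecture) -> str:
    """Repeat count -> subfamily; 0 or >4 repeats are flagged "none"."""
    cls = CLASS_BY_COUNT.get(arch.repeat_count, "none")
    arch.family_class = cls
    return cls


def dedupe_transcripts(
    proteins: list[ProteinRecord], models: list[GeneModel]
) -> list[ProteinRecord]:
    """One representative per gene: longest CDS, ties broken by the
    lexicographically smallest transcript id."""
    gene_ids = {m.gene_id for m in models}
    cds_len = {m.transcript_id: sum(e - s + 1 for s, e in m.exons) for m in models}
    by_gene: dict[str, list[ProteinRecord]] = defaultdict(list)
    for p in proteins:
        if p.gene_id not in gene_ids:
            raise ValueError(f"protein {p.protein_id} has no parent gene {p.gene_id}")
        by_gene[p.gene_id].append(p)
    out: list[ProteinRecord] = []
    for gid in sorted(by_gene):
        best = min(
            by_gene[gid],
            key=lambda p: (-cds_len.get(p.protein_id, 3 * len(p.sequence)), p.protein_id),
        )
        out.append(ProteinRecord(best.protein_id, gid, best.sequence, True))
    return out


def assign_names(
    members: list[tuple[str, str, str, int]], prefix: str = "TaMYB"
) -> list[FamilyMember]:
    """Name (gene_id, class, chromosome, start) tuples in chromosomal order.

    The 2R series is plain ``prefix + ordinal``; other classes get the class
    tag spliced in (e.g. ``prefix3R1``).  Genes on unparseable chromosomes
    are appended after the placed ones, in input order.
    """
    seen: set[str] = set()
    for gid, *_ in members:
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid}")
        seen.add(gid)
    def sort_key(item: tuple[int, tuple[str, str, str, int]]):
        i, (gid, _cls, chrom, start) = item
        placed, num, raw = chromosome_sort_key(chrom)
        if placed:  # unparseable chromosome: keep input order, after the rest
            return (1, i, "", 0, "")
        return (0, num, raw, start, gid)

    indexed = sorted(enumerate(members), key=sort_key)
    counters: dict[str, int] = defaultdict(int)
    out = []
    for _i, (gid, cls, chrom, start) in indexed:
        counters[cls] += 1
        tag = "" if cls == "2R" else cls
        out.append(FamilyMember(gid, f"{prefix}{tag}{counters[cls]}", cls, chrom, start))
    return out


def classify_proteome(
    proteins: list[ProteinRecord],
    pssm: np.ndarray,
    bit_threshold: float = DEFAULT_BIT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> dict[str, RepeatArchitecture]:
    """Scan + merge + classify every representative protein; keyed by gene."""
    out: dict[str, RepeatArchitecture] = {}
    for p in proteins:
        hits = scan_repeats(p, pssm, bit_threshold)
        out[p.gene_id] = merge_hits(hits, min_separation, gene_id=p.gene_id)
    return out
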