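"""Tandem clusters, segmental blocks and cross-subgenome homolog groups
from pairwise similarity evidence plus gene order.

Tandem criteria (all four must hold for a linked pair): alignment covers
>= 80% of the longer gene, identity > 80%, E-value < 1e-10 (or an
equivalent score threshold when hits come from the internal aligner, which
reports no E-value), and no annotated gene of any kind lies between the
two.  Segmental blocks are chains of collinear non-adjacent anchor pairs
whose regions each span >= min_span.
"""

from __future__ import annotations

import os
from collections import defaultdict

from Bio import Align
from Bio.Align import substitution_matrices

from .models import (
    GeneModel,
    HomologGroup,
    PairHit,
    SegmentalBlock,
    TandemCluster,
    chromosome_sort_key,
    subgenome_of,
)

_NUC = set("ACGTUN")


def _make_aligner(mode: str, is_nucleotide: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if is_nucleotide:
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_align(
    seq_a: str,
    seq_b: str,
    mode: str = "global",
    id_a: str = "a",
    id_b: str = "b",
) -> PairHit:
    """Affine-gap alignment; identity is counted over all alignment columns
    (gap columns included), so a single mismatch in 4 columns gives 75%."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    is_nuc = set(seq_a) <= _NUC and set(seq_b) <= _NUC
    aligner = _make_aligner(mode, is_nuc)
    aln = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ncols = len(row_a)
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return PairHit(
        query_id=id_a,
        subject_id=id_b,
        pct_identity=100.0 * matches / ncols if ncols else 0.0,
        aln_length=ncols,
        evalue=None,
        score=float(aln.score),
    )


def ingest_pairhits(path: str | os.PathLike) -> list[PairHit]:
    """BLAST outfmt-6 tabular ingest; self-hits dropped, both directions of
    a reciprocal pair retained."""
    hits: list[PairHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                (q, s, pident, length, _mm, _go, qs, qe, ss, se, ev, bits) = parts
                hit = PairHit(
                    query_id=q,
                    subject_id=s,
                    pct_identity=float(pident),
                    aln_length=int(length),
                    evalue=float(ev),
                    score=float(bits),
                    query_range=(int(qs), int(qe)),
                    subject_range=(int(ss), int(se)),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if hit.query_id != hit.subject_id:
                hits.append(hit)
    return hits


def candidate_pairs(
    sequences: dict[str, str], k: int = 6, min_shared: int = 5
) -> list[tuple[str, str]]:
    """Cheap shared-k-mer prefilter to avoid all-vs-all alignment."""
    kmers = {
        name: {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for name, seq in sequences.items()
    }
    index: dict[str, list[str]] = defaultdict(list)
    for name in sorted(kmers):
        for km in kmers[name]:
            index[km].append(name)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for km, names in index.items():
        if len(names) < 2 or len(names) > 50:
            continue
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                counts[(names[i], names[j])] += 1
    return sorted(p for p, c in counts.items() if c >= min_shared)


def _gene_length(model: GeneModel) -> int:
    if model.cds_sequence:
        return len(model.cds_sequence)
    if model.exons:
        return sum(e - s + 1 for s, e in model.exons)
    return model.end - model.start + 1


def _positional_index(models: list[GeneModel]) -> dict[str, tuple[str, int]]:
    """gene -> (chromosome, rank in the all-genes order of that chromosome)."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_chrom[m.chromosome].append(m)
    idx: dict[str, tuple[str, int]] = {}
    for chrom, genes in by_chrom.items():
        for rank, m in enumerate(sorted(genes, key=lambda g: (g.start, g.gene_id))):
            idx[m.gene_id] = (chrom, rank)
    return idx


def _evidence_ok(hit: PairHit, max_evalue: float, min_score: float) -> bool:
    if hit.evalue is not None:
        return hit.evalue < max_evalue
    return hit.score is not None and hit.score >= min_score


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def call_tandem(
    hits: list[PairHit],
    models: list[GeneModel],
    family: set[str],
    coverage: float = 0.8,
    min_identity: float = 80.0,
    max_evalue: float = 1e-10,
    min_score: float = 50.0,
) -> list[TandemCluster]:
    by_id = {m.gene_id: m for m in models}
    pos = _positional_index(models)
    uf = _UnionFind()
    support: dict[tuple[str, str], PairHit] = {}
    linked: set[str] = set()
    for hit in hits:
        q, s = hit.query_id, hit.subject_id
        if q == s:
            continue
        if q not in by_id or s not in by_id:
            raise ValueError(f"hit references unknown gene: {q} / {s}")
        if q not in family or s not in family:
            continue
        chrom_q, rank_q = pos[q]
        chrom_s, rank_s = pos[s]
        if chrom_q != chrom_s or abs(rank_q - rank_s) != 1:
            continue  # criterion 3: an intervening gene (or other chromosome)
        longer = max(_gene_length(by_id[q]), _gene_length(by_id[s]))
        if hit.aln_length < coverage * longer:
            continue
        if hit.pct_identity <= min_identity:
            continue
        if not _evidence_ok(hit, max_evalue, min_score):
            continue
        uf.union(q, s)
        linked.update((q, s))
        support[tuple(sorted((q, s)))] = hit

    comps: dict[str, list[str]] = defaultdict(list)
    for g in sorted(linked):
        comps[uf.find(g)].append(g)
    clusters: list[TandemCluster] = []
    ordered = sorted(
        comps.values(),
        key=lambda ms: (chromosome_sort_key(pos[ms[0]][0]), min(pos[m][1] for m in ms)),
    )
    for i, members in enumerate(ordered, 1):
        members = sorted(members, key=lambda g: pos[g][1])
        pair_hits = [
            support[k]
            for k in sorted(support)
            if k[0] in members and k[1] in members
        ]
        clusters.append(
            TandemCluster(f"TD{i}", pos[members[0]][0], members, pair_hits)
        )
    return clusters


def call_segmental(
    hits: list[PairHit],
    models: list[GeneModel],
    family: set[str],
    min_span: int = 600_000,
    min_identity: float = 90.0,
    min_anchors: int = 2,
    max_evalue: float = 1e-10,
    min_score: float = 50.0,
    chain_gap: int | None = None,
) -> list[SegmentalBlock]:
    """Chain collinear anchor pairs into duplicated blocks.

    Anchors on the same chromosome must be non-adjacent (tandem pairs are
    excluded); a chain keeps a consistent relative orientation and a
    monotone second region (descending only when the orientation is
    flipped); both chained regions must span >= min_span.
    """
    if chain_gap is None:
        chain_gap = min_span
    by_id = {m.gene_id: m for m in models}
    pos = _positional_index(models)

    best: dict[tuple[str, str], PairHit] = {}
    for hit in hits:
        q, s = hit.query_id, hit.subject_id
        if q == s or q not in family or s not in family:
            continue
        if q not in by_id or s not in by_id:
            raise ValueError(f"hit references unknown gene: {q} / {s}")
        if hit.pct_identity < min_identity:
            continue
        if not _evidence_ok(hit, max_evalue, min_score):
            continue
        chrom_q, rank_q = pos[q]
        chrom_s, rank_s = pos[s]
        if chrom_q == chrom_s and abs(rank_q - rank_s) <= 1:
            continue
        key = tuple(sorted((q, s)))
        if key not in best or hit.pct_identity > best[key].pct_identity:
            best[key] = hit

    # canonical anchor orientation: region A holds the earlier gene
    anchors_by_pair: dict[tuple[str, str], list[tuple[GeneModel, GeneModel, PairHit]]] = (
        defaultdict(list)
    )
    for (g1, g2), hit in sorted(best.items()):
        m1, m2 = by_id[g1], by_id[g2]
        key1 = (chromosome_sort_key(m1.chromosome), m1.start)
        key2 = (chromosome_sort_key(m2.chromosome), m2.start)
        a, b = (m1, m2) if key1 <= key2 else (m2, m1)
        anchors_by_pair[(a.chromosome, b.chromosome)].append((a, b, hit))

    blocks: list[SegmentalBlock] = []
    for chrom_pair in sorted(anchors_by_pair):
        anchors = sorted(
            anchors_by_pair[chrom_pair], key=lambda t: (t[0].start, t[1].start)
        )
        chains: list[list[tuple[GeneModel, GeneModel, PairHit]]] = []
        chain: list[tuple[GeneModel, GeneModel, PairHit]] = []
        direction = 0
        for item in anchors:
            a, b, _hit = item
            rel = a.strand == b.strand
            if not chain:
                chain = [item]
                direction = 0
                continue
            pa, pb, _ = chain[-1]
            prev_rel = pa.strand == pb.strand
            gap_a = a.start - pa.end
            step_b = b.start - pb.start
            want = 1 if rel else -1
            ok = (
                rel == prev_rel
                and 0 < gap_a <= chain_gap
                and step_b * want > 0
                and abs(b.start - pb.end if want > 0 else pb.start - b.end) <= chain_gap
            )
            if direction and (1 if step_b > 0 else -1) != direction:
                ok = False
            if ok:
                chain.append(item)
                direction = 1 if step_b > 0 else -1
            else:
                chains.append(chain)
                chain = [item]
                direction = 0
        if chain:
            chains.append(chain)

        for ch in chains:
            if len(ch) < min_anchors:
                continue
            sa = min(a.start for a, _b, _h in ch)
            ea = max(a.end for a, _b, _h in ch)
            sb = min(b.start for _a, b, _h in ch)
            eb = max(b.end for _a, b, _h in ch)
            if ea - sa + 1 < min_span or eb - sb + 1 < min_span:
                continue
            if ch[0][0].chromosome == ch[0][1].chromosome and not (ea < sb or eb < sa):
                continue  # overlapping regions on one chromosome
            blocks.append(
                SegmentalBlock(
                    block_id=f"SB{len(blocks) + 1}",
                    chrom_a=ch[0][0].chromosome,
                    start_a=sa,
                    end_a=ea,
                    chrom_b=ch[0][1].chromosome,
                    start_b=sb,
                    end_b=eb,
                    anchors=[(a.gene_id, b.gene_id) for a, b, _h in ch],
                    mean_identity=sum(h.pct_identity for _a, _b, h in ch) / len(ch),
                )
            )
    return blocks


def find_homolog_groups(
    hits: list[PairHit],
    models: list[GeneModel],
    family: set[str],
    subgenomes: set[str] | None = None,
) -> tuple[list[HomologGroup], float]:
    """Reciprocal-best-hit grouping across subgenomes.

    Returns the groups (singletons included) and the fraction of family
    genes that sit in a group covering every subgenome.  ``subgenomes``
    defaults to the letters observed across all gene models.
    """
    sub: dict[str, str] = {}
    for m in models:
        if m.gene_id in family:
            letter = subgenome_of(m.chromosome)
            if letter is None:
                raise ValueError(
                    f"gene {m.gene_id} on {m.chromosome} has no subgenome label"
                )
            sub[m.gene_id] = letter
    missing = family - set(sub)
    if missing:
        raise ValueError(f"family genes without models: {sorted(missing)[:5]}")
    if subgenomes is None:
        observed = {subgenome_of(m.chromosome) for m in models}
        subgenomes = {s for s in observed if s is not None}
    letters = sorted(subgenomes)

    def strength(h: PairHit) -> float:
        return h.score if h.score is not None else h.pct_identity * h.aln_length

    best: dict[tuple[str, str], tuple[float, str]] = {}
    for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
        for q, s in ((h.query_id, h.subject_id), (h.subject_id, h.query_id)):
            if q not in sub or s not in sub or sub[q] == sub[s]:
                continue
            key = (q, sub[s])
            val = (strength(h), s)
            if key not in best or val > best[key]:
                best[key] = val

    edges: list[tuple[float, str, str]] = []
    seen = set()
    for (q, letter), (sc, s) in best.items():
        back = best.get((s, sub[q]))
        if back and back[1] == q:
            key = tuple(sorted((q, s)))
            if key not in seen:
                seen.add(key)
                edges.append((sc, key[0], key[1]))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    uf = _UnionFind()
    comp_letters: dict[str, set[str]] = {g: {sub[g]} for g in sub}
    for _sc, a, b in edges:
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        if comp_letters[ra] & comp_letters[rb]:
            continue  # would put two genes in one subgenome slot
        uf.union(a, b)
        root = uf.find(a)
        merged = comp_letters[ra] | comp_letters[rb]
        comp_letters[root] = merged

    comps: dict[str, dict[str, str]] = defaultdict(dict)
    for g in sorted(sub):
        comps[uf.find(g)][sub[g]] = g
    groups = [
        HomologGroup(f"HG{i}", members)
        for i, (_root, members) in enumerate(sorted(comps.items()), 1)
    ]
    complete_genes = sum(
        len(g.members) for g in groups if set(g.members) == set(letters)
    )
    fraction = complete_genes / len(sub) if sub else 0.0
    return groups, fraction
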