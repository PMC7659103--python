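"""Core record types passed between pipeline stages.

Coordinates are 1-based inclusive throughout (GFF3 convention); protein
positions are 1-based residue indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass
class GeneModel:
    """A gene's placement and sequence content."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_sequence: str = ""
    protein_sequence: str = ""
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        self.exons = ex

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str
    sequence: str
    is_representative: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id}")
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.protein_id}")


@dataclass(frozen=True)
class DomainHit:
    """One repeat-profile match on a protein (1-based inclusive residues)."""

    protein_id: str
    start: int
    end: int
    score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad hit interval {self.start}..{self.end}")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class RepeatArchitecture:
    gene_id: str
    repeats: list[tuple[int, int]]
    family_class: str = "none"

    @property
    def repeat_count(self) -> int:
        return len(self.repeats)


@dataclass(frozen=True)
class FamilyMember:
    gene_id: str
    assigned_name: str
    family_class: str
    chromosome: str
    start: int


_CHROM_RE = re.compile(r"^(?:chr)?(\d+)([A-Za-z])$", re.IGNORECASE)


def chromosome_sort_key(chrom: str) -> tuple[int, int, str]:
    """Sort key (1..7 ascending, subgenome A<B<D); unparseable labels last."""
    m = _CHROM_RE.match(chrom.strip())
    if not m:
        return (1, 10**9, chrom)
    return (0, int(m.group(1)) * 100 + ord(m.group(2).upper()), "")


def subgenome_of(chrom: str) -> str | None:
    m = _CHROM_RE.match(chrom.strip())
    return m.group(2).upper() if m else None


@dataclass(frozen=True)
class PairHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float | None = None
    score: float | None = None
    query_range: tuple[int, int] | None = None
    subject_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"identity {self.pct_identity} out of range")
        if self.aln_length <= 0:
            raise ValueError("non-positive alignment length")


@dataclass
class TandemCluster:
    cluster_id: str
    chromosome: str
    members: list[str]
    hits: list[PairHit] = field(default_factory=list)


@dataclass
class SegmentalBlock:
    block_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    anchors: list[tuple[str, str]] = field(default_factory=list)
    mean_identity: float = 0.0

    @property
    def span_a(self) -> int:
        return self.end_a - self.start_a + 1

    @property
    def span_b(self) -> int:
        return self.end_b - self.start_b + 1


@dataclass
class HomologGroup:
    group_id: str
    members: dict[str, str]  # subgenome letter -> gene_id

    @property
    def completeness(self) -> int:
        return len(self.members)


@dataclass
class KaKsResult:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    selection_label: str
    path_fallback: bool = False


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    timepoint: str = ""
    replicate: int = 1


@dataclass
class ExpressionDesign:
    samples: list[Sample]
    contrasts: list[tuple[str, str]]  # (treated_condition, control_condition)

    def __post_init__(self) -> None:
        conds = {s.condition for s in self.samples}
        for t, c in self.contrasts:
            if t not in conds or c not in conds:
                raise ValueError(f"contrast ({t}, {c}) references unknown condition")

    def samples_of(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    contrast: str
    log2fc: float
    p_value: float
    status: str  # up / down / ns / undetected


@dataclass(frozen=True)
class QpcrMeasurement:
    sample: str
    target_ct: float
    reference_ct: float
    group: str  # treated / calibrator


@dataclass(frozen=True)
class MotifOccurrence:
    gene_id: str
    motif_name: str
    strand: str
    offset: int  # 1-based from the promoter 5' end
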