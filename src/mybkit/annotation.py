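"""Gene-structure and protein physicochemical characterization plus
promoter cis-element scanning."""

from __future__ import annotations

import re
from typing import Mapping, NamedTuple

from .models import GeneModel, MotifOccurrence

# ExPASy-style average residue masses (Da); water added once per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524
_X_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / 20.0

# Bjellqvist pKa set (the constants the ExPASy tool family uses)
_POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PK_NTERMINAL = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
_PK_CTERMINAL = {"D": 4.55, "E": 4.75}


def count_introns(model: GeneModel) -> int:
    if model.n_exons == 0:
        raise ValueError(f"gene {model.gene_id} has no exons")
    return model.n_exons - 1


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in kilodaltons; X contributes the mean
    residue mass."""
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for aa in sequence.upper():
        if aa == "X":
            total += _X_MASS
        else:
            try:
                total += AVERAGE_RESIDUE_MASS[aa]
            except KeyError:
                raise ValueError(f"unknown residue {aa!r}") from None
    return total / 1000.0


def _net_charge(sequence: str, ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - _PK_NTERMINAL.get(sequence[0], _POSITIVE_PKS["Nterm"])))
    charge -= 1.0 / (1.0 + 10 ** (_PK_CTERMINAL.get(sequence[-1], _NEGATIVE_PKS["Cterm"]) - ph))
    for aa, pk in _POSITIVE_PKS.items():
        if len(aa) == 1:
            charge += sequence.count(aa) / (1.0 + 10 ** (ph - pk))
    for aa, pk in _NEGATIVE_PKS.items():
        if len(aa) == 1:
            charge -= sequence.count(aa) / (1.0 + 10 ** (pk - ph))
    return charge


def isoelectric_point(sequence: str, tolerance: float = 1e-3) -> float:
    """pH of zero net charge by bisection over (0, 14)."""
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if _net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class Promoter(NamedTuple):
    sequence: str
    truncated: bool


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def extract_promoter(
    chromosomes: Mapping[str, str], model: GeneModel, length: int = 1500
) -> Promoter:
    """Upstream promoter, strand-aware, truncated (and flagged) at
    chromosome edges."""
    try:
        chrom = chromosomes[model.chromosome]
    except KeyError:
        raise ValueError(f"chromosome {model.chromosome} not loaded") from None
    if model.strand == "+":
        lo = max(1, model.start - length)
        seq = chrom[lo - 1 : model.start - 1]
    else:
        hi = min(len(chrom), model.end + length)
        seq = _revcomp(chrom[model.end : hi])
    return Promoter(seq.upper(), truncated=len(seq) < length)


IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_revcomp(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMP)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        try:
            opts = IUPAC_CODES[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {ch!r} in pattern {pattern!r}") from None
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motifs(
    promoter: str,
    dictionary: Mapping[str, str],
    both_strands: bool = True,
    gene_id: str = "",
) -> list[MotifOccurrence]:
    """Exact IUPAC occurrences; offsets are 1-based window starts on the
    promoter (5' end), for both strands when requested."""
    promoter = promoter.upper()
    occurrences: list[MotifOccurrence] = []
    for name in sorted(dictionary):
        pattern = dictionary[name]
        for strand, pat in (("+", pattern), ("-", _iupac_revcomp(pattern))):
            if strand == "-" and not both_strands:
                continue
            rx = _iupac_regex(pat)
            for m in rx.finditer(promoter):
                occurrences.append(
                    MotifOccurrence(gene_id, name, strand, m.start() + 1)
                )
    occurrences.sort(key=lambda o: (o.offset, o.motif_name, o.strand))
    return occurrences
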