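"""Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.

Site counts use stop-excluded one-step denominators; between-codon
differences are averaged over all substitution orderings that avoid stop
codons (with a flagged per-position fallback when every ordering is
blocked).  Rates saturate at p >= 3/4, where the corrected rate — and any
ratio built from it — is reported as undefined rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ..codons import codon_pair_differences, codon_site_counts, is_stop, translate


@dataclass
class CodonAlignment:
    """Two (or more) equal-length codon-aligned CDS rows; gaps are whole
    codons ('---')."""

    ids: list[str]
    rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length not divisible by 3")
        for rid, row in zip(self.ids, self.rows):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon:
                    continue
                if is_stop(codon) and i + 3 < len(row):
                    raise ValueError(f"internal stop codon in {rid} at column {i}")


def codon_align(
    cds_a: str, cds_b: str, protein_alignment: tuple[str, str],
    ids: tuple[str, str] = ("a", "b"),
) -> CodonAlignment:
    """Back-translate a pairwise protein alignment onto the two CDS."""
    rows = []
    for cds, aln in zip((cds_a, cds_b), protein_alignment):
        cds = cds.upper()
        protein = translate(cds)
        residues = aln.replace("-", "")
        if residues != protein[: len(residues)] or len(residues) != len(protein):
            for k, (x, y) in enumerate(zip(residues, protein)):
                if x != y:
                    raise ValueError(
                        f"protein alignment disagrees with translation at residue {k + 1}"
                    )
            raise ValueError(
                f"protein alignment has {len(residues)} residues, translation has "
                f"{len(protein)}"
            )
        out = []
        cursor = 0
        for aa in aln:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[cursor : cursor + 3])
                cursor += 3
        rows.append("".join(out))
    return CodonAlignment(ids=list(ids), rows=rows)


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(alignment: CodonAlignment, pair_id: str = "") -> "KaKsResult":
    from ..models import KaKsResult

    if len(alignment.rows) != 2:
        raise ValueError("NG86 needs exactly two aligned sequences")
    row_a, row_b = alignment.rows
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    compared = 0
    fallback = False
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if is_stop(ca) or is_stop(cb):
            continue  # trailing stop column
        compared += 1
        sa, _ = codon_site_counts(ca)
        sb, _ = codon_site_counts(cb)
        S_a += sa
        S_b += sb
        sd, nd, flagged = codon_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
        fallback = fallback or flagged
    if compared == 0:
        raise ValueError("no comparable (ungapped) codon columns")

    S = (S_a + S_b) / 2.0
    N = 3.0 * compared - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(pS)
    Ka = _jc_correct(pN)
    if Ks is None or Ks == 0.0 or Ka is None:
        ratio = None
        label = "undefined"
    else:
        ratio = Ka / Ks
        if abs(ratio - 1.0) < 1e-9:
            label = "neutral"
        elif ratio < 1.0:
            label = "purifying"
        else:
            label = "positive"
    return KaKsResult(
        pair_id=pair_id,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ka=Ka,
        Ks=Ks,
        ratio=ratio,
        selection_label=label,
        path_fallback=fallback,
    )
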