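"""Genetic-code helpers shared by the simulator and the Ka/Ks estimator.

The standard code (NCBI translation table 1) is taken from Biopython; the
site/difference bookkeeping built on top of it is local because it encodes
the exact counting conventions used downstream (stop-excluded one-step
denominators, path averaging over substitution orderings).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(cds: str) -> str:
    """Translate a CDS (no internal stops allowed, length % 3 == 0)."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        try:
            aa = CODON_TO_AA[codon]
        except KeyError:
            raise ValueError(f"invalid codon {codon!r} at nucleotide {i}") from None
        if aa == "*":
            if i + 3 == len(cds):
                break  # trailing stop tolerated
            raise ValueError(f"internal stop codon {codon} at nucleotide {i}")
        aas.append(aa)
    return "".join(aas)


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) for one codon.

    Per position the synonymous fraction is the number of one-step
    synonymous changes divided by the number of one-step changes that do
    not create a stop; changes to stop codons are excluded from both
    numerator and denominator.  s + n == 3 exactly.
    """
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    s = 0.0
    aa0 = CODON_TO_AA[codon]
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(alt):
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa0:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_pair_differences(a: str, b: str) -> tuple[float, float, bool]:
    """Average (sd, nd) between two sense codons, with a fallback flag.

    All orderings of the differing positions are enumerated; paths passing
    through a stop codon are discarded and the synonymous/nonsynonymous
    step counts are averaged over the surviving paths.  If every path hits
    a stop, each differing position is classified independently by mutating
    it alone in ``a`` (flagged True).
    """
    if is_stop(a) or is_stop(b):
        raise ValueError("stop codons cannot be compared")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0, False
    path_sd: list[float] = []
    path_nd: list[float] = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            path_sd.append(sd)
            path_nd.append(nd)
    if path_sd:
        k = len(path_sd)
        return sum(path_sd) / k, sum(path_nd) / k, False
    # all paths blocked by stops: final-state per-position comparison
    sd = nd = 0
    for pos in diff:
        alt = a[:pos] + b[pos] + a[pos + 1 :]
        if not is_stop(alt) and CODON_TO_AA[alt] == CODON_TO_AA[a]:
            sd += 1
        else:
            nd += 1
    return float(sd), float(nd), True


def synonymous_codons(aa: str) -> tuple[str, ...]:
    return tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
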