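"""Plant synonymous/nonsynonymous substitutions at controlled NG86-scale rates.

The target rates are the Jukes–Cantor-corrected Ka/Ks an estimator should
recover, so the planted numbers of observed differences are obtained by
inverting the correction: p = 3/4 (1 - exp(-4 rate / 3)), then
n_syn = round(pS * S) and n_nonsyn = round(pN * N) with (S, N) counted on
the input sequence.  Substitutions are spread over distinct codons where
possible (single-difference codons classify unambiguously), never create a
stop, and never touch the same nucleotide twice.
"""

from __future__ import annotations

import math

import numpy as np

from ..codons import BASES, CODON_TO_AA, codon_site_counts, is_stop


class DivergenceRangeError(ValueError):
    """Requested divergence cannot be realized on this sequence."""


def _planted_counts(cds: str, target_ks: float, target_ka: float) -> tuple[int, int]:
    if target_ks < 0 or target_ka < 0:
        raise DivergenceRangeError("divergence targets must be >= 0")
    p_s = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    p_n = 0.75 * (1.0 - math.exp(-4.0 * target_ka / 3.0))
    if p_s >= 0.75 - 1e-6 or p_n >= 0.75 - 1e-6:
        raise DivergenceRangeError("target beyond Jukes-Cantor saturation (p >= 0.75)")
    S = N = 0.0
    for i in range(0, len(cds), 3):
        s, n = codon_site_counts(cds[i : i + 3])
        S += s
        N += n
    return round(p_s * S), round(p_n * N)


def simulate_codon_divergence(
    cds: str, target_ks: float, target_ka: float, seed: int
) -> str:
    """Return a copy of ``cds`` diverged to ~(target_ka, target_ks).

    Deterministic for a fixed seed; raises :class:`DivergenceRangeError` for
    unreachable targets and ``ValueError`` for malformed input.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons):
        if is_stop(c):
            raise ValueError(f"stop codon at codon index {i}")
        if c not in CODON_TO_AA:
            raise ValueError(f"invalid codon {c!r} at codon index {i}")

    n_syn, n_nonsyn = _planted_counts(cds, target_ks, target_ka)
    if n_syn == 0 and n_nonsyn == 0:
        return cds

    rng = np.random.default_rng(seed)
    budgets = {"syn": n_syn, "non": n_nonsyn}
    used_positions: set[tuple[int, int]] = set()

    # two passes: first at most one change per codon, then (if budgets
    # remain) additional changes at still-untouched positions
    for allow_touched in (False, True):
        if budgets["syn"] == 0 and budgets["non"] == 0:
            break
        order = rng.permutation(len(codons))
        touched = {i for (i, _p) in used_positions}
        for ci in order:
            if budgets["syn"] == 0 and budgets["non"] == 0:
                break
            if not allow_touched and ci in touched:
                continue
            options = []
            for pos in range(3):
                if (ci, pos) in used_positions:
                    continue
                for b in BASES:
                    if b == codons[ci][pos]:
                        continue
                    alt = codons[ci][:pos] + b + codons[ci][pos + 1 :]
                    if is_stop(alt):
                        continue
                    cat = "syn" if CODON_TO_AA[alt] == CODON_TO_AA[codons[ci]] else "non"
                    if budgets[cat] > 0:
                        options.append((pos, b, alt, cat))
            if not options:
                continue
            pos, b, alt, cat = options[rng.integers(len(options))]
            codons[ci] = alt
            budgets[cat] -= 1
            used_positions.add((ci, pos))
            touched.add(ci)

    if budgets["syn"] or budgets["non"]:
        raise DivergenceRangeError(
            f"could not place requested substitutions "
            f"(remaining syn={budgets['syn']}, nonsyn={budgets['non']})"
        )
    return "".join(codons)
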