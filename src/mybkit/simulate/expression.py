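"""TPM-like expression matrices with planted up/down genes.

Counts follow a gamma-multiplicative negative-binomial-style noise model:
value = condition_mean * Gamma(1/dispersion, dispersion), after which each
sample is scaled to a fixed library size (sum 1e6), mirroring TPM
normalization without read-level simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..models import ExpressionDesign, Sample
from .genome import TruthRecord


def default_stress_design(n_replicates: int = 3) -> ExpressionDesign:
    """Drought/heat/combined stress at 1 h and 6 h vs an untreated control."""
    conditions = ["CK", "D_1", "D_6", "H_1", "H_6", "DH_1", "DH_6"]
    samples = [
        Sample(f"{cond}_r{r}", cond, cond.split("_")[1] if "_" in cond else "0", r)
        for cond in conditions
        for r in range(1, n_replicates + 1)
    ]
    contrasts = [(c, "CK") for c in conditions if c != "CK"]
    return ExpressionDesign(samples=samples, contrasts=contrasts)


def generate_expression(
    genes: list[str],
    design: ExpressionDesign,
    planted_up: float = 0.1,
    planted_down: float = 0.1,
    effect_range: tuple[float, float] = (1.5, 4.0),
    dispersion: float = 0.1,
    seed: int = 0,
    mean_log2_range: tuple[float, float] = (2.0, 9.0),
    scale_mode: str = "per_sample",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Genes x samples TPM-like matrix plus the planted truth.

    ``planted_up``/``planted_down`` are per-contrast fractions; each treated
    condition gets its own independent draw of regulated genes.
    """
    if not genes:
        raise ValueError("empty gene list")
    if planted_up < 0 or planted_down < 0 or planted_up + planted_down > 1:
        raise ValueError("planted fractions must be >= 0 and sum to <= 1")
    if scale_mode not in ("per_sample", "global", "none"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")

    rng = np.random.default_rng(seed)
    n = len(genes)
    baseline = 2.0 ** rng.uniform(*mean_log2_range, size=n)

    conditions = sorted({s.condition for s in design.samples})
    cond_mean = {c: baseline.copy() for c in conditions}

    truth = TruthRecord()
    n_up = int(round(planted_up * n))
    n_down = int(round(planted_down * n))
    for treated, control in design.contrasts:
        contrast_name = f"{treated}_vs_{control}"
        chosen = rng.permutation(n)[: n_up + n_down]
        status = {}
        for idx in chosen[:n_up]:
            lfc = float(rng.uniform(*effect_range))
            cond_mean[treated][idx] = baseline[idx] * 2.0**lfc
            status[genes[idx]] = {"status": "up", "log2fc": lfc}
        for idx in chosen[n_up:]:
            lfc = -float(rng.uniform(*effect_range))
            cond_mean[treated][idx] = baseline[idx] * 2.0**lfc
            status[genes[idx]] = {"status": "down", "log2fc": lfc}
        for g in genes:
            if g not in status:
                status[g] = {"status": "null", "log2fc": 0.0}
        truth.expression[contrast_name] = status

    cols = {}
    for s in design.samples:
        mu = cond_mean[s.condition]
        if dispersion > 0:
            noise = rng.gamma(1.0 / dispersion, dispersion, size=n)
        else:
            noise = np.ones(n)
        cols[s.sample_id] = mu * noise
    matrix = pd.DataFrame(cols, index=list(genes))

    if scale_mode == "per_sample":
        matrix = matrix * (1e6 / matrix.sum(axis=0))
    elif scale_mode == "global":
        matrix = matrix * (1e6 / matrix.sum(axis=0).mean())
    return matrix, truth
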