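"""TPM normalization, differential screening, profile clustering and qPCR
relative expression.

Z-score rows standardize log2(TPM + pseudocount) across samples; screening
calls up/down when |log2FC| exceeds the fold-change threshold AND the
replicate-level p-value clears alpha (no multiple-testing correction by
default — an FDR option is exposed but off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import DifferentialCall, ExpressionDesign, QpcrMeasurement


@dataclass
class ZScoreMatrix:
    values: pd.DataFrame
    flagged: list[str] = field(default_factory=list)  # zero-variance genes


def zscore_normalize(
    matrix: pd.DataFrame, pseudocount: float = 1.0, ddof: int = 1
) -> ZScoreMatrix:
    """Per-gene standardization of log2(TPM + pseudocount)."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples for a standard deviation")
    if (matrix.values < 0).any():
        raise ValueError("negative TPM values")
    logged = np.log2(matrix + pseudocount)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=ddof)
    flagged = list(matrix.index[sd == 0])
    sd_safe = sd.replace(0, 1.0)
    z = logged.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[flagged] = 0.0
    return ZScoreMatrix(values=z, flagged=flagged)


def _welch_or_pooled(
    treated: np.ndarray, control: np.ndarray, equal_var: bool
) -> np.ndarray:
    """Row-wise t-test p-values with a zero-variance special case."""
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(treated, control, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    var_t = treated.var(axis=1, ddof=1)
    var_c = control.var(axis=1, ddof=1)
    degenerate = (var_t == 0) & (var_c == 0)
    same_mean = np.isclose(treated.mean(axis=1), control.mean(axis=1))
    p[degenerate & same_mean] = 1.0
    p[degenerate & ~same_mean] = 0.0
    p[np.isnan(p)] = 1.0
    return p


def screen_differential(
    matrix: pd.DataFrame,
    design: ExpressionDesign,
    contrast: tuple[str, str],
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    equal_var: bool = False,
    fdr: bool = False,
) -> list[DifferentialCall]:
    treated_cond, control_cond = contrast
    if (treated_cond, control_cond) not in design.contrasts:
        raise ValueError(f"contrast {contrast} not in design")
    t_cols = design.samples_of(treated_cond)
    c_cols = design.samples_of(control_cond)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    treated = matrix[t_cols].to_numpy(float)
    control = matrix[c_cols].to_numpy(float)

    log2fc = np.log2(
        (treated.mean(axis=1) + pseudocount) / (control.mean(axis=1) + pseudocount)
    )
    logged_t = np.log2(treated + pseudocount)
    logged_c = np.log2(control + pseudocount)
    p = _welch_or_pooled(logged_t, logged_c, equal_var)
    if fdr:
        p = _benjamini_hochberg(p)

    undetected = (treated == 0).all(axis=1) & (control == 0).all(axis=1)
    name = f"{treated_cond}_vs_{control_cond}"
    calls = []
    for i, gene in enumerate(matrix.index):
        if undetected[i]:
            status = "undetected"
        elif log2fc[i] > fc_threshold and p[i] < alpha:
            status = "up"
        elif log2fc[i] < -fc_threshold and p[i] < alpha:
            status = "down"
        else:
            status = "ns"
        calls.append(DifferentialCall(str(gene), name, float(log2fc[i]), float(p[i]), status))
    return calls


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def hierarchical_cluster(z: ZScoreMatrix, k: int) -> dict[str, int]:
    """Average-linkage clustering of z-rows at distance 1 - Pearson r,
    cut into k groups; flagged rows are excluded."""
    from scipy.cluster import hierarchy

    usable = z.values.drop(index=z.flagged, errors="ignore")
    n = len(usable)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} clusterable genes")
    if k == n:
        return {g: i + 1 for i, g in enumerate(usable.index)}
    link = hierarchy.linkage(usable.to_numpy(float), method="average", metric="correlation")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return {str(g): int(lbl) for g, lbl in zip(usable.index, labels)}


def ddct(measurements: list[QpcrMeasurement]) -> dict[str, float]:
    """Livak 2^-ddCt relative expression per sample, calibrated against the
    mean dCt of the calibrator group."""
    if not measurements:
        raise ValueError("no measurements")
    dct = {m.sample: m.target_ct - m.reference_ct for m in measurements}
    calib = [dct[m.sample] for m in measurements if m.group == "calibrator"]
    if not calib:
        raise ValueError("no calibrator sample")
    baseline = sum(calib) / len(calib)
    return {s: 2.0 ** -(v - baseline) for s, v in dct.items()}


def summarize_calls(calls: list[DifferentialCall]) -> pd.DataFrame:
    """Up/down/ns/undetected counts per contrast (the per-stress tally)."""
    rows: dict[str, dict[str, int]] = {}
    for c in calls:
        rows.setdefault(c.contrast, {"up": 0, "down": 0, "ns": 0, "undetected": 0})
        rows[c.contrast][c.status] += 1
    return pd.DataFrame(rows).T.sort_index()
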