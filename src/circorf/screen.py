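"""Expression screen: paired fold changes, DE test, recurrence, ROC.

The decision rule of the screen is |fold change| > 2 and p < 0.05 on a paired
tumor/normal design, with an additional recurrence requirement (per-pair fold
change > 2 in at least k of n pairs).  The group test is a paired two-sided
t-test on log2(TPM + pseudocount); a Benjamini-Hochberg-adjusted column is
available behind a flag but the default decision uses raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "ROCResult",
    "per_pair_fold_change",
    "de_test",
    "recurrence_filter",
    "roc_biomarker",
]


def _paired_matrices(
    tpm: pd.DataFrame, design: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Align tumor and normal sample columns pair by pair."""
    pairs = sorted(design["pair"].unique())
    t_cols, n_cols = [], []
    for p in pairs:
        sub = design[design["pair"] == p]
        t = sub[sub["condition"] == "tumor"]["sample"].tolist()
        n = sub[sub["condition"] == "normal"]["sample"].tolist()
        if len(t) != 1 or len(n) != 1:
            raise InputError(
                f"design error: pair {p} must have exactly one tumor and one normal sample"
            )
        t_cols.append(t[0])
        n_cols.append(n[0])
    return tpm[t_cols].to_numpy(float), tpm[n_cols].to_numpy(float), pairs


def per_pair_fold_change(
    tpm: pd.DataFrame, design: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-pair tumor/normal fold change: (t + eps) / (n + eps)."""
    T, N, pairs = _paired_matrices(tpm, design)
    fc = (T + pseudocount) / (N + pseudocount)
    return pd.DataFrame(fc, index=tpm.index, columns=[f"pair_{p}" for p in pairs])


def recurrence_filter(
    per_pair_fc: pd.DataFrame, k: int = 3, threshold: float = 2.0
) -> pd.Series:
    """Flag features with per-pair FC strictly above ``threshold`` in >= k pairs."""
    if k > per_pair_fc.shape[1]:
        raise InputError(f"recurrence k={k} exceeds number of pairs {per_pair_fc.shape[1]}")
    return (per_pair_fc > threshold).sum(axis=1) >= k


def de_test(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    recurrence_k: int = 3,
    recurrence_fc: float = 2.0,
    bh: bool = False,
) -> pd.DataFrame:
    """Paired two-sided t-test on log2(TPM + pseudocount), plus screen flags.

    Returns one row per feature, sorted by p-value, with ``log2fc`` (mean of
    per-pair log2 ratios), ``p_value``, per-pair fold changes, ``recurrence``
    (count of pairs with FC > recurrence_fc), ``passes_de``
    (|FC| > fc_threshold and p < alpha) and ``passes_recurrence``.  Features
    with zero variance across pairs get p = 1 and a ``degenerate`` flag.
    """
    T, N, pairs = _paired_matrices(tpm, design)
    if len(pairs) < 2:
        raise InputError("de_test requires at least 2 pairs")
    diffs = np.log2(T + pseudocount) - np.log2(N + pseudocount)
    log2fc = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    degenerate = sd == 0
    n = diffs.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = log2fc / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    p = np.where(degenerate, 1.0, p)
    fc_df = per_pair_fold_change(tpm, design, pseudocount)
    recurrence = (fc_df > recurrence_fc).sum(axis=1).to_numpy()
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "recurrence": recurrence,
            "degenerate": degenerate,
            "passes_de": (np.abs(log2fc) > np.log2(fc_threshold)) & (p < alpha),
            "passes_recurrence": recurrence >= recurrence_k,
        },
        index=tpm.index,
    )
    if bh:
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    out = pd.concat([out, fc_df], axis=1)
    return out.sort_values("p_value")


@dataclass
class ROCResult:
    """Rank-based AUC plus the Youden-optimal cutoff (at an observed value)."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray

    def trapezoid_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_biomarker(values, labels) -> ROCResult:
    """ROC analysis of a continuous marker against binary labels.

    AUC is the tie-corrected Mann-Whitney statistic (probability a random
    positive outranks a random negative).  The cutoff maximizes Youden's
    J = sensitivity + specificity - 1 under the rule "positive iff
    value >= cutoff", evaluated at observed values; J-ties break toward
    higher specificity, then toward the larger cutoff.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise InputError("roc_biomarker: values and labels differ in length")
    pos, neg = v[y == 1], v[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("roc_biomarker: both label classes must be present")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (len(pos) * len(neg))
    cutoffs = np.unique(v)
    best = None
    for c in cutoffs:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        key = (j, spec, c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    # full curve: thresholds descending, (0,0) -> (1,1)
    thr = np.concatenate(([np.inf], np.sort(cutoffs)[::-1]))
    tpr = np.array([np.mean(pos >= t) for t in thr])
    fpr = np.array([np.mean(neg >= t) for t in thr])
    return ROCResult(
        auc=auc, cutoff=float(best[1]), sensitivity=best[2], specificity=best[3],
        fpr=fpr, tpr=tpr,
    )
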