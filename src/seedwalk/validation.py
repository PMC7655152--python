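"""Expression-validation statistics: 2^-ddCt, group comparison, ROC/AUC.

Relative expression from qPCR cycle thresholds follows the standard
2^-ddCt transform: dCt = Ct(target) - Ct(reference gene) per sample,
ddCt = dCt - mean dCt of the calibrator group, fold change = 2^-ddCt.
Lower dCt means higher expression.

Group comparison uses Welch's two-sample t-test (no equal-variance
assumption), on the dCt scale by default. Diagnostic performance is the
area under the ROC curve in its probabilistic pair-counting form,
AUC = P[score_pos > score_neg] + 0.5 P[tie], equivalent to the
Mann-Whitney U statistic scaled by the number of pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["read_ct_table", "delta_ct", "ddct_fold_change",
           "relative_expression", "compare_groups", "auc_roc", "roc_points"]

CT_COLUMNS = ("sample_id", "group", "ct_target", "ct_reference")


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct table TSV with columns sample_id, group, ct_target,
    ct_reference; Ct values must be finite."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("ct_target", "ct_reference"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise ValueError(f"{path}: non-finite Ct values in {col}")
    return df


def delta_ct(table: pd.DataFrame) -> pd.Series:
    """Per-sample dCt = Ct(target) - Ct(reference)."""
    return table["ct_target"] - table["ct_reference"]


def ddct_fold_change(dct, calibrator_mean_dct: float) -> np.ndarray | float:
    """Fold change 2^-(dCt - calibrator mean dCt)."""
    ddct = np.asarray(dct, dtype=float) - calibrator_mean_dct
    out = np.power(2.0, -ddct)
    return float(out) if out.ndim == 0 else out


def relative_expression(table: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-sample fold changes relative to the calibrator group's mean dCt."""
    groups = set(table["group"])
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} not in table")
    dct = delta_ct(table)
    calibrator = float(dct[table["group"] == calibrator_group].mean())
    out = table.copy()
    out["dct"] = dct
    out["fold_change"] = ddct_fold_change(dct.to_numpy(), calibrator)
    return out


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Welch two-sample two-sided t-test; returns (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def auc_roc(scores_pos, scores_neg) -> float:
    """AUC by pair counting: (#{pos > neg} + 0.5 #{pos == neg}) / (n+ * n-)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return float(wins / (pos.size * neg.size))


def roc_points(scores_pos, scores_neg) -> pd.DataFrame:
    """ROC curve points (threshold, tpr, fpr), score >= threshold positive."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([pos, neg]))[::-1]))
    rows = [
        (float(t), float((pos >= t).mean()), float((neg >= t).mean()))
        for t in thresholds
    ]
    return pd.DataFrame(rows, columns=["threshold", "tpr", "fpr"])
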