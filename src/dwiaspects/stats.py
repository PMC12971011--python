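"""Agreement and diagnostic-performance statistics.

Dice overlap, Spearman correlation with Fisher-z CI, intraclass
correlation (two-way random effects, absolute agreement, single
measurement — ICC(2,1) — with the consistency form behind a flag),
Mann-Whitney / chi-square / Fisher group comparison with the small-count
rule (Fisher's exact when every contingency cell is below 10), empirical
ROC with the Youden operating point, and the DeLong test for paired AUCs.

ROC direction must be stated per marker: an ASPECTS score flags the
positive (moderate-severe) class at the *low* tail (score <= threshold),
a core volume at the *high* tail (volume >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .volume_io import LabeledVolume


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# overlap

def dice(a: LabeledVolume | np.ndarray, b: LabeledVolume | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    da = a.data if isinstance(a, LabeledVolume) else np.asarray(a)
    db = b.data if isinstance(b, LabeledVolume) else np.asarray(b)
    if isinstance(a, LabeledVolume) and isinstance(b, LabeledVolume):
        if not a.same_grid(b):
            raise StatsError("dice requires masks on the same grid")
    elif da.shape != db.shape:
        raise StatsError("dice requires masks of equal shape")
    for d in (da, db):
        if not np.isin(np.unique(d), (0, 1)).all():
            raise StatsError("dice requires binary masks")
    da, db = da > 0, db > 0
    na, nb = int(da.sum()), int(db.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((da & db).sum()) / (na + nb)


# ---------------------------------------------------------------------------
# correlation / agreement

@dataclass
class AgreementResult:
    spearman_r: float
    spearman_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    n: int


def spearman_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation with a Fisher-z normal-approximation CI.

    Ties receive average ranks. The CI uses the Bonett-Wright standard
    error sqrt((1 + r^2/2) / (n - 3)) on the z scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 4:
        raise StatsError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("correlation undefined for constant input")
    r = float(sps.spearmanr(x, y).statistic)
    if abs(r) >= 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    se = np.sqrt((1 + r ** 2 / 2) / (n - 3))
    zc = sps.norm.ppf(1 - alpha / 2)
    return r, (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def icc_mean_squares(ratings: np.ndarray, form: str = "absolute") -> float:
    """ICC point estimate straight from the two-way mean-squares decomposition.

    ``absolute`` -> ICC(2,1); ``consistency`` -> ICC(3,1). Kept as a
    transparent reference formula; :func:`icc_absolute_agreement` adds the
    F-based CI.
    """
    r = np.asarray(ratings, dtype=float)
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((r - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "absolute":
        return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
    if form == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise StatsError(f"unknown ICC form {form!r}")


def icc_absolute_agreement(
    ratings: np.ndarray, alpha: float = 0.05, form: str = "absolute"
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) (or ICC(3,1) with ``form='consistency'``) with F-based CI.

    ``ratings`` is an n-subjects x k-raters table with no missing cells;
    n >= 5 and k >= 2 required.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise StatsError("ratings must be an n x k table")
    n, k = r.shape
    if n < 5 or k < 2:
        raise StatsError("need >= 5 subjects and >= 2 raters")
    if np.isnan(r).any():
        raise StatsError("missing cells are not supported")

    import pingouin as pg

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": r.ravel(),
    })
    icc_table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
    kind = "ICC(A,1)" if form == "absolute" else "ICC(C,1)"
    ci_col = next(c for c in icc_table.columns if c.startswith("CI95"))
    row = icc_table[icc_table["Type"] == kind].iloc[0]
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))


def agreement(x, y, alpha: float = 0.05) -> AgreementResult:
    """Spearman + ICC(2,1) between two paired measurement vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, rci = spearman_ci(x, y, alpha)
    icc, icc_ci = icc_absolute_agreement(np.column_stack([x, y]), alpha)
    return AgreementResult(r, rci, icc, icc_ci, n=len(x))


# ---------------------------------------------------------------------------
# ROC / Youden / DeLong

@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    direction: str  # 'high' -> positive iff score >= threshold; 'low' -> <=

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "threshold": self.threshold, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "accuracy": self.accuracy,
            "direction": self.direction,
        }


def _check_roc_inputs(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise StatsError("scores and labels must be 1-D of equal length")
    if not np.isin(np.unique(labels), (0, 1)).all():
        raise StatsError("labels must be binary {0,1}")
    if labels.min() == labels.max():
        raise StatsError("both classes must be present")
    return scores, labels


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance) for one marker via the midrank formulation."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, p in enumerate(pos):
        v10[i] = (np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
    for j, q in enumerate(neg):
        v01[j] = (np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return float(auc), float(var)


def roc_youden(scores, labels, direction: str = "high",
               alpha: float = 0.05) -> RocResult:
    """Empirical ROC with the Youden-index operating point.

    ``direction='high'`` treats large scores as positive-class evidence
    (core volume); ``'low'`` treats small scores as positive (ASPECTS).
    AUC equals the normalised Mann-Whitney statistic; the optimal threshold
    maximises sensitivity + specificity - 1, ties broken toward higher
    sensitivity; the threshold is an observed score value. The AUC CI is a
    normal interval on the DeLong variance, clipped to [0,1].
    """
    if direction not in ("high", "low"):
        raise StatsError("direction must be 'high' or 'low'")
    scores, labels = _check_roc_inputs(scores, labels)
    s = scores if direction == "high" else -scores
    fpr, tpr, thresholds = roc_curve(labels, s, drop_intermediate=False)
    auc, var = _delong_variance(s, labels)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # thresholds are sorted by decreasing s, i.e. increasing tpr: take the
    # last maximiser to break ties toward higher sensitivity
    k = int(best[np.argmax(tpr[best])])
    thr = float(thresholds[k])
    if not np.isfinite(thr):  # sklearn's sentinel above the max score
        thr = float(s.max())
    threshold = thr if direction == "high" else -thr

    if direction == "high":
        pred = scores >= threshold
    else:
        pred = scores <= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / int(np.sum(labels == 1))
    spec = tn / int(np.sum(labels == 0))
    acc = (tp + tn) / len(labels)
    zc = sps.norm.ppf(1 - alpha / 2)
    half = zc * np.sqrt(var)
    return RocResult(
        auc=auc, auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
        threshold=threshold, sensitivity=sens, specificity=spec,
        accuracy=acc, direction=direction,
    )


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong two-sided test comparing two paired empirical AUCs.

    Returns (auc_a, auc_b, p). Scores must be paired on the same subjects.
    An exactly-zero AUC difference (e.g. identical or rank-equivalent
    score vectors) yields p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise StatsError("paired score vectors must have equal length")
    _, labels = _check_roc_inputs(scores_a, labels)

    pos_a, neg_a = scores_a[labels == 1], scores_a[labels == 0]
    pos_b, neg_b = scores_b[labels == 1], scores_b[labels == 0]
    m, n = len(pos_a), len(neg_a)

    def structural(pos, neg):
        v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg)
                        for p in pos])
        v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos)
                        for q in neg])
        return v10, v01

    v10a, v01a = structural(pos_a, neg_a)
    v10b, v01b = structural(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if diff == 0.0:
        return auc_a, auc_b, 1.0
    if var_diff <= 0:
        return auc_a, auc_b, 0.0
    z = diff / np.sqrt(var_diff)
    p = float(2 * sps.norm.sf(abs(z)))
    return auc_a, auc_b, p


# ---------------------------------------------------------------------------
# group comparison

def group_compare(values, group_labels, variable_kind: str) -> tuple[str, float, float]:
    """Two-group comparison returning (test name, statistic, p).

    Continuous variables use the Mann-Whitney U test (two groups).
    Categorical variables build the group x category contingency table and
    apply the small-count rule: Fisher's exact test when every cell count
    is below 10 (2x2 tables), otherwise the chi-square test without
    continuity correction.
    """
    values = np.asarray(values)
    groups = np.asarray(group_labels)
    if values.shape != groups.shape:
        raise StatsError("values and group labels must align")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise StatsError("need at least two groups")

    if variable_kind == "continuous":
        if len(uniq) != 2:
            raise StatsError("Mann-Whitney comparison requires exactly two groups")
        a = values[groups == uniq[0]].astype(float)
        b = values[groups == uniq[1]].astype(float)
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return "mann-whitney", float(res.statistic), float(res.pvalue)

    if variable_kind == "categorical":
        table = pd.crosstab(groups, values).to_numpy()
        if (table < 10).all() and table.shape == (2, 2):
            res = sps.fisher_exact(table)
            return "fisher", float(res.statistic), float(res.pvalue)
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return "chi-square", float(chi2), float(p)

    raise StatsError(f"unknown variable kind {variable_kind!r}")
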