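"""Cohort-level severity interpretation of automated ASPECTS outputs.

Builds per-region deduction-frequency tables stratified by clinical
severity (NIHSS bands: mild 0-7, moderate 8-16, severe 17-42) and
hemisphere, min-max-normalised frequency maps, per-region association
tests across severity classes, and ROC/Youden thresholds that separate
mild from moderate-severe disease using the ASPECTS score (low tail
positive) and the core volume (high tail positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import CODES, HEMISPHERES
from .phantoms import NIHSS_BANDS, SEVERITIES
from .scoring import AspectsResult
from .stats import RocResult, StatsError, delong_test, group_compare, roc_youden


class SeverityError(ValueError):
    pass


def severity_from_nihss(nihss: int) -> str:
    """Map an NIHSS score to its band: mild 0-7, moderate 8-16, severe 17-42."""
    if not (0 <= nihss <= 42):
        raise SeverityError(f"NIHSS must lie in [0, 42], got {nihss}")
    for sev, (lo, hi) in NIHSS_BANDS.items():
        if lo <= nihss <= hi:
            return sev
    raise SeverityError(f"unmapped NIHSS {nihss}")  # pragma: no cover


@dataclass
class DeductionFrequencyTable:
    """Deduction counts/frequencies per (code, hemisphere, severity).

    ``rows`` has columns code, hemisphere (left/right/both for the pooled
    view), severity, count, frequency; the denominator is always the
    severity-class size. Severity classes with zero subjects are absent,
    never NaN.
    """

    rows: pd.DataFrame
    class_sizes: dict[str, int]

    def frequency(self, code: str, hemisphere: str, severity: str) -> float:
        m = self.rows[(self.rows.code == code)
                      & (self.rows.hemisphere == hemisphere)
                      & (self.rows.severity == severity)]
        if m.empty:
            raise KeyError((code, hemisphere, severity))
        return float(m.frequency.iloc[0])


def deduction_frequency(
    results: list[tuple[AspectsResult, str]]
) -> DeductionFrequencyTable:
    """Tally deduction frequencies per region and severity class.

    ``results`` pairs each subject's :class:`AspectsResult` with its
    clinical severity class. Emits per-hemisphere rows plus a pooled
    ``hemisphere='both'`` view (a subject deducting a code in either
    hemisphere counts once in the pooled row).
    """
    if not results:
        raise SeverityError("empty cohort")
    class_sizes: dict[str, int] = {}
    for _, sev in results:
        if sev not in SEVERITIES:
            raise SeverityError(f"unknown severity {sev!r}")
        class_sizes[sev] = class_sizes.get(sev, 0) + 1

    records = []
    for sev, size in class_sizes.items():
        in_class = [r for r, s in results if s == sev]
        for code in CODES:
            for hemi in HEMISPHERES:
                count = sum(1 for r in in_class if (code, hemi) in r.deductions)
                records.append({"code": code, "hemisphere": hemi, "severity": sev,
                                "count": count, "frequency": count / size})
            pooled = sum(1 for r in in_class
                         if any((code, h) in r.deductions for h in HEMISPHERES))
            records.append({"code": code, "hemisphere": "both", "severity": sev,
                            "count": pooled, "frequency": pooled / size})
    return DeductionFrequencyTable(rows=pd.DataFrame(records),
                                   class_sizes=class_sizes)


def normalized_frequency_map(table: DeductionFrequencyTable,
                             hemisphere_view: str | None = None) -> pd.DataFrame:
    """Min-max scale frequencies to [0,1] within each severity class.

    Mirrors a 0-1 colour-bar rendering of per-region deduction frequency:
    within a class the smallest frequency maps to 0 and the largest to 1;
    a constant class maps to all zeros. Rank order within a class is
    preserved. ``hemisphere_view`` restricts to 'left'/'right'/'both'
    rows (default: per-hemisphere rows, excluding the pooled view).
    """
    rows = table.rows
    if hemisphere_view is None:
        rows = rows[rows.hemisphere != "both"]
    else:
        rows = rows[rows.hemisphere == hemisphere_view]
    out = []
    for sev, grp in rows.groupby("severity", sort=False):
        f = grp.frequency.to_numpy(dtype=float)
        lo, hi = f.min(), f.max()
        scaled = np.zeros_like(f) if hi == lo else (f - lo) / (hi - lo)
        g = grp.copy()
        g["normalized"] = scaled
        out.append(g)
    return pd.concat(out, ignore_index=True)


def region_association_tests(
    results: list[tuple[AspectsResult, str]]
) -> pd.DataFrame:
    """Per-(region, hemisphere) deduction-vs-severity association tests.

    Each subject contributes a binary deducted/not-deducted indicator; the
    indicator x severity-class contingency table is tested with the
    categorical small-count rule (Fisher when every cell < 10 on a 2x2,
    chi-square otherwise). Regions deducted in no subject (or all) are
    flagged non-testable. A Bonferroni-adjusted column is emitted for
    transparency; raw p-values remain the reported quantity.
    """
    if not results:
        raise SeverityError("empty cohort")
    severities = [s for _, s in results]
    present = [s for s in SEVERITIES if s in severities]
    if len(present) < 2:
        raise SeverityError("need at least two severity classes")

    records = []
    for code in CODES:
        for hemi in HEMISPHERES:
            deducted = np.array([(code, hemi) in r.deductions for r, _ in results],
                                dtype=int)
            if deducted.min() == deducted.max():
                records.append({"code": code, "hemisphere": hemi, "test": "non-testable",
                                "statistic": np.nan, "p": np.nan})
                continue
            test, stat, p = group_compare(deducted, np.asarray(severities),
                                          "categorical")
            records.append({"code": code, "hemisphere": hemi, "test": test,
                            "statistic": stat, "p": p})
    df = pd.DataFrame(records)
    n_tests = int(df.p.notna().sum())
    df["p_bonferroni"] = (df.p * n_tests).clip(upper=1.0)
    return df


def dichotomize(severity: str) -> int:
    """1 for the moderate-severe composite class, 0 for mild."""
    if severity not in SEVERITIES:
        raise SeverityError(f"unknown severity {severity!r}")
    return 0 if severity == "mild" else 1


def derive_thresholds(
    cohort: list[tuple[AspectsResult, str]],
    extra_score_sets: dict[str, np.ndarray] | None = None,
) -> dict:
    """ROC/Youden operating points for mild vs moderate-severe separation.

    Returns a dict with ``aspects`` and ``volume`` :class:`RocResult`s —
    ASPECTS scored with the low tail positive (score <= threshold flags
    moderate-severe), volume with the high tail positive — plus pairwise
    DeLong comparisons between any additional score vectors supplied in
    ``extra_score_sets`` (keyed by name, paired with the cohort order,
    low-tail markers should be negated by the caller).
    """
    labels = np.array([dichotomize(s) for _, s in cohort])
    if labels.min() == labels.max():
        raise StatsError("need both mild and moderate-severe subjects")
    aspects_scores = np.array([r.reported_score for r, _ in cohort], dtype=float)
    volumes = np.array([r.core_volume_mL for r, _ in cohort], dtype=float)

    out = {
        "aspects": roc_youden(aspects_scores, labels, direction="low"),
        "volume": roc_youden(volumes, labels, direction="high"),
        "delong": {},
    }
    # orient both built-in markers so higher = more severe for AUC pairing
    base = {"aspects": -aspects_scores, "volume": volumes}
    if extra_score_sets:
        base.update({k: np.asarray(v, dtype=float)
                     for k, v in extra_score_sets.items()})
    names = sorted(base)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            auc_a, auc_b, p = delong_test(base[a], base[b], labels)
            out["delong"][f"{a}_vs_{b}"] = {"auc_a": auc_a, "auc_b": auc_b, "p": p}
    return out
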