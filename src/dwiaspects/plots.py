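"""Optional figure outputs for cohort severity analyses (needs matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import CODES
from .severity import DeductionFrequencyTable, normalized_frequency_map
from .stats import RocResult


def _pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_deduction_histogram(table: DeductionFrequencyTable,
                             path: str | Path,
                             hemisphere: str = "both") -> Path:
    """Stacked per-region deduction-frequency bars, one colour per severity."""
    plt = _pyplot()
    rows = table.rows[table.rows.hemisphere == hemisphere]
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = np.zeros(len(CODES))
    for sev, colour in (("mild", "#7fc97f"), ("moderate", "#fdc086"),
                        ("severe", "#f0027f")):
        grp = rows[rows.severity == sev].set_index("code")
        if grp.empty:
            continue
        vals = np.array([grp.frequency.get(c, 0.0) for c in CODES])
        ax.bar(CODES, vals, bottom=bottom, label=f"{sev} (n={table.class_sizes.get(sev, 0)})",
               color=colour)
        bottom += vals
    ax.set_ylabel("deduction frequency")
    ax.set_title(f"ASPECTS deduction frequency ({hemisphere} hemisphere)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_normalized_map(table: DeductionFrequencyTable, path: str | Path) -> Path:
    """Severity x (region, hemisphere) heat map of min-max scaled frequencies."""
    plt = _pyplot()
    norm = normalized_frequency_map(table)
    norm["region"] = norm.code + "-" + norm.hemisphere.str[0].str.upper()
    pivot = norm.pivot_table(index="severity", columns="region",
                             values="normalized", sort=False)
    fig, ax = plt.subplots(figsize=(9, 2.5))
    im = ax.imshow(pivot.to_numpy(), cmap="inferno", vmin=0, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    fig.colorbar(im, label="normalised deduction frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_roc(results: dict[str, RocResult], scores: dict[str, np.ndarray],
             labels: np.ndarray, path: str | Path) -> Path:
    """Empirical ROC curves for the ASPECTS and volume markers."""
    from sklearn.metrics import roc_curve

    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, res in results.items():
        s = np.asarray(scores[name], dtype=float)
        if res.direction == "low":
            s = -s
        fpr, tpr, _ = roc_curve(labels, s)
        ax.plot(fpr, tpr, label=f"{name}: AUC {res.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
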