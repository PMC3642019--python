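"""Group summaries and pairwise comparisons of angiographic scores.

Each acquisition group (CT1 fundus .. CT4 iris) contributes 27 ROI scores;
groups are summarized as mean +/- sample SD and compared pairwise with
two-sample tests (Welch's t by default, Mann-Whitney U as an option).  No
multiple-testing correction is applied by default; Bonferroni is available.
Significance stars: * for p < 0.05, ** for p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparisonMatrix",
    "GROUP_ORDER",
    "summarize",
    "compare_pairwise",
    "plot_scores",
]

GROUP_ORDER = ("CT1", "CT2", "CT3", "CT4")


@dataclass
class GroupComparisonMatrix:
    """Symmetric matrix of pairwise p-values with star annotations."""

    groups: tuple[str, ...]
    p_values: np.ndarray
    test_name: str
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.asarray(self.p_values, dtype=float)
        if p.shape != (len(self.groups), len(self.groups)):
            raise ValueError("p-value matrix shape must match the group list")
        if not np.allclose(p, p.T):
            raise ValueError("p-value matrix must be symmetric")
        if not np.allclose(np.diag(p), 1.0):
            raise ValueError("diagonal p-values must be exactly 1")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        self.p_values = p

    def stars(self) -> np.ndarray:
        """'', '*' or '**' per cell (diagonal blank)."""
        out = np.full(self.p_values.shape, "", dtype=object)
        a1, a2 = self.alpha_levels
        for i in range(len(self.groups)):
            for j in range(len(self.groups)):
                if i == j:
                    continue
                p = self.p_values[i, j]
                out[i, j] = "**" if p < a2 else ("*" if p < a1 else "")
        return out

    def to_frame(self) -> pd.DataFrame:
        """Table of p-values annotated with stars, in group order."""
        stars = self.stars()
        cells = [
            [
                "1" if i == j else f"{self.p_values[i, j]:.2f}{stars[i, j]}"
                for j in range(len(self.groups))
            ]
            for i in range(len(self.groups))
        ]
        return pd.DataFrame(cells, index=self.groups, columns=self.groups)


def summarize(groups: dict[str, np.ndarray],
              order: tuple[str, ...] = GROUP_ORDER) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and n, in CT1..CT4 order.

    ``order`` entries must all be present; a missing group is reported by
    name.
    """
    rows = []
    for g in order:
        if g not in groups:
            raise KeyError(f"missing group {g!r}")
        scores = np.asarray(groups[g], dtype=float)
        if len(scores) < 2:
            raise ValueError(f"group {g!r} needs at least 2 scores")
        rows.append({"group": g, "mean": scores.mean(),
                     "sd": scores.std(ddof=1), "n": len(scores)})
    return pd.DataFrame(rows).set_index("group")


def compare_pairwise(groups: dict[str, np.ndarray],
                     test: str = "welch_t",
                     alpha_levels: tuple[float, float] = (0.05, 0.01),
                     bonferroni: bool = False,
                     order: tuple[str, ...] = GROUP_ORDER) -> GroupComparisonMatrix:
    """All pairwise two-sample comparisons between the score groups.

    ``test`` is ``'welch_t'`` (unequal-variance t) or ``'mann_whitney'``
    (two-sided, normal approximation with tie correction).  Identical
    constant groups make Welch's t undefined; their p is reported as 1 and
    noted in the log.  ``bonferroni`` multiplies p-values by the number of
    pairs (capped at 1).
    """
    if test not in ("welch_t", "mann_whitney"):
        raise ValueError("test must be 'welch_t' or 'mann_whitney'")
    for g in order:
        if g not in groups:
            raise KeyError(f"missing group {g!r}")
        if len(np.asarray(groups[g])) < 2:
            raise ValueError(f"group {g!r} needs at least 2 scores")
    k = len(order)
    p = np.eye(k)  # off-diagonal filled below; diagonal stays 1
    log: list[str] = []
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            a = np.asarray(groups[order[i]], dtype=float)
            b = np.asarray(groups[order[j]], dtype=float)
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                log.append(f"{order[i]} vs {order[j]}: identical constant groups; p set to 1")
                pij = 1.0
            else:
                if test == "welch_t":
                    res = sps.ttest_ind(a, b, equal_var=False)
                else:
                    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                                           method="asymptotic")
                pij = float(res.pvalue)
                if np.isnan(pij):
                    log.append(f"{order[i]} vs {order[j]}: degenerate {test}; p set to 1")
                    pij = 1.0
            if bonferroni:
                pij = min(1.0, pij * n_pairs)
            p[i, j] = p[j, i] = pij
    return GroupComparisonMatrix(tuple(order), p, test, alpha_levels, log)


def plot_scores(summary: pd.DataFrame, path: str | None = None):
    """Bar chart of group means with SD error bars (density-profile figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.bar(summary.index, summary["mean"], yerr=summary["sd"], capsize=4,
           color="#7a9cc6", edgecolor="black")
    ax.set_ylabel("angiographic score")
    ax.set_xlabel("acquisition group")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
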