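"""Group comparisons used to quantify pharmacology and cell-type effects.

Thin wrappers over the standard procedures: exact two-sided Wilcoxon
signed-rank for paired samples, Welch's t for two unpaired groups, and
one-way ANOVA with Tukey's HSD post hoc for three or more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "anova_tukey"]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    significant: bool
    posthoc: Optional[object] = None   # statsmodels Tukey results when ANOVA

    def summary(self) -> str:
        lines = [f"{self.test}: statistic = {self.statistic:.4g}, "
                 f"p = {self.pvalue:.4g} (n = {self.n})"]
        if self.posthoc is not None:
            lines.append(str(self.posthoc))
        return "\n".join(lines)


def compare_groups(samples_a: Sequence[float], samples_b: Sequence[float],
                   paired: bool = False) -> ComparisonResult:
    """Two-group comparison, two-sided, α = 0.05.

    Paired samples use the exact Wilcoxon signed-rank test (identical pairs
    are degenerate and return p = 1); unpaired samples use Welch's t test.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length samples")
        diffs = a - b
        if np.all(diffs == 0):
            return ComparisonResult("wilcoxon-signed-rank", 0.0, 1.0,
                                    (a.size, b.size), False)
        stat, p = sps.wilcoxon(a, b, alternative="two-sided", method="exact",
                               zero_method="wilcox")
        name = "wilcoxon-signed-rank"
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        name = "welch-t"
    return ComparisonResult(name, float(stat), float(p), (a.size, b.size),
                            bool(p < ALPHA))


def anova_tukey(groups: dict[str, Sequence[float]]) -> ComparisonResult:
    """One-way ANOVA across named groups with Tukey HSD post hoc."""
    if len(groups) < 3:
        raise ValueError("ANOVA path expects at least 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 3 for a in arrays.values()):
        raise ValueError("each group needs at least 3 observations")
    f, p = sps.f_oneway(*arrays.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * a.size for k, a in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    return ComparisonResult("anova-oneway", float(f), float(p),
                            tuple(a.size for a in arrays.values()),
                            bool(p < ALPHA), posthoc=tukey)
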