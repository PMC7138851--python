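"""Shared group-comparison statistics: one-way ANOVA with Holm-Sidak post hoc.

Used by the pKa assay (comparison of fitted midpoints between variants) and
the roGFP2 dose-response analysis (comparison of AUCs against a reference
construct).  Significance labels follow the common star convention:
P > 0.05 ns; P <= 0.05 *; P <= 0.01 **; P <= 0.001 ***.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "compare_groups", "significance_label"]


def significance_label(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    f_statistic: float
    anova_p: float
    reference: str
    raw_p: dict[str, float]
    adjusted_p: dict[str, float]
    labels: dict[str, str]

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F = {self.f_statistic:.4g}, P = {self.anova_p:.3g}",
            f"Holm-Sidak pairwise vs reference '{self.reference}':",
        ]
        for name in self.raw_p:
            lines.append(
                f"  {name}: raw P = {self.raw_p[name]:.3g}, "
                f"adj P = {self.adjusted_p[name]:.3g} [{self.labels[name]}]"
            )
        return "\n".join(lines)


def compare_groups(groups: dict[str, np.ndarray],
                   reference: str | None = None) -> GroupComparison:
    """One-way ANOVA plus Holm-Sidak-adjusted pairwise tests vs a reference.

    ``groups`` maps a label to the replicate values of that group; every
    group needs at least 2 replicates.  Pairwise comparisons use two-sample
    t tests against ``reference`` (defaults to the first group), adjusted
    with the Holm-Sidak step-down procedure.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    if reference is None:
        reference = next(iter(arrays))
    if reference not in arrays:
        raise ValueError(f"unknown reference group {reference!r}")

    f_stat, anova_p = sps.f_oneway(*arrays.values())

    others = [k for k in arrays if k != reference]
    raw = {}
    for name in others:
        _, p = sps.ttest_ind(arrays[name], arrays[reference])
        raw[name] = float(p)
    if others:
        _, adj, _, _ = multipletests(list(raw.values()), method="holm-sidak")
        adjusted = dict(zip(raw, (float(a) for a in adj)))
    else:
        adjusted = {}
    labels = {k: significance_label(v) for k, v in adjusted.items()}
    return GroupComparison(
        f_statistic=float(f_stat), anova_p=float(anova_p), reference=reference,
        raw_p=raw, adjusted_p=adjusted, labels=labels,
    )
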