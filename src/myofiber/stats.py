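"""Group summaries, pairwise comparisons and densitometry ratios.

Group values are reported as mean ± SEM. Pairwise comparisons use the
two-sample Student's t-test (pooled variance by default, Welch optional)
with a Bonferroni adjustment of the significance threshold when several
group pairs are compared: with three surgery groups and hence three pairs,
significance requires p < 0.05/3 ≈ 0.0167.

Densitometry operations start from extracted band/spot intensities (image
quantification is out of scope): phosphoform percentages normalize each
signal to the summed phosphoform signal, and relative phosphorylation
divides a phospho-specific signal by the matching total-protein signal and
rescales so the reference group averages 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "DensitometryRecord",
    "summarize",
    "compare_groups",
    "phosphoform_percentages",
    "relative_phosphorylation",
]

BASE_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    def __str__(self) -> str:
        return f"{self.label}: {self.mean:.3g} ± {self.sem:.2g} (n = {self.n})"


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, str]
    p_value: float
    adjusted_alpha: float
    significant: bool
    t_statistic: float = float("nan")


@dataclass
class DensitometryRecord:
    sample_id: str
    group: str
    signals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.signals.items():
            if value < 0:
                raise ValueError(f"signal {name!r} is negative")


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean ± SEM of a group of measurements (SEM = sample SD / sqrt(n);
    zero for a single measurement)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return GroupSummary(label=label, mean=float(arr.mean()), sem=sem, n=int(arr.size))


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    m_comparisons: int = 1,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
    base_alpha: float = BASE_ALPHA,
) -> ComparisonResult:
    """Two-sample t-test with a Bonferroni-adjusted significance threshold.

    ``m_comparisons`` is the number of pairwise comparisons in the family;
    the comparison is significant iff p < base_alpha / m_comparisons. The
    pooled-variance Student's test is the default; pass ``welch=True`` for
    unequal variances.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    t, p = sps.ttest_ind(xa, xb, equal_var=not welch)
    if not np.isfinite(p):  # both groups constant
        p = 1.0 if xa.mean() == xb.mean() else 0.0
        t = 0.0 if p == 1.0 else float("inf")
    alpha = base_alpha / m_comparisons
    return ComparisonResult(
        groups=labels,
        p_value=float(p),
        adjusted_alpha=alpha,
        significant=bool(p < alpha),
        t_statistic=float(t),
    )


def phosphoform_percentages(rec: DensitometryRecord) -> dict[str, float]:
    """Express each phosphoform signal as a percentage of the summed
    phosphoform signal; the percentages sum to 100."""
    total = float(sum(rec.signals.values()))
    if total <= 0:
        raise ValueError(f"sample {rec.sample_id!r}: all signals are zero")
    return {name: 100.0 * value / total for name, value in rec.signals.items()}


def relative_phosphorylation(
    records: Sequence[DensitometryRecord],
    reference_group: str,
    phospho_key: str = "phospho",
    total_key: str = "total",
) -> dict[str, float]:
    """Per-sample phospho/total ratio scaled so the reference group's mean
    is 100%.

    The ratio is invariant to any global rescaling of the raw intensities,
    so results from different gels or scanner settings are comparable once
    each sample carries its own total-protein signal.
    """
    ratios: dict[str, float] = {}
    ref: list[float] = []
    for rec in records:
        try:
            phospho = rec.signals[phospho_key]
            total = rec.signals[total_key]
        except KeyError as exc:
            raise ValueError(f"sample {rec.sample_id!r} lacks signal {exc}") from exc
        if total <= 0:
            raise ValueError(f"sample {rec.sample_id!r}: total signal is zero")
        ratios[rec.sample_id] = phospho / total
        if rec.group == reference_group:
            ref.append(phospho / total)
    if not ref:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    ref_mean = float(np.mean(ref))
    if ref_mean <= 0:
        raise ValueError("reference group mean ratio is zero")
    return {sid: 100.0 * r / ref_mean for sid, r in ratios.items()}


def pairwise_comparisons(
    groups: Mapping[str, Sequence[float]],
    m_comparisons: int | None = None,
    welch: bool = False,
    base_alpha: float = BASE_ALPHA,
) -> list[ComparisonResult]:
    """All pairwise group comparisons; m defaults to the number of pairs."""
    labels = list(groups)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    m = m_comparisons if m_comparisons is not None else max(len(pairs), 1)
    return [
        compare_groups(groups[a], groups[b], m, labels=(a, b), welch=welch,
                       base_alpha=base_alpha)
        for a, b in pairs
    ]
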