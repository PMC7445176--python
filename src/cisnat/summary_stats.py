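"""Descriptive comparisons between transcript categories and tally tables.

Length, GC-content and expression-level distributions of NATs, lincRNAs
and mRNAs are summarised by medians and compared with Welch's
unequal-variance t-test plus the Mann-Whitney U test (both two-sided,
both reported).  A literally paired test between populations of unequal,
unmatched sizes is undefined, so the two unpaired tests assess the same
scientific claim — that the distributions differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import Concordance, NATPair, ResponsePattern
from .io_formats import ValidationError
from .nat_classify import CandidateLabel, NATCall, OverlapClass

__all__ = ["CategorySummary", "median", "compare_groups", "category_counts", "summarize_categories"]


@dataclass(frozen=True)
class CategorySummary:
    category: str  # NAT, LINCRNA or MRNA
    n: int
    median_length_nt: float
    median_gc_pct: float
    median_fpkm: float


def median(values: Sequence[float]) -> float:
    """Standard median (mean of the two central order statistics for
    even n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("median of an empty series")
    return float(np.median(arr))


def compare_groups(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Welch's t-test and Mann-Whitney U between two value series.

    Returns ``{"t_statistic", "t_p", "u_statistic", "u_p"}``, all
    two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values")
    t = stats.ttest_ind(a, b, equal_var=False)
    u = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "t_statistic": float(t.statistic),
        "t_p": float(t.pvalue),
        "u_statistic": float(u.statistic),
        "u_p": float(u.pvalue),
    }


def summarize_categories(
    features: pd.DataFrame,
) -> list[CategorySummary]:
    """Per-category medians from a feature frame with columns
    ``category`` (NAT/LINCRNA/MRNA), ``length_nt``, ``gc_pct``,
    ``fpkm_max`` (missing values are skipped)."""
    out = []
    for cat, grp in features.groupby("category", sort=True):
        out.append(
            CategorySummary(
                category=str(cat),
                n=len(grp),
                median_length_nt=median(grp["length_nt"].dropna()),
                median_gc_pct=median(grp["gc_pct"].dropna()),
                median_fpkm=median(grp["fpkm_max"].dropna()),
            )
        )
    return out


def category_counts(
    labels: Mapping[str, CandidateLabel],
    nat_calls: Sequence[NATCall] = (),
    responses: Optional[Mapping[str, ResponsePattern]] = None,
    pairs: Sequence[NATPair] = (),
) -> dict[str, dict]:
    """All bookkeeping tallies in one place.

    Returns a dict with:

    * ``labels``: count per CandidateLabel (a partition of the candidates)
    * ``overlap_classes``: NAT count per overlap class (sums to the NAT total)
    * ``responsive``: count per ResponsePattern among classified transcripts
    * ``pairs``: pair count per (concordance, overlap class) plus marginals
    """
    label_counts = {lab.value: 0 for lab in CandidateLabel}
    for lab in labels.values():
        label_counts[CandidateLabel(lab).value] += 1

    class_counts = {cls.value: 0 for cls in OverlapClass}
    for call in nat_calls:
        class_counts[call.overlap_class.value] += 1

    response_counts = {pat.value: 0 for pat in ResponsePattern}
    if responses:
        for pat in responses.values():
            response_counts[ResponsePattern(pat).value] += 1

    pair_counts: dict[str, int] = {
        f"{conc.value}_{cls.value}": 0
        for conc in Concordance
        for cls in OverlapClass
    }
    for p in pairs:
        pair_counts[f"{p.concordance.value}_{p.overlap_class.value}"] += 1
    pair_counts["CONCORDANT"] = sum(
        1 for p in pairs if p.concordance == Concordance.CONCORDANT
    )
    pair_counts["DISCORDANT"] = sum(
        1 for p in pairs if p.concordance == Concordance.DISCORDANT
    )
    pair_counts["TOTAL"] = len(pairs)

    return {
        "labels": label_counts,
        "overlap_classes": class_counts,
        "responsive": response_counts,
        "pairs": pair_counts,
    }
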