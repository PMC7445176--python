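"""Expression quantification, differential expression and pair detection.

FPKM (fragments per kilobase of exon per million mapped fragments) is
computed from pooled fragment counts.  Differential expression between
two conditions combines a fold-change gate (>= de_fold up, <= 1/de_fold
down) with a two-sided Fisher's exact test on the 2x2 table of fragment
counts against the library remainders; both gates must pass.  No
multiple-testing correction is applied by default (an optional
Benjamini-Hochberg helper is provided for users who want one).

Phosphate (Pi) responsiveness is a pattern over five physiological
states C4, P4, P8, R4, C8: up-regulation under depletion (P4 vs C4 or P8
vs C8) followed by a return toward control on resupply (R4 down vs P4,
or R4 unchanged vs C4) defines an up-Pi-responsive transcript, and the
mirrored pattern a down-Pi-responsive one.  A transcript whose depletion
arm fires without the resupply criterion is "depletion only".

NAT-mRNA pairs are Pi-responsive NATs whose five-condition FPKM profile
correlates with the cognate mRNA's at r^2 >= 0.6; a positive correlation
makes the pair concordant, a negative one discordant.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CONDITIONS, ExpressionTable, ValidationError
from .nat_classify import NATCall, OverlapClass, Thresholds
from .transcript_model import UndefinedValueError

__all__ = [
    "DEStatus",
    "ResponsePattern",
    "ConditionProfile",
    "DECall",
    "NATPair",
    "Concordance",
    "fpkm",
    "select_robust_replicates",
    "pool_replicates",
    "fisher_de",
    "fold_change",
    "call_de",
    "classify_pi_response",
    "pearson_r",
    "detect_nat_pairs",
    "bh_adjust",
]

logger = logging.getLogger(__name__)


class DEStatus(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNCHANGED = "UNCHANGED"


class ResponsePattern(str, enum.Enum):
    UP_PI_RESPONSIVE = "UP_PI_RESPONSIVE"
    DOWN_PI_RESPONSIVE = "DOWN_PI_RESPONSIVE"
    UP_DEPLETION_ONLY = "UP_DEPLETION_ONLY"
    DOWN_DEPLETION_ONLY = "DOWN_DEPLETION_ONLY"
    NONE = "NONE"


class Concordance(str, enum.Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"


@dataclass(frozen=True)
class ConditionProfile:
    """Per-transcript pooled expression across the five states.

    ``fpkm`` maps each condition to its pooled FPKM; ``counts``
    optionally maps each condition to ``(fragment_count, library_total)``
    so the exact test can run.
    """

    transcript_id: str
    fpkm: Mapping[str, float]
    counts: Optional[Mapping[str, tuple[int, int]]] = None
    exonic_length: Optional[int] = None

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.fpkm]
        if missing:
            raise ValidationError(
                f"{self.transcript_id}: missing conditions {missing}"
            )
        if any(v < 0 for v in self.fpkm.values()):
            raise ValidationError(f"{self.transcript_id}: negative FPKM")

    def series(self) -> np.ndarray:
        return np.array([self.fpkm[c] for c in CONDITIONS], dtype=float)


@dataclass(frozen=True)
class DECall:
    contrast: tuple[str, str]  # (reference, alternative)
    fold_change: float
    p_value: float  # NaN when the p gate is disabled (FPKM-only mode)
    status: DEStatus


@dataclass(frozen=True)
class NATPair:
    nat_id: str
    gene_id: str
    overlap_class: OverlapClass
    r: float
    r2: float
    concordance: Concordance


def fpkm(count: float, library_total: int, exonic_length: int) -> float:
    """count x 10^9 / (library_total x exonic_length)."""
    if library_total <= 0:
        raise ValidationError("library_total must be positive")
    if exonic_length <= 0:
        raise ValidationError("exonic_length must be positive")
    if count < 0:
        raise ValidationError("count must be non-negative")
    return count * 1e9 / (library_total * exonic_length)


def select_robust_replicates(
    replicates: pd.DataFrame,
    kind: str = "counts",
    warn_below: float = 0.9,
) -> tuple[tuple[str, str], pd.Series, float]:
    """Pick the two most correlated replicate columns and pool them.

    Returns ``((rep_a, rep_b), pooled, r)`` where ``pooled`` is the
    per-transcript sum for counts and the mean for FPKM.  Replicate
    correlations below ``warn_below`` are reported with a warning, since
    pooling weakly correlated libraries muddies every downstream call.
    """
    cols = list(replicates.columns)
    if len(cols) < 2:
        raise ValidationError("need at least 2 replicates to pool")
    best: tuple[float, tuple[str, str]] | None = None
    for a, b in combinations(cols, 2):
        x, y = replicates[a].to_numpy(float), replicates[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        key = -1.0 if np.isnan(r) else r
        if best is None or key > best[0]:
            best = (key, (a, b))
    r_best, (a, b) = best
    if r_best < warn_below:
        warnings.warn(
            f"best replicate pair ({a}, {b}) correlates at r={r_best:.3f} "
            f"< {warn_below}",
            stacklevel=2,
        )
    if kind == "counts":
        pooled = replicates[a] + replicates[b]
    else:
        pooled = (replicates[a] + replicates[b]) / 2.0
    return (a, b), pooled, r_best


def pool_replicates(
    expr: ExpressionTable,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, tuple[str, str]]]:
    """Pool each condition's two most robust replicates.

    Returns ``(pooled_values, pooled_totals, chosen_pairs)`` with one
    column per condition.  For counts tables the pooled library total is
    the sum of the two chosen replicates' totals; FPKM tables carry no
    totals (empty dict).
    """
    pooled = {}
    totals: dict[str, int] = {}
    chosen: dict[str, tuple[str, str]] = {}
    for cond in expr.conditions:
        cols = expr.samples_for(cond)
        if len(cols) == 1:
            pooled[cond] = expr.values[cols[0]]
            if expr.kind == "counts":
                totals[cond] = int(expr.library_totals[cols[0]])
            chosen[cond] = (cols[0], cols[0])
            continue
        (a, b), col, _r = select_robust_replicates(expr.values[cols], kind=expr.kind)
        pooled[cond] = col
        chosen[cond] = (a, b)
        if expr.kind == "counts":
            totals[cond] = int(expr.library_totals[a]) + int(expr.library_totals[b])
    return pd.DataFrame(pooled), totals, chosen


def fisher_de(c1: int, n1: int, c2: int, n2: int) -> float:
    """Two-sided Fisher's exact test p-value for the 2x2 table
    [[c1, n1-c1], [c2, n2-c2]].

    The two-sided rule sums the probabilities of all tables with the
    observed margins whose point probability does not exceed that of the
    observed table (the same convention as ``scipy.stats.fisher_exact``).
    """
    if not (0 <= c1 <= n1 and 0 <= c2 <= n2):
        raise ValidationError("require 0 <= c_i <= n_i")
    M, K = n1 + n2, c1 + c2
    lo, hi = max(0, K - n2), min(K, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, M, K, n1)
    p_obs = pmf[c1 - lo]
    # tolerance guards against ties broken by floating-point noise
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def fold_change(fpkm_ref: float, fpkm_alt: float, pseudocount: float = 0.1) -> float:
    """(alt + pc) / (ref + pc), with the pseudocount applied only when
    either term falls below it; well-measured ratios are left exact."""
    if fpkm_ref < 0 or fpkm_alt < 0:
        raise ValidationError("FPKM values must be non-negative")
    if min(fpkm_ref, fpkm_alt) < pseudocount:
        return (fpkm_alt + pseudocount) / (fpkm_ref + pseudocount)
    if fpkm_ref == 0:  # only reachable with pseudocount == 0
        raise UndefinedValueError("fold change undefined: zero reference FPKM")
    return fpkm_alt / fpkm_ref


def call_de(
    fpkm_ref: float,
    fpkm_alt: float,
    th: Thresholds = Thresholds(),
    counts: Optional[tuple[int, int, int, int]] = None,
    contrast: tuple[str, str] = ("ref", "alt"),
) -> DECall:
    """Differential-expression call for one contrast.

    ``counts`` is ``(c_ref, total_ref, c_alt, total_alt)``; when absent
    the p gate is disabled and the call falls back to fold change only
    (p_value = NaN), with a warning — this degrades the published
    two-gate criterion.
    """
    fc = fold_change(fpkm_ref, fpkm_alt, th.fc_pseudocount)
    if counts is not None:
        c1, n1, c2, n2 = counts
        p = fisher_de(c1, n1, c2, n2)
        p_pass = p < th.de_p
    else:
        warnings.warn(
            "no fragment counts available: p-value gate disabled, "
            "DE calls use fold change only",
            stacklevel=2,
        )
        p = float("nan")
        p_pass = True
    if fc >= th.de_fold and p_pass:
        status = DEStatus.UP
    elif fc <= 1.0 / th.de_fold and p_pass:
        status = DEStatus.DOWN
    else:
        status = DEStatus.UNCHANGED
    return DECall(contrast=contrast, fold_change=fc, p_value=p, status=status)


def _contrast(profile: ConditionProfile, ref: str, alt: str, th: Thresholds) -> DECall:
    counts = None
    if profile.counts is not None:
        c1, n1 = profile.counts[ref]
        c2, n2 = profile.counts[alt]
        counts = (c1, n1, c2, n2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fold-only warning handled once upstream
        return call_de(
            profile.fpkm[ref], profile.fpkm[alt], th, counts=counts, contrast=(ref, alt)
        )


def classify_pi_response(
    profile: ConditionProfile, th: Thresholds = Thresholds()
) -> ResponsePattern:
    """Phosphate-responsiveness pattern over the five states.

    Up arm: UP in P4 vs C4 or in P8 vs C8.  Resupply criterion: DOWN in
    R4 vs P4 (expression falls back from the depleted level) or UNCHANGED
    in R4 vs C4 (returned to control).  Both readings of "return to
    control levels" are accepted via OR.  The down-responsive pattern is
    the exact mirror.  When both arms fire (one contrast up, the other
    down — a pathological profile), the up arm takes precedence.
    """
    p4 = _contrast(profile, "C4", "P4", th)
    p8 = _contrast(profile, "C8", "P8", th)
    r4_vs_p4 = _contrast(profile, "P4", "R4", th)
    r4_vs_c4 = _contrast(profile, "C4", "R4", th)

    up_arm = DEStatus.UP in (p4.status, p8.status)
    down_arm = DEStatus.DOWN in (p4.status, p8.status)
    if up_arm:
        if r4_vs_p4.status == DEStatus.DOWN or r4_vs_c4.status == DEStatus.UNCHANGED:
            return ResponsePattern.UP_PI_RESPONSIVE
        return ResponsePattern.UP_DEPLETION_ONLY
    if down_arm:
        if r4_vs_p4.status == DEStatus.UP or r4_vs_c4.status == DEStatus.UNCHANGED:
            return ResponsePattern.DOWN_PI_RESPONSIVE
        return ResponsePattern.DOWN_DEPLETION_ONLY
    return ResponsePattern.NONE


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises for constant series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def detect_nat_pairs(
    nat_calls: Sequence[NATCall],
    profiles: Mapping[str, ConditionProfile],
    responses: Mapping[str, ResponsePattern],
    th: Thresholds = Thresholds(),
    log_fpkm: bool = False,
) -> list[NATPair]:
    """Correlated sense-antisense pairs among Pi-responsive NATs.

    For every NAT whose response pattern is not NONE, the Pearson
    correlation between its five pooled condition FPKMs and its cognate
    mRNA's is computed (optionally on log2(FPKM+1)); pairs with
    r^2 >= pair_r2 are kept and labelled concordant (r > 0) or
    discordant (r < 0).  Pairs with a constant profile on either side are
    skipped and logged.
    """
    pairs: list[NATPair] = []
    for call in nat_calls:
        pattern = responses.get(call.nat_id, ResponsePattern.NONE)
        if pattern == ResponsePattern.NONE:
            continue
        nat_profile = profiles.get(call.nat_id)
        gene_profile = profiles.get(call.cognate_gene_id)
        if nat_profile is None or gene_profile is None:
            raise ValidationError(
                f"pair {call.nat_id}/{call.cognate_gene_id}: missing profile"
            )
        x, y = nat_profile.series(), gene_profile.series()
        if log_fpkm:
            x, y = np.log2(x + 1.0), np.log2(y + 1.0)
        try:
            r = pearson_r(x, y)
        except UndefinedValueError:
            logger.info(
                "pair %s/%s skipped: constant expression profile",
                call.nat_id,
                call.cognate_gene_id,
            )
            continue
        r2 = r * r
        if r2 < th.pair_r2:
            continue
        assert r != 0.0, "r == 0 cannot satisfy a positive r^2 threshold"
        pairs.append(
            NATPair(
                nat_id=call.nat_id,
                gene_id=call.cognate_gene_id,
                overlap_class=call.overlap_class,
                r=r,
                r2=r2,
                concordance=Concordance.CONCORDANT if r > 0 else Concordance.DISCORDANT,
            )
        )
    return pairs


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in
    the pipeline, matching the published two-gate criterion)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
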