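"""Three-way SWL outcome classification and CIRF re-classification.

After shockwave lithotripsy (SWL), follow-up CT places each case in one
of three categories:

* ``completely_stone_free`` — no fragments remain;
* ``stone_free_with_cirfs`` — fragments remain, but every fragment's
  major axis is at or below the clinically-insignificant-residual-
  fragment (CIRF) threshold (4 mm by convention, inclusive);
* ``not_stone_free`` — at least one fragment exceeds the threshold.

Because the CIRF rule is axis-based while residual burden is better
captured by total fragment volume, the two scales can disagree: a case
called "stone-free with CIRFs" may carry more residual volume than the
smallest fragment in the "not stone-free" group, and a "not stone-free"
fragment may have a sub-threshold axis on re-measurement.
:func:`volume_reclassification_report` quantifies both directions of
this disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from stonevol.errors import DomainError, UndefinedStatisticError
from stonevol.morphometry import StoneMetrics, total_burden

DEFAULT_CIRF_THRESHOLD_MM = 4.0


class OutcomeCategory(str, Enum):
    COMPLETELY_STONE_FREE = "completely_stone_free"
    STONE_FREE_WITH_CIRFS = "stone_free_with_cirfs"
    NOT_STONE_FREE = "not_stone_free"


@dataclass(frozen=True)
class CaseRecord:
    """One treated case: pre-treatment burden, residual fragments, outcome."""

    case_id: str
    post_fragments: tuple[StoneMetrics, ...] = ()
    pre_metrics: tuple[StoneMetrics, ...] = ()
    cirf_threshold_mm: float = DEFAULT_CIRF_THRESHOLD_MM
    n_sessions: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "post_fragments", tuple(self.post_fragments))
        object.__setattr__(self, "pre_metrics", tuple(self.pre_metrics))

    @property
    def outcome(self) -> OutcomeCategory:
        return classify_outcome(self.post_fragments, self.cirf_threshold_mm)

    @property
    def total_residual_volume_mm3(self) -> float:
        return total_burden(self.post_fragments)[0]

    @property
    def max_fragment_axis_mm(self) -> float:
        return total_burden(self.post_fragments)[2]


def classify_outcome(
    fragments: Sequence[StoneMetrics],
    cirf_threshold_mm: float = DEFAULT_CIRF_THRESHOLD_MM,
) -> OutcomeCategory:
    """Classify a fragment list into the three-way SWL outcome.

    The fragment-size measure is the major horizontal axis; the CIRF
    comparison is inclusive (a fragment of exactly the threshold length
    still counts as clinically insignificant), applied per fragment.
    """
    if cirf_threshold_mm <= 0:
        raise DomainError("CIRF threshold must be positive")
    if not fragments:
        return OutcomeCategory.COMPLETELY_STONE_FREE
    if all(f.major_horizontal_axis_mm <= cirf_threshold_mm for f in fragments):
        return OutcomeCategory.STONE_FREE_WITH_CIRFS
    return OutcomeCategory.NOT_STONE_FREE


@dataclass(frozen=True)
class ReclassificationReport:
    """Both directions of axis-vs-volume outcome disagreement.

    ``min_not_stone_free_volume_mm3`` — smallest total residual volume
    in the not-stone-free group.  ``cirf_cases_exceeding`` — CIRF cases
    whose total residual volume strictly exceeds that minimum (their
    axis-based label understates burden).  ``axis_requalified`` — cases
    labelled not-stone-free whose every fragment axis is at or below the
    threshold on re-measurement (they would qualify as CIRF cases).
    """

    min_not_stone_free_volume_mm3: float
    cirf_cases_exceeding: tuple[str, ...]
    axis_requalified: tuple[str, ...]
    cirf_threshold_mm: float

    @property
    def n_cirf_exceeding(self) -> int:
        return len(self.cirf_cases_exceeding)

    @property
    def n_axis_requalified(self) -> int:
        return len(self.axis_requalified)

    def as_dict(self) -> dict:
        return {
            "min_not_stone_free_volume_mm3": self.min_not_stone_free_volume_mm3,
            "cirf_cases_exceeding": list(self.cirf_cases_exceeding),
            "n_cirf_exceeding": self.n_cirf_exceeding,
            "axis_requalified": list(self.axis_requalified),
            "n_axis_requalified": self.n_axis_requalified,
            "cirf_threshold_mm": self.cirf_threshold_mm,
        }


def volume_reclassification_report(
    cirf_cases: Sequence[CaseRecord],
    non_free_cases: Sequence[CaseRecord],
    cirf_threshold_mm: float = DEFAULT_CIRF_THRESHOLD_MM,
) -> ReclassificationReport:
    """Compare axis-based outcome labels against volume-based burden.

    Exceedance is strict: a CIRF case is flagged only when its total
    residual volume is larger than the smallest not-stone-free volume.
    Multi-fragment cases use total residual volume for the volume
    comparison but the per-fragment maximum axis for the CIRF rule.
    """
    if not non_free_cases:
        raise UndefinedStatisticError(
            "minimum not-stone-free volume undefined for an empty group"
        )
    min_volume = min(c.total_residual_volume_mm3 for c in non_free_cases)
    exceeding = tuple(
        c.case_id for c in cirf_cases if c.total_residual_volume_mm3 > min_volume
    )
    requalified = tuple(
        c.case_id
        for c in non_free_cases
        if c.post_fragments
        and all(f.major_horizontal_axis_mm <= cirf_threshold_mm for f in c.post_fragments)
    )
    return ReclassificationReport(
        min_not_stone_free_volume_mm3=min_volume,
        cirf_cases_exceeding=exceeding,
        axis_requalified=requalified,
        cirf_threshold_mm=cirf_threshold_mm,
    )


def stone_free_indicator(
    cases: Sequence[CaseRecord], definition: str = "completely_stone_free"
) -> np.ndarray:
    """Binary stone-free outcome vector for regression.

    ``definition`` selects what counts as success (coded 1):
    ``"completely_stone_free"`` — no fragments at all (the default,
    the strictest headline definition) — or ``"stone_free_with_cirfs"``
    — no fragment above the CIRF threshold, i.e. CIRF cases count as
    successes too.
    """
    if definition == "completely_stone_free":
        success = {OutcomeCategory.COMPLETELY_STONE_FREE}
    elif definition == "stone_free_with_cirfs":
        success = {
            OutcomeCategory.COMPLETELY_STONE_FREE,
            OutcomeCategory.STONE_FREE_WITH_CIRFS,
        }
    else:
        raise DomainError(f"unknown stone-free definition: {definition!r}")
    return np.array([1 if c.outcome in success else 0 for c in cases], dtype=int)


def cohort_summary(cases: Sequence[CaseRecord]) -> dict:
    """Tally a treated cohort: outcome counts/percentages and sessions.

    Percentages are reported to one decimal; for an empty cohort the
    percentage fields are ``None``.  Burden summaries (median, IQR,
    range of total residual volume) are included per outcome group when
    fragments are present.
    """
    n = len(cases)
    outcome_counts = {cat.value: 0 for cat in OutcomeCategory}
    for c in cases:
        outcome_counts[c.outcome.value] += 1

    def pct(k: int) -> float | None:
        return round(100.0 * k / n, 1) if n else None

    session_counts: dict[int, int] = {}
    for c in cases:
        if c.n_sessions is not None:
            session_counts[c.n_sessions] = session_counts.get(c.n_sessions, 0) + 1
    n_sessions_known = sum(session_counts.values())
    single_session_pct = (
        round(100.0 * session_counts.get(1, 0) / n_sessions_known, 1)
        if n_sessions_known
        else None
    )

    burden: dict[str, dict] = {}
    for cat in OutcomeCategory:
        vols = [
            c.total_residual_volume_mm3
            for c in cases
            if c.outcome is cat and c.post_fragments
        ]
        if vols:
            arr = np.asarray(vols)
            burden[cat.value] = {
                "median_mm3": float(np.median(arr)),
                "iqr_mm3": [float(np.percentile(arr, 25)), float(np.percentile(arr, 75))],
                "range_mm3": [float(arr.min()), float(arr.max())],
            }

    return {
        "n_cases": n,
        "outcome_counts": outcome_counts,
        "outcome_pct": {k: pct(v) for k, v in outcome_counts.items()},
        "session_counts": dict(sorted(session_counts.items())),
        "single_session_pct": single_session_pct,
        "residual_burden": burden,
    }
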