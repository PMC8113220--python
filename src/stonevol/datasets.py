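"""Bundled example data: residual fragments from a 72-case SWL cohort.

The worked examples and the acceptance checks use measurements reported
for a clinical shockwave-lithotripsy cohort of 72 treated renal-stone
cases: the major horizontal axis length and software-measured volume of
the five smallest residual fragments in the "not stone-free" group and
of the five smallest in the "stone-free with CIRFs" group, together
with the cohort's outcome and session tallies.

These records are inputs to the classification and reclassification
operations, not expected outputs; every derived quantity (minimum
volumes, reclassification counts, rates) is computed from them at run
time.
"""

from __future__ import annotations

from stonevol.morphometry import StoneMetrics
from stonevol.outcomes import CaseRecord

#: (major horizontal axis mm, volume mm3) of the five smallest residual
#: fragments in the 'not stone-free' group.
NOT_STONE_FREE_FRAGMENTS: tuple[tuple[float, float], ...] = (
    (2.387, 8.34),
    (2.535, 10.61),
    (3.516, 10.78),
    (4.238, 16.18),
    (4.386, 19.11),
)

#: (major horizontal axis mm, volume mm3) of the five smallest residual
#: fragments in the 'stone-free with CIRFs' group.
CIRF_FRAGMENTS: tuple[tuple[float, float], ...] = (
    (1.642, 2.38),
    (2.304, 7.05),
    (3.516, 10.30),
    (3.672, 11.73),
    (3.854, 26.07),
)

#: Outcome tallies of the 72 treated cases.  'completely stone-free' is
#: a subset of 'stone-free with CIRFs or better'; the disjoint
#: three-way split is 32 / 5 / 35.
COHORT_OUTCOME_COUNTS = {
    "n_cases": 72,
    "completely_stone_free": 32,
    "stone_free_with_cirfs_only": 5,
    "not_stone_free": 35,
}

#: Number of SWL sessions per case: 60 single-session, 10 two-session,
#: one three-session and one four-or-more-session case.
COHORT_SESSION_COUNTS = {1: 60, 2: 10, 3: 1, 4: 1}


def example_fragment_cases() -> tuple[list[CaseRecord], list[CaseRecord]]:
    """The ten example residual-fragment cases as (CIRF, not-stone-free) lists.

    Each case carries a single residual fragment with the measured axis
    and volume above.
    """
    cirf = [
        CaseRecord(
            case_id=f"cirf-{i + 1}",
            post_fragments=(
                StoneMetrics(
                    stone_id=f"cirf-{i + 1}-frag",
                    major_horizontal_axis_mm=axis,
                    volume_mm3=vol,
                ),
            ),
        )
        for i, (axis, vol) in enumerate(CIRF_FRAGMENTS)
    ]
    not_free = [
        CaseRecord(
            case_id=f"nsf-{i + 1}",
            post_fragments=(
                StoneMetrics(
                    stone_id=f"nsf-{i + 1}-frag",
                    major_horizontal_axis_mm=axis,
                    volume_mm3=vol,
                ),
            ),
        )
        for i, (axis, vol) in enumerate(NOT_STONE_FREE_FRAGMENTS)
    ]
    return cirf, not_free


def example_cohort_cases(cirf_threshold_mm: float = 4.0) -> list[CaseRecord]:
    """72 case records reproducing the cohort's outcome and session tallies.

    Residual-fragment sizes are synthetic placeholders chosen only to
    realise each case's recorded category (no fragments; all fragments
    at or below the CIRF threshold; one fragment above it) — the
    categorical tallies are the data, the individual fragment sizes are
    not.
    """
    counts = COHORT_OUTCOME_COUNTS
    sessions: list[int] = []
    for k, n in sorted(COHORT_SESSION_COUNTS.items()):
        sessions.extend([k] * n)

    cases: list[CaseRecord] = []

    def frag(cid: str, axis: float) -> StoneMetrics:
        # nominal volume from a sphere of that diameter; only the axis
        # drives classification
        import math

        return StoneMetrics(
            stone_id=f"{cid}-frag",
            major_horizontal_axis_mm=axis,
            volume_mm3=math.pi / 6.0 * axis**3,
        )

    i = 0
    for _ in range(counts["completely_stone_free"]):
        cases.append(
            CaseRecord(case_id=f"case-{i:02d}", post_fragments=(), n_sessions=sessions[i])
        )
        i += 1
    for _ in range(counts["stone_free_with_cirfs_only"]):
        cid = f"case-{i:02d}"
        cases.append(
            CaseRecord(
                case_id=cid,
                post_fragments=(frag(cid, 0.75 * cirf_threshold_mm),),
                n_sessions=sessions[i],
            )
        )
        i += 1
    for _ in range(counts["not_stone_free"]):
        cid = f"case-{i:02d}"
        cases.append(
            CaseRecord(
                case_id=cid,
                post_fragments=(frag(cid, 1.5 * cirf_threshold_mm),),
                n_sessions=sessions[i],
            )
        )
        i += 1
    return cases
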