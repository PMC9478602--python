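"""RTOG acute skin-toxicity grading and cohort tabulation.

Grades are assigned from the presentation codes recorded at follow-up:

=====  =============================================  grade
code   presentation
=====  =============================================  =====
FE     faint erythema                                 1
DD     dry desquamation                               1
MER    moderate erythema                              2
MED    moderate edema                                 2
PMD    patchy moist desquamation                      2
CMD    confluent moist desquamation                   3
PE     pitting edema                                  3
NEC    necrosis / ulceration / bleeding               4
=====  =============================================  =====

A patient's grade is the maximum over their presentations (adding a code can
never lower the grade).  The distinguishing features are moist desquamation
and edema for grades 2-3 and necrosis/ulceration for grade 4.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ValidationError
from .util import round_half_up

__all__ = [
    "CODE_GRADE",
    "CODE_ORDER",
    "FRACTION_BINS_DURING",
    "FRACTION_BINS",
    "ToxicityRecord",
    "GradeSummary",
    "grade_from_presentation",
    "combo_label",
    "tabulate_by_fraction_bin",
    "tabulate_timepoints",
    "interruption_rate",
]

CODE_GRADE: dict[str, int] = {
    "FE": 1,
    "DD": 1,
    "MER": 2,
    "MED": 2,
    "PMD": 2,
    "CMD": 3,
    "PE": 3,
    "NEC": 4,
}

# canonical display order for combination labels, e.g. "PMD+MER+MED"
CODE_ORDER: tuple[str, ...] = ("FE", "DD", "PMD", "MER", "MED", "PE", "CMD", "NEC")

FRACTION_BINS_DURING: tuple[str, ...] = ("<=10", "11-15", "16-20", "21-25")
FRACTION_BINS: tuple[str, ...] = FRACTION_BINS_DURING + ("post-RT",)


@dataclass(frozen=True)
class ToxicityRecord:
    """One patient's worst acute-dermatitis finding in one follow-up period."""

    patient_id: str
    fraction_bin: str
    presentations: frozenset[str]
    interrupted: bool = False

    def __post_init__(self) -> None:
        if self.fraction_bin not in FRACTION_BINS:
            raise ValidationError(
                f"fraction_bin: {self.fraction_bin!r} not one of {FRACTION_BINS}"
            )
        if not self.presentations:
            raise ValidationError("presentations: must be non-empty for graded records")
        unknown = set(self.presentations) - set(CODE_GRADE)
        if unknown:
            raise ValidationError(f"presentations: unknown code(s) {sorted(unknown)}")

    @property
    def grade(self) -> int:
        return grade_from_presentation(self.presentations)


def grade_from_presentation(codes) -> int:
    """Worst applicable RTOG grade for a set of presentation codes."""
    codes = set(codes)
    if not codes:
        raise ValidationError("presentations: must be non-empty")
    unknown = codes - set(CODE_GRADE)
    if unknown:
        raise ValidationError(f"presentations: unknown code(s) {sorted(unknown)}")
    return max(CODE_GRADE[c] for c in codes)


def combo_label(codes) -> str:
    """Canonical '+'-joined label for a presentation combination."""
    return "+".join(c for c in CODE_ORDER if c in set(codes))


@dataclass
class GradeSummary:
    """Counts and percents of a toxicity tabulation.

    ``grade_percent`` is the cohort share of each grade (exact, unrounded;
    callers round to table precision).  ``combo_bins`` maps
    (grade, combo label) -> per-bin counts; ``combo_row_percent`` holds the
    within-row percents, denominated by that row's total.
    """

    total: int
    grade_counts: dict[int, int]
    grade_percent: dict[int, float]
    combo_bins: dict[tuple[int, str], dict[str, int]] = field(default_factory=dict)
    combo_totals: dict[tuple[int, str], int] = field(default_factory=dict)
    combo_row_percent: dict[tuple[int, str], dict[str, float]] = field(default_factory=dict)
    interrupted_count: int = 0
    interrupted_percent: float = 0.0


def tabulate_by_fraction_bin(records) -> GradeSummary:
    """During-radiotherapy tabulation: grade x onset-bin x presentation combo.

    Each patient must appear exactly once (their worst-grade record for the
    treatment period); duplicate patient ids raise an error.  Cohort
    percents are denominated by the total patient count, within-combo row
    percents by that row's total.
    """
    records = list(records)
    ids = [r.patient_id for r in records]
    dupes = [pid for pid, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValidationError(f"duplicate patient_id in during-RT set: {sorted(dupes)[:5]}")

    total = len(records)
    grade_counts: dict[int, int] = {g: 0 for g in (1, 2, 3, 4)}
    combo_bins: dict[tuple[int, str], dict[str, int]] = {}
    n_interrupted = 0
    for r in records:
        g = r.grade
        grade_counts[g] += 1
        key = (g, combo_label(r.presentations))
        row = combo_bins.setdefault(key, {b: 0 for b in FRACTION_BINS_DURING})
        row[r.fraction_bin] = row.get(r.fraction_bin, 0) + 1
        n_interrupted += bool(r.interrupted)

    combo_totals = {k: sum(v.values()) for k, v in combo_bins.items()}
    combo_row_percent = {
        k: {b: (100.0 * c / combo_totals[k] if combo_totals[k] else 0.0) for b, c in v.items()}
        for k, v in combo_bins.items()
    }
    grade_percent = {
        g: (100.0 * c / total if total else 0.0) for g, c in grade_counts.items()
    }
    return GradeSummary(
        total=total,
        grade_counts=grade_counts,
        grade_percent=grade_percent,
        combo_bins=combo_bins,
        combo_totals=combo_totals,
        combo_row_percent=combo_row_percent,
        interrupted_count=n_interrupted,
        interrupted_percent=100.0 * n_interrupted / total if total else 0.0,
    )


def _timepoint_summary(records) -> GradeSummary:
    records = list(records)
    total = len(records)
    grade_counts = {g: 0 for g in (1, 2, 3, 4)}
    for r in records:
        grade_counts[r.grade] += 1
    grade_percent = {
        g: (round_half_up(100.0 * c / total, 2) if total else 0.0)
        for g, c in grade_counts.items()
    }
    return GradeSummary(total=total, grade_counts=grade_counts, grade_percent=grade_percent)


def tabulate_timepoints(during, post_rt) -> tuple[GradeSummary, GradeSummary]:
    """Grade counts/percents during radiotherapy and 2-4 weeks after.

    Both record sets must cover the same patient roster.  Percents are
    rounded half-up to 2 decimals.
    """
    during = list(during)
    post_rt = list(post_rt)
    if {r.patient_id for r in during} != {r.patient_id for r in post_rt}:
        raise ValidationError("during and post-RT sets do not cover the same roster")
    return _timepoint_summary(during), _timepoint_summary(post_rt)


def interruption_rate(records) -> float:
    """Treatment-interruption rate in percent of the cohort, 1 decimal."""
    records = list(records)
    if not records:
        raise ValidationError("records: empty cohort")
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("records: each patient must appear exactly once")
    n_int = sum(bool(r.interrupted) for r in records)
    return round_half_up(100.0 * n_int / len(records), 1)
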