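"""Packaged reference tables and self-consistency checks.

The package ships CSV transcriptions of the published phantom plan
statistics, the 27-patient in-vivo skin-dose table, the acute-toxicity
tabulations and the cohort staging breakdown.  ``run_table_checks``
recomputes every derivable quantity in those tables with the library's own
formulas and compares against the printed values — the dosimetric
equivalent of a round-trip test against the clinical report.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import FixtureError
from .film import SkinDoseRecord, percent_diff, summarize_cohort
from .toxicity import (
    ToxicityRecord,
    interruption_rate,
    tabulate_by_fraction_bin,
    tabulate_timepoints,
)
from .util import round_half_up

__all__ = [
    "load_table",
    "toxicity_records_from_table",
    "hi_from_quantiles",
    "TableCheck",
    "run_table_checks",
]

_TABLE_FILES = {
    "phantom_plan": "table1_phantom_plan.csv",
    "skin_dose": "table3_skin_dose.csv",
    "toxicity": "table4_toxicity.csv",
    "timepoints": "table5_timepoints.csv",
    "staging": "table2_staging.csv",
}

_BIN_COLS = {"n_le10": "<=10", "n_11_15": "11-15", "n_16_20": "16-20", "n_21_25": "21-25"}


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged reference table by short name."""
    if name not in _TABLE_FILES:
        raise FixtureError(f"unknown table {name!r}; have {sorted(_TABLE_FILES)}")
    ref = resources.files("bolusqa") / "data" / _TABLE_FILES[name]
    try:
        with resources.as_file(ref) as path:
            return pd.read_csv(path, keep_default_na=False)
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise FixtureError(f"fixture file {_TABLE_FILES[name]} missing") from exc


def hi_from_quantiles(d2: float, d98: float, d50: float) -> float:
    """Homogeneity index from the three DVH quantiles, report-rounded."""
    return round_half_up((d2 - d98) / d50, 2)


def toxicity_records_from_table(
    df: pd.DataFrame | None = None, total: int = 360
) -> list[ToxicityRecord]:
    """Expand the during-RT toxicity tabulation into per-patient records.

    Each presentation-combination row contributes one record per counted
    patient in each onset bin; interruption flags are assigned to patients
    in the bins of the interruption row.  The reconstructed cohort
    round-trips through :func:`tabulate_by_fraction_bin`.
    """
    df = load_table("toxicity") if df is None else df
    records: list[ToxicityRecord] = []
    interruption_bins: dict[str, int] = {}
    i = 0
    for _, row in df.iterrows():
        if str(row["grade"]) == "interruption":
            interruption_bins = {b: int(row[c]) for c, b in _BIN_COLS.items()}
            continue
        codes = frozenset(str(row["presentations"]).split("+"))
        for col, fbin in _BIN_COLS.items():
            for _ in range(int(row[col])):
                i += 1
                records.append(
                    ToxicityRecord(f"T{i:04d}", fbin, codes, interrupted=False)
                )
    # flag interrupted patients per bin (grade-agnostic: the printed
    # interruption row is tabulated independently of the grade rows)
    flagged: list[ToxicityRecord] = []
    remaining = dict(interruption_bins)
    for r in records:
        if remaining.get(r.fraction_bin, 0) > 0:
            remaining[r.fraction_bin] -= 1
            r = ToxicityRecord(r.patient_id, r.fraction_bin, r.presentations, True)
        flagged.append(r)
    # pad to the cohort total with toxicity-free placeholders is not needed:
    # the published denominators equal the graded-patient total
    if len(flagged) > total:
        raise FixtureError(f"table rows sum to {len(flagged)} > cohort total {total}")
    return flagged


def _timepoint_records(df: pd.DataFrame, col: str, prefix: str) -> list[ToxicityRecord]:
    grade_codes = {1: frozenset({"FE"}), 2: frozenset({"MER"}), 3: frozenset({"CMD"}), 4: frozenset({"NEC"})}
    fbin = "21-25" if col == "during_n" else "post-RT"
    records = []
    i = 0
    for _, row in df.iterrows():
        for _ in range(int(row[col])):
            i += 1
            records.append(ToxicityRecord(f"{prefix}{i:04d}", fbin, grade_codes[int(row["grade"])]))
    return records


@dataclass(frozen=True)
class TableCheck:
    """One recomputed-vs-printed comparison."""

    name: str
    computed: float
    printed: float
    passed: bool


def run_table_checks() -> list[TableCheck]:
    """Recompute every derivable printed value and compare.

    Covers: the phantom-plan homogeneity index from its DVH quantiles, all
    27 per-patient |%diff| values and the D_fact column summary of the
    in-vivo table, the toxicity grade shares, the interruption rate, the
    post-RT grade-4 share, and the stage-III share of the cohort.
    """
    checks: list[TableCheck] = []

    def add(name: str, computed: float, printed: float) -> None:
        checks.append(TableCheck(name, computed, printed, bool(computed == printed)))

    # --- phantom plan: HI from D2%/D98%/D50% ---
    t1 = load_table("phantom_plan").set_index(["structure", "metric"])["value"].astype(float)
    add(
        "phantom HI from D2%/D98%/D50%",
        hi_from_quantiles(t1[("PTV", "D2%")], t1[("PTV", "D98%")], t1[("PTV", "D50%")]),
        t1[("PTV", "HI")],
    )

    # --- in-vivo skin dose: per-patient |%diff| and cohort summary ---
    t3 = load_table("skin_dose")
    records = []
    for _, row in t3.iterrows():
        add(
            f"{row['patient_id']} |%diff|",
            percent_diff(float(row["d_fact_cgy"]), float(row["d_theory_cgy"])),
            float(row["pct_diff_printed"]),
        )
        records.append(
            SkinDoseRecord(
                row["patient_id"],
                {1: float(row["d_fact_cgy"])},
                {1: float(row["d_theory_cgy"])},
            )
        )
    summary = summarize_cohort(records)
    add("D_fact median", round_half_up(summary["d_fact"]["median"], 2), 209.53)
    add("D_fact min", round_half_up(summary["d_fact"]["min"], 2), 204.14)
    add("D_fact max", round_half_up(summary["d_fact"]["max"], 2), 214.42)

    # --- toxicity during RT ---
    cohort = toxicity_records_from_table()
    during = tabulate_by_fraction_bin(cohort)
    add("grade 1 cohort share (%)", round_half_up(during.grade_percent[1], 1), 89.2)
    add("grade 3 cohort share (%)", round_half_up(during.grade_percent[3], 1), 1.9)
    add("interruption rate (%)", interruption_rate(cohort), 1.1)

    # --- during vs post-RT timepoints ---
    t5 = load_table("timepoints")
    d_recs = _timepoint_records(t5, "during_n", "D")
    p_recs = _timepoint_records(t5, "post_n", "P")
    # rosters differ in size only through grade-4 additions; compare by padding ids
    if len(d_recs) != len(p_recs):  # pragma: no cover - fixture always balanced
        raise FixtureError("timepoint fixtures do not cover the same roster size")
    p_recs = [
        ToxicityRecord(d.patient_id, p.fraction_bin, p.presentations, p.interrupted)
        for d, p in zip(d_recs, p_recs)
    ]
    s_during, s_post = tabulate_timepoints(d_recs, p_recs)
    add("grade 2 during-RT share (%)", s_during.grade_percent[2], 8.89)
    add("grade 4 post-RT share (%)", round_half_up(s_post.grade_percent[4], 1), 4.4)

    # --- staging: stage-III share ---
    t2 = load_table("staging").set_index("category")["n"].astype(int)
    stage3 = t2[["IIIA", "IIIB", "IIIC"]].sum()
    add("stage III share (%)", round_half_up(100.0 * stage3 / t2["total"], 1), 60.3)

    return checks
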