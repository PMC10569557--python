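"""Dataset-level statistics: quartile placement, evidence categories, χ².

Proteins are binned by the quarter of the primary structure holding their
best motif hit (P1 = N-terminal 25% ... P4 = C-terminal 25%) and by a
four-way localisation-evidence category derived from curated annotation
scores:

  A  secreted,    score 5 (experimentally confirmed)
  B  secreted,    score strictly between 1 and 3
  C  cytoplasmic, score 5
  D  everything else (no information / residual)

The quartile distribution is tested against a uniform null (a quarter of
the hits in each bin) with a Pearson goodness-of-fit χ², df = 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io_core import ProteinRecord
from .motif_scan import QUARTERS

CATEGORIES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class QuartileCounts:
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(QUARTERS):
            raise ValueError("counts must cover exactly P1..P4")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_tuple(self) -> tuple[int, int, int, int]:
        return tuple(self.counts[q] for q in QUARTERS)


def assign_category(record: ProteinRecord) -> str:
    """Map a record's annotation to evidence category A/B/C/D.

    D is the residual bin: it absorbs secreted proteins with scores 3-4,
    every other localisation, and unannotated records, keeping the
    partition total and exclusive.
    """
    loc, score = record.annotated_localisation, record.annotation_score
    if loc == "secreted" and score == 5:
        return "A"
    if loc == "secreted" and 1 < score < 3:
        return "B"
    if loc == "cytoplasmic" and score == 5:
        return "C"
    return "D"


def category_percentages(categories: list[str]) -> dict[str, float]:
    """Percentage of records per category, rounded to 2 decimals."""
    if not categories:
        raise ValueError("cannot compute percentages of an empty list")
    bad = set(categories) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    n = len(categories)
    return {
        c: round(100.0 * categories.count(c) / n, 2) for c in CATEGORIES
    }


def quartile_distribution(quarters: list[str]) -> QuartileCounts:
    """Count best-match quarters (one entry per protein with a motif)."""
    bad = set(quarters) - set(QUARTERS)
    if bad:
        raise ValueError(f"unknown quarter labels {sorted(bad)}")
    return QuartileCounts({q: quarters.count(q) for q in QUARTERS})


def chi_square_uniform(counts: QuartileCounts) -> tuple[float, int, float]:
    """Pearson χ² of the quartile counts against the uniform null.

    Expected count is total/4 in each quarter; df = 3; p is the upper-tail
    probability of the χ² distribution.
    """
    if counts.total == 0:
        raise ValueError("chi-square undefined for zero total")
    observed = counts.as_tuple()
    statistic, p = stats.chisquare(observed)  # uniform expected by default
    return float(statistic), len(observed) - 1, float(p)


def crosstab(
    categories: dict[str, str], quarters: dict[str, str]
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Category × quarter contingency table keyed by protein id.

    Also reports the headline placement checks: do all A-category proteins
    carry their motif in P1, and do no C-category proteins?
    """
    missing = set(categories) ^ set(quarters)
    if missing:
        raise ValueError(f"ids not present in both inputs: {sorted(missing)}")
    if not categories:
        raise ValueError("crosstab needs at least one protein")
    frame = pd.DataFrame(
        {
            "category": pd.Series(categories),
            "quarter": pd.Series(quarters),
        }
    )
    table = pd.crosstab(frame["category"], frame["quarter"]).reindex(
        index=list(CATEGORIES), columns=list(QUARTERS), fill_value=0
    )
    a_row, c_row = table.loc["A"], table.loc["C"]
    summary = {
        "all_A_in_P1": bool(a_row.sum() > 0 and a_row["P1"] == a_row.sum()),
        "no_C_in_P1": bool(c_row["P1"] == 0),
    }
    return table, summary


def function_crosstab(
    functions: dict[str, str], quarters: dict[str, str]
) -> pd.DataFrame:
    """Annotated-function × quarter contingency table (descriptive)."""
    missing = set(functions) ^ set(quarters)
    if missing:
        raise ValueError(f"ids not present in both inputs: {sorted(missing)}")
    frame = pd.DataFrame(
        {"function": pd.Series(functions), "quarter": pd.Series(quarters)}
    )
    return pd.crosstab(frame["function"], frame["quarter"]).reindex(
        columns=list(QUARTERS), fill_value=0
    )
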