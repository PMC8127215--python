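"""Before/after Likert survey analysis: grouped 2x2 Pearson chi-squared.

Responses on an ordered scale, collected before and after an intervention, are
collapsed into a 2x2 table (low categories vs high categories, before vs
after) and tested for association with Pearson's chi-squared on one degree of
freedom.  Relative percentages of each survey's total are the companion
descriptive view.  The two surveys are treated as independent samples
(respondents were anonymous, so no pairing is possible).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


@dataclass(frozen=True)
class LikertTable:
    """Ordered response categories with before/after respondent counts."""

    categories: tuple[str, ...]
    before_counts: tuple[int, ...]
    after_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.categories) == len(self.before_counts) == len(self.after_counts)):
            raise ValueError("categories, before_counts and after_counts must align")
        if any(c < 0 for c in self.before_counts + self.after_counts):
            raise ValueError("counts must be non-negative")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def totals(self) -> tuple[int, int]:
        return sum(self.before_counts), sum(self.after_counts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LikertTable":
        """Load from a CSV with header ``category,before,after``."""
        df = pd.read_csv(path)
        required = {"category", "before", "after"}
        if not required.issubset(df.columns):
            raise ValueError(f"survey CSV needs columns {sorted(required)}")
        return cls(
            categories=tuple(str(c) for c in df["category"]),
            before_counts=tuple(int(c) for c in df["before"]),
            after_counts=tuple(int(c) for c in df["after"]),
        )


def load_table1() -> LikertTable:
    """The bundled first-year case-count estimation survey fixture.

    Students estimated, before and after the class simulation, how many cases
    of a prevalence-1/10,000 condition their graduating cohort would see in
    its first year of practice.
    """
    with resources.as_file(
        resources.files("rarecareer.data").joinpath("table1.csv")
    ) as path:
        return LikertTable.from_csv(path)


def group_to_2x2(table: LikertTable, split_after: int) -> np.ndarray:
    """Collapse ordered categories into a 2x2 before/after x low/high table.

    ``split_after`` is the 1-based index of the last category in the low
    group.  Rows are (before, after); columns are (low, high).  Grand totals
    are preserved.
    """
    if not 1 <= split_after < table.n_categories:
        raise ValueError(
            f"split_after must be in 1..{table.n_categories - 1}, got {split_after}"
        )
    before = np.asarray(table.before_counts)
    after = np.asarray(table.after_counts)
    return np.array(
        [
            [before[:split_after].sum(), before[split_after:].sum()],
            [after[:split_after].sum(), after[split_after:].sum()],
        ],
        dtype=np.int64,
    )


def pearson_chi2(table2x2: np.ndarray, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test of association on a 2x2 table.

    Returns ``(statistic, df, p_value)`` with df = 1 and expected counts from
    the margins.  Continuity correction is off by default; pass ``yates=True``
    for the corrected statistic.

    Raises
    ------
    ValueError
        If any count is negative or any row/column margin is zero (the test
        is undefined).
    """
    obs = np.asarray(table2x2, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("chi-squared test undefined with a zero margin")
    result = chi2_contingency(obs, correction=yates)
    return float(result.statistic), int(result.dof), float(result.pvalue)


def relative_percentages(table: LikertTable, decimals: int = 1) -> pd.DataFrame:
    """Per-category percentages of each survey's respondent total.

    Returns a DataFrame indexed by category with ``before_pct`` and
    ``after_pct`` columns, rounded to ``decimals`` decimal places.
    """
    total_before, total_after = table.totals
    if total_before == 0 or total_after == 0:
        raise ValueError("relative percentages undefined for an empty survey")
    return pd.DataFrame(
        {
            "before": table.before_counts,
            "before_pct": np.round(
                100 * np.asarray(table.before_counts) / total_before, decimals
            ),
            "after": table.after_counts,
            "after_pct": np.round(
                100 * np.asarray(table.after_counts) / total_after, decimals
            ),
        },
        index=pd.Index(table.categories, name="category"),
    )
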