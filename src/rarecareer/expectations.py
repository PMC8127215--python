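"""Closed-form expected encounter counts: the simulator's deterministic oracle.

Expectations are linear in prevalence, panel size, years and cohort size —
prevalence is treated as a per-year encounter probability, with no
finite-panel depletion correction.  The classic desk arithmetic follows
directly: a panel of 2000 yields about one case per year of a 1/2000
condition; one case per 30-year career at 1/60,000; and a cohort of 200 such
clinicians can expect 12 career encounters with a one-in-a-million condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_non_negative(**kwargs) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def expected_annual_cases(prevalence: float, panel_size: float) -> float:
    """Expected cases per clinician per year: prevalence * panel_size."""
    _check_non_negative(prevalence=prevalence, panel_size=panel_size)
    if prevalence > 1:
        raise ValueError(f"prevalence must be <= 1, got {prevalence}")
    return prevalence * panel_size


def expected_career_cases(prevalence: float, panel_size: float, years: float) -> float:
    """Expected cases per clinician over a career of ``years`` years."""
    _check_non_negative(years=years)
    return expected_annual_cases(prevalence, panel_size) * years


def expected_cohort_cases(
    prevalence: float, panel_size: float, years: float, n_clinicians: float
) -> float:
    """Expected cases across a whole cohort of clinicians."""
    _check_non_negative(n_clinicians=n_clinicians)
    return expected_career_cases(prevalence, panel_size, years) * n_clinicians


def expectation_table(
    prevalences, panel_size: float, years: float, n_clinicians: float
) -> pd.DataFrame:
    """Tabulate annual / career / cohort expectations over a prevalence grid."""
    p = np.asarray(list(prevalences), dtype=float)
    return pd.DataFrame(
        {
            "prevalence": p,
            "annual_per_clinician": p * panel_size,
            "career_per_clinician": p * panel_size * years,
            "cohort_total": p * panel_size * years * n_clinicians,
        }
    )
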