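"""Aggregate a simulated case cube into the standard presentation views.

Four views mirror how a class examines a run: cohort per-condition career
totals, cohort first-year totals, the all-clinician all-year scatter, and the
per-clinician career table (where congenital persistence shows up as
consecutive-year runs ending only at practice changes).  Scatter rows carry a
colour-bin label running from black (exactly 1 case) to magenta (>= 300).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rarecareer.engine import CaseCube

#: Geometric colour-bin edges; the endpoints (1 -> black, >=300 -> magenta)
#: are fixed, the interior edges are cosmetic.
COLOUR_BINS: tuple[tuple[int, int | None, str], ...] = (
    (1, 1, "black"),
    (2, 4, "blue"),
    (5, 14, "cyan"),
    (15, 49, "green"),
    (50, 149, "yellow"),
    (150, 299, "red"),
    (300, None, "magenta"),
)


def _pick_array(cube: CaseCube, mode: str) -> np.ndarray:
    if mode == "new":
        return cube.new_counts
    if mode == "counts":
        return cube.counts
    raise ValueError(f"mode must be 'new' or 'counts', got {mode!r}")


def cohort_condition_totals(cube: CaseCube, mode: str = "new") -> pd.Series:
    """Per-code totals across all clinicians and years.

    The default ``new`` mode counts unique patients; ``counts`` instead counts
    patient-years, so persisting congenital cases are counted in every year
    they remain in the panel.
    """
    arr = _pick_array(cube, mode)
    totals = arr.sum(axis=(0, 1))
    return pd.Series(totals, index=np.arange(1, cube.n_conditions + 1), name="cases")


def first_year_totals(cube: CaseCube, mode: str = "new") -> pd.Series:
    """Per-code cohort totals in the first year of practice."""
    arr = _pick_array(cube, mode)
    totals = arr[:, 0, :].sum(axis=0)
    return pd.Series(totals, index=np.arange(1, cube.n_conditions + 1), name="cases")


def clinician_career_table(
    cube: CaseCube, clinician_index: int, mode: str = "counts"
) -> pd.DataFrame:
    """One clinician's year x code table (1-based clinician index).

    Defaults to ``counts`` so that congenital caseloads persisting between
    practice changes are visible as consecutive-year runs.
    """
    counts, new_counts = cube.clinician_slice(clinician_index)
    arr = counts if mode == "counts" else new_counts
    return pd.DataFrame(
        arr,
        index=pd.Index(np.arange(1, cube.years + 1), name="year"),
        columns=pd.Index(np.arange(1, cube.n_conditions + 1), name="code"),
    )


def colour_bin(cases: int) -> str:
    """Colour-bin label for a positive case count (1 = black ... >=300 = magenta)."""
    if cases < 1:
        raise ValueError(f"colour bins are defined for cases >= 1, got {cases}")
    for lo, hi, label in COLOUR_BINS:
        if hi is None or lo <= cases <= hi:
            if cases >= lo:
                return label
    raise AssertionError("unreachable")


def _binned_rows(x: np.ndarray, y: np.ndarray, cases: np.ndarray) -> pd.DataFrame:
    keep = cases >= 1
    df = pd.DataFrame({"x": x[keep], "y": y[keep], "cases": cases[keep]})
    df["bin"] = [colour_bin(c) for c in df["cases"]]
    return df


def scatter_table(cube: CaseCube, view: str, clinician_index: int | None = None,
                  mode: str = "new") -> pd.DataFrame:
    """Scatter rows (zero cells omitted) for one of the presentation views.

    ``view`` is one of:

    - ``cohort``: x = code, y = cohort career total
    - ``first_year``: x = code, y = cohort year-1 total
    - ``all``: x = code, y = clinician, cases summed over years
    - ``clinician``: x = code, y = year, for one clinician (``clinician_index``)
    """
    codes = np.arange(1, cube.n_conditions + 1)
    if view == "cohort":
        totals = cohort_condition_totals(cube, mode=mode).to_numpy()
        return _binned_rows(codes, totals, totals)
    if view == "first_year":
        totals = first_year_totals(cube, mode=mode).to_numpy()
        return _binned_rows(codes, totals, totals)
    if view == "all":
        arr = _pick_array(cube, mode).sum(axis=1)  # clinician x code
        clin, code = np.nonzero(arr)
        return _binned_rows(code + 1, clin + 1, arr[clin, code])
    if view == "clinician":
        if clinician_index is None:
            raise ValueError("clinician view requires clinician_index")
        table = clinician_career_table(
            cube, clinician_index, mode="counts" if mode == "counts" else "new"
        ).to_numpy()
        year, code = np.nonzero(table)
        return _binned_rows(code + 1, year + 1, table[year, code])
    raise ValueError(f"unknown view {view!r}")


def plot_scattergram(df: pd.DataFrame, title: str = "", ax=None):
    """Optional matplotlib rendering of a scatter table (headless CSV is the contract)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    palette = {label: label for _, _, label in COLOUR_BINS}
    for label in palette:
        sub = df[df["bin"] == label]
        if len(sub):
            ax.scatter(sub["x"], sub["y"], s=6, c=label, label=label)
    ax.set_title(title)
    ax.set_xlabel("condition code")
    ax.legend(fontsize="x-small", title="cases")
    return ax
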