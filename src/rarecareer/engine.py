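"""Cohort career simulator.

An outer loop over clinicians and an inner loop over conditions assign, year by
year, random case counts drawn according to (locally jittered) prevalence.
Spontaneous conditions arise anew in the standing panel each year; congenital/
persistent conditions are only encountered in patients newly entering the panel
(a full fresh panel in year one and at each practice change, otherwise the
attrition-replacement fraction), and their caseload accumulates until the
clinician moves to a new practice.

Each clinician runs on an independent RNG substream derived from the master
seed, so enlarging the cohort never perturbs earlier clinicians' careers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rarecareer.config import (
    SimulationConfig,
    BINOMIAL,
    EXPECTED_BRANCH,
    JOB_CHANGE_ONLY,
    ATTRITION_ALSO,
)
from rarecareer.prevalence import Condition, DiseaseList


@dataclass(frozen=True)
class CareerPlan:
    """Practice-change schedule for one clinician.

    ``job_change_years`` are the years (within 2..years) in which the clinician
    starts at a new practice; year 1 is always a fresh panel and never listed.
    """

    clinician_index: int
    job_change_years: frozenset[int]

    def is_change_year(self, year: int) -> bool:
        return year in self.job_change_years


def clinician_rng(seed: int, clinician_index: int) -> np.random.Generator:
    """Independent substream for one clinician, stable across cohort sizes."""
    return np.random.default_rng(np.random.SeedSequence((seed, clinician_index)))


def draw_career_plan(
    config: SimulationConfig, clinician_index: int, rng: np.random.Generator
) -> CareerPlan:
    """Draw a practice-change schedule.

    The number of changes is uniform on [min_job_changes, max_job_changes];
    the change years are drawn uniformly without replacement from {2..years}.
    """
    if config.max_job_changes > config.years - 1:
        raise ValueError("max_job_changes cannot exceed years - 1")
    n_changes = int(rng.integers(config.min_job_changes, config.max_job_changes + 1))
    candidates = np.arange(2, config.years + 1)
    change_years = rng.choice(candidates, size=n_changes, replace=False)
    return CareerPlan(
        clinician_index=clinician_index,
        job_change_years=frozenset(int(y) for y in change_years),
    )


def jittered_prevalence(
    p: float, jitter_fraction: float, rng: np.random.Generator
) -> float:
    """Perturb a prevalence by a uniform relative factor in +/- jitter_fraction.

    Drawn once per (clinician, condition) and held constant over that career,
    mimicking fixed local demographics.  The result is clamped to [0, 1].
    """
    if not 0 <= p <= 1:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    u = rng.uniform(-jitter_fraction, jitter_fraction)
    return float(np.clip(p * (1.0 + u), 0.0, 1.0))


def new_patient_count(plan: CareerPlan, year: int, config: SimulationConfig) -> int:
    """Number of patients newly entering the panel in ``year``.

    The whole panel in year 1 and in practice-change years; otherwise the
    attrition-replacement fraction, rounded half away from zero.
    """
    if not 1 <= year <= config.years:
        raise ValueError(f"year out of range 1..{config.years}: {year}")
    if year == 1 or plan.is_change_year(year):
        return config.panel_size
    return int(np.floor(config.attrition_rate * config.panel_size + 0.5))


def sample_case_count(
    n_exposed: int | np.ndarray,
    p: float,
    mode: str,
    rng: np.random.Generator,
):
    """Random yearly case count among ``n_exposed`` patients at prevalence ``p``.

    ``binomial`` draws Binomial(n_exposed, p).  ``expected_branch`` reproduces
    the branch on whether the expected count lambda = n_exposed * p is below
    one: floor(lambda) certain cases plus a Bernoulli(lambda - floor(lambda))
    extra case (for lambda < 1 this is simply Bernoulli(lambda)).  Both modes
    have mean n_exposed * p.  Accepts scalar or array ``n_exposed``.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    n = np.asarray(n_exposed)
    if np.any(n < 0):
        raise ValueError("n_exposed must be non-negative")
    if mode == BINOMIAL:
        out = rng.binomial(n, p)
    elif mode == EXPECTED_BRANCH:
        lam = n * p
        base = np.floor(lam)
        frac = lam - base
        out = (base + (rng.random(lam.shape) < frac)).astype(np.int64)
        out = np.minimum(out, n)  # cannot exceed the exposed pool
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return int(out) if np.isscalar(n_exposed) else out


def simulate_condition_career(
    condition: Condition,
    plan: CareerPlan,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one condition over one clinician's career.

    Returns ``(counts, new_counts)``, each of length ``config.years``.
    For spontaneous conditions the two are identical: an independent draw from
    the standing panel each year.  For congenital/persistent conditions
    ``new_counts`` are draws from that year's newly arriving patients, and
    ``counts`` is the active caseload: reset to the fresh draw in year 1 and at
    each practice change, otherwise accumulating (and, in ``attrition_also``
    mode, also shedding each carried patient with the attrition probability).
    The caseload is capped at the panel size.
    """
    years = config.years
    p_eff = jittered_prevalence(condition.prevalence, config.jitter_fraction, rng)

    if not condition.is_congenital:
        counts = sample_case_count(
            np.full(years, config.panel_size), p_eff, config.sampling_mode, rng
        )
        return counts.astype(np.int64), counts.astype(np.int64)

    n_new = np.array(
        [new_patient_count(plan, y, config) for y in range(1, years + 1)]
    )
    new_counts = sample_case_count(n_new, p_eff, config.sampling_mode, rng).astype(
        np.int64
    )
    counts = np.zeros(years, dtype=np.int64)
    active = 0
    for y in range(1, years + 1):
        new = int(new_counts[y - 1])
        if y == 1 or plan.is_change_year(y):
            active = new
        else:
            if config.congenital_loss == ATTRITION_ALSO and active > 0:
                active -= int(rng.binomial(active, config.attrition_rate))
            active += new
        active = min(active, config.panel_size)
        counts[y - 1] = active
    return counts, new_counts


@dataclass(frozen=True)
class CaseCube:
    """Case counts indexed (clinician, year, condition code), all 1-based.

    ``counts`` is the caseload seen in each year; ``new_counts`` restricts to
    newly encountered patients (identical for spontaneous conditions).
    """

    counts: np.ndarray      # shape (n_clinicians, years, n_conditions)
    new_counts: np.ndarray  # same shape
    config: SimulationConfig
    disease_fingerprint: str
    plans: tuple[CareerPlan, ...] = field(repr=False, default=())

    @property
    def n_clinicians(self) -> int:
        return self.counts.shape[0]

    @property
    def years(self) -> int:
        return self.counts.shape[1]

    @property
    def n_conditions(self) -> int:
        return self.counts.shape[2]

    def clinician_slice(self, clinician_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(counts, new_counts) year x code matrices for one clinician (1-based)."""
        if not 1 <= clinician_index <= self.n_clinicians:
            raise IndexError(
                f"clinician index out of range 1..{self.n_clinicians}: {clinician_index}"
            )
        i = clinician_index - 1
        return self.counts[i], self.new_counts[i]

    def to_long_frame(self, drop_zero: bool = True) -> pd.DataFrame:
        """Long-format table: clinician, year, code, cases, new_cases."""
        C, Y, N = self.counts.shape
        idx = np.nonzero(self.counts | self.new_counts) if drop_zero else np.nonzero(
            np.ones_like(self.counts)
        )
        return pd.DataFrame(
            {
                "clinician": idx[0] + 1,
                "year": idx[1] + 1,
                "code": idx[2] + 1,
                "cases": self.counts[idx],
                "new_cases": self.new_counts[idx],
            }
        )

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write the long-format CSV, plus a JSON provenance sidecar."""
        import json
        from pathlib import Path

        self.to_long_frame().to_csv(path, index=False)
        if sidecar_path is not None:
            Path(sidecar_path).write_text(
                json.dumps(
                    {
                        "config": self.config.to_dict(),
                        "disease_fingerprint": self.disease_fingerprint,
                        "shape": list(self.counts.shape),
                    },
                    indent=2,
                )
                + "\n"
            )


def simulate_cohort(config: SimulationConfig, disease_list: DiseaseList) -> CaseCube:
    """Run the full double loop: every clinician, every condition, every year.

    Bit-identical for identical (config, disease_list): each clinician draws
    from a substream seeded by (master seed, clinician index).
    """
    C, Y, N = config.n_clinicians, config.years, len(disease_list)
    counts = np.zeros((C, Y, N), dtype=np.int64)
    new_counts = np.zeros((C, Y, N), dtype=np.int64)
    plans = []
    for i in range(1, C + 1):
        rng = clinician_rng(config.seed, i)
        plan = draw_career_plan(config, i, rng)
        plans.append(plan)
        for j, condition in enumerate(disease_list):
            c, nc = simulate_condition_career(condition, plan, config, rng)
            counts[i - 1, :, j] = c
            new_counts[i - 1, :, j] = nc
    return CaseCube(
        counts=counts,
        new_counts=new_counts,
        config=config,
        disease_fingerprint=disease_list.fingerprint(),
        plans=tuple(plans),
    )
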