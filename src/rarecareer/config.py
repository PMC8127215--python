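"""Simulation configuration: cohort, career, panel and sampling parameters."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

#: Sampling of yearly case counts from exposed patients.
BINOMIAL = "binomial"            # Binomial(n_exposed, p): patient-level draw
EXPECTED_BRANCH = "expected_branch"  # floor(lambda) + Bernoulli(frac), lambda = n*p

#: How a congenital caseload can shrink.
JOB_CHANGE_ONLY = "job_change_only"  # reset only on moving to a new practice
ATTRITION_ALSO = "attrition_also"    # afflicted patients also leave via attrition


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one cohort career simulation.

    Attributes
    ----------
    n_clinicians:
        Cohort size (e.g. a graduating class of 95-97 students).
    years:
        Career length in years of practice.
    panel_size:
        Patients per clinician panel (~2000 medical, ~1500 dental).
    min_job_changes, max_job_changes:
        Range for the number of moves to a new practice after the first job;
        the actual count per clinician is drawn uniformly from this range.
    attrition_rate:
        Fraction of the panel replaced by new patients in a year without a
        practice change; the only other route by which congenital cases enter.
    jitter_fraction:
        Maximum relative perturbation of prevalence per (clinician, condition),
        mimicking local geographic/demographic variation; default +/-15%.
    sampling_mode:
        ``binomial`` (default) or ``expected_branch``; both have mean
        n_exposed * prevalence.
    congenital_loss:
        ``job_change_only`` (default: caseload persists until a practice
        change) or ``attrition_also``.
    seed:
        Master RNG seed; per-clinician substreams are derived from it.
    """

    n_clinicians: int = 97
    years: int = 30
    panel_size: int = 1500
    min_job_changes: int = 2
    max_job_changes: int = 10
    attrition_rate: float = 0.10
    jitter_fraction: float = 0.15
    sampling_mode: str = BINOMIAL
    congenital_loss: str = JOB_CHANGE_ONLY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clinicians < 1 or self.years < 1 or self.panel_size < 1:
            raise ValueError("n_clinicians, years and panel_size must be >= 1")
        if not (0 <= self.min_job_changes <= self.max_job_changes <= self.years - 1):
            raise ValueError(
                "need 0 <= min_job_changes <= max_job_changes <= years - 1, got "
                f"{self.min_job_changes}..{self.max_job_changes} for {self.years} years"
            )
        if not 0 <= self.attrition_rate < 1:
            raise ValueError(f"attrition_rate must be in [0, 1), got {self.attrition_rate}")
        if not 0 <= self.jitter_fraction < 1:
            raise ValueError(f"jitter_fraction must be in [0, 1), got {self.jitter_fraction}")
        if self.sampling_mode not in (BINOMIAL, EXPECTED_BRANCH):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")
        if self.congenital_loss not in (JOB_CHANGE_ONLY, ATTRITION_ALSO):
            raise ValueError(f"unknown congenital_loss {self.congenital_loss!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
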