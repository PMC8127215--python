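"""Theoretical disease list: exponentially decaying prevalence over condition codes.

The list assigns each condition a Condition Code Number (CCN, 1-based) and a
prevalence p(c) = p_max * exp(-k * (c - 1)), with the decay rate k anchored so
that code 1 has prevalence ``p_max`` and the last code has ``p_min``.  With the
defaults (0.641 down to 1e-6 over 462 codes) code 200 lands at the 1/500
European rare-disease threshold of 2e-3, code 303 at 1e-4 and code 382 at 1e-5.

Each condition is additionally labelled as either *spontaneous* (arising anew in
the standing patient panel each year, e.g. infections) or
*congenital/persistent* (carried lifelong, e.g. haemophilia or amelogenesis
imperfecta, hence first encountered only when the carrying patient newly enters
the panel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SPONTANEOUS = "spontaneous"
CONGENITAL = "congenital"

#: Default anchors: 462 conditions spanning prevalence 0.641 down to 1e-6,
#: of which 73 are congenital/persistent.
DEFAULT_P_MAX = 0.641
DEFAULT_P_MIN = 1e-6
DEFAULT_N_CONDITIONS = 462
DEFAULT_N_CONGENITAL = 73


def decay_rate(p_max: float, p_min: float, n_conditions: int) -> float:
    """Per-code exponential decay rate anchored by the two endpoint prevalences.

    Returns k = ln(p_max / p_min) / (n_conditions - 1), so that
    p(1) = p_max and p(n_conditions) = p_min exactly.

    Raises
    ------
    ValueError
        If prevalences are non-positive, p_min > p_max, or fewer than two codes.
    """
    if not (0 < p_min <= p_max <= 1):
        raise ValueError(
            f"require 0 < p_min <= p_max <= 1, got p_min={p_min}, p_max={p_max}"
        )
    if n_conditions < 2:
        raise ValueError(f"n_conditions must be >= 2, got {n_conditions}")
    return math.log(p_max / p_min) / (n_conditions - 1)


@dataclass(frozen=True)
class PrevalenceCurve:
    """Decaying-exponential mapping from condition code to prevalence."""

    p_max: float = DEFAULT_P_MAX
    p_min: float = DEFAULT_P_MIN
    n_conditions: int = DEFAULT_N_CONDITIONS
    decay_rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_conditions == 1:
            if not (0 < self.p_min == self.p_max <= 1):
                raise ValueError("single-code curve requires p_min == p_max in (0, 1]")
            object.__setattr__(self, "decay_rate", 0.0)
        else:
            object.__setattr__(
                self, "decay_rate", decay_rate(self.p_max, self.p_min, self.n_conditions)
            )

    def prevalence(self, code: int | np.ndarray) -> float | np.ndarray:
        """Prevalence at ``code`` (1-based); endpoints reproduce the anchors exactly."""
        code_arr = np.asarray(code)
        if np.any(code_arr < 1) or np.any(code_arr > self.n_conditions):
            raise ValueError(f"code out of range 1..{self.n_conditions}: {code}")
        p = self.p_max * np.exp(-self.decay_rate * (code_arr - 1))
        # pin the far endpoint to p_min at full floating precision
        p = np.where(code_arr == self.n_conditions, self.p_min, p)
        return float(p) if np.isscalar(code) or code_arr.ndim == 0 else p


def prevalence_for_code(curve: PrevalenceCurve, code: int) -> float:
    """Functional alias for :meth:`PrevalenceCurve.prevalence`."""
    return curve.prevalence(code)


def assign_acquisition_classes(
    n_conditions: int, n_congenital: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Randomly label exactly ``n_congenital`` of the codes congenital/persistent.

    Codes are chosen uniformly without replacement; the remainder are
    spontaneous.  Deterministic for a given seed.  Returns an array of
    ``n_conditions`` labels in code order.
    """
    if not 0 <= n_congenital <= n_conditions:
        raise ValueError(
            f"n_congenital must be in 0..{n_conditions}, got {n_congenital}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.full(n_conditions, SPONTANEOUS, dtype=object)
    chosen = rng.choice(n_conditions, size=n_congenital, replace=False)
    labels[chosen] = CONGENITAL
    return labels


@dataclass(frozen=True)
class Condition:
    """One theoretical condition: code, prevalence, acquisition class."""

    code: int
    prevalence: float
    acquisition_class: str

    def __post_init__(self) -> None:
        if self.code < 1:
            raise ValueError("code must be >= 1")
        if not 0 <= self.prevalence <= 1:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.acquisition_class not in (SPONTANEOUS, CONGENITAL):
            raise ValueError(f"unknown acquisition class {self.acquisition_class!r}")

    @property
    def is_congenital(self) -> bool:
        return self.acquisition_class == CONGENITAL


@dataclass(frozen=True)
class DiseaseList:
    """Ordered list of conditions with contiguous 1-based codes."""

    conditions: tuple[Condition, ...]
    curve: PrevalenceCurve | None = None  # None for user-supplied lists

    def __post_init__(self) -> None:
        codes = [c.code for c in self.conditions]
        if codes != list(range(1, len(codes) + 1)):
            raise ValueError("condition codes must be contiguous and 1-based")

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def __getitem__(self, i):
        return self.conditions[i]

    @property
    def prevalences(self) -> np.ndarray:
        return np.array([c.prevalence for c in self.conditions])

    @property
    def congenital_mask(self) -> np.ndarray:
        return np.array([c.is_congenital for c in self.conditions])

    @property
    def n_congenital(self) -> int:
        return int(self.congenital_mask.sum())

    def fingerprint(self) -> str:
        """Stable hex digest of codes, prevalences and classes (provenance)."""
        import hashlib

        h = hashlib.sha256()
        for c in self.conditions:
            h.update(f"{c.code},{c.prevalence!r},{c.acquisition_class};".encode())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [c.code for c in self.conditions],
                "prevalence": [c.prevalence for c in self.conditions],
                "acquisition_class": [c.acquisition_class for c in self.conditions],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        # %.17g round-trips any double exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DiseaseList":
        required = {"code", "prevalence", "acquisition_class"}
        if not required.issubset(df.columns):
            raise ValueError(f"disease list needs columns {sorted(required)}")
        df = df.sort_values("code")
        conditions = tuple(
            Condition(int(r.code), float(r.prevalence), str(r.acquisition_class))
            for r in df.itertuples()
        )
        return cls(conditions=conditions, curve=None)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiseaseList":
        """Load a user-supplied list (columns: code, prevalence, acquisition_class)."""
        # round_trip parser: pandas' fast float path can be 1 ulp off
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


def build_disease_list(
    p_max: float = DEFAULT_P_MAX,
    p_min: float = DEFAULT_P_MIN,
    n_conditions: int = DEFAULT_N_CONDITIONS,
    n_congenital: int = DEFAULT_N_CONGENITAL,
    seed: int = 0,
) -> DiseaseList:
    """Construct the theoretical disease list from the curve parameters.

    A pure function of its arguments: the same parameters and seed always
    return an identical list.
    """
    curve = PrevalenceCurve(p_max, p_min, n_conditions)
    labels = assign_acquisition_classes(n_conditions, n_congenital, seed)
    conditions = tuple(
        Condition(code, float(curve.prevalence(code)), labels[code - 1])
        for code in range(1, n_conditions + 1)
    )
    return DiseaseList(conditions=conditions, curve=curve)
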