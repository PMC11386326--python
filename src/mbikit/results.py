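"""Shared container for regression results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd


@dataclass(frozen=True)
class TermEstimate:
    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError(
                f"term {self.name!r}: CI [{self.ci_low}, {self.ci_high}] "
                f"does not bracket estimate {self.estimate}"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"term {self.name!r}: p-value {self.p_value} outside [0,1]")


@dataclass
class ModelResult:
    """Coefficient table for one fitted model (linear or Cox)."""

    terms: list[TermEstimate]
    stratum: str
    outcome: str
    n_used: int
    n_dropped: int = 0
    #: design matrix retained for residual diagnostics (not serialized)
    design: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __getitem__(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.name for t in self.terms],
                "estimate": [t.estimate for t in self.terms],
                "se": [t.se for t in self.terms],
                "ci_low": [t.ci_low for t in self.terms],
                "ci_high": [t.ci_high for t in self.terms],
                "p": [t.p_value for t in self.terms],
            }
        ).assign(stratum=self.stratum, outcome=self.outcome, n=self.n_used)
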