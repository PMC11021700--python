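"""Shared result containers for intervention-effect estimates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

METHODS = ("noncausal", "ipw", "external")


@dataclass
class EffectEstimate:
    """Relative risk of treated vs untreated cumulative five-year risk."""

    rr: float
    ci_low: float
    ci_high: float
    method: str
    n: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.rr <= 0:
            raise ValueError("relative risk must be positive")
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not self.ci_low <= self.rr <= self.ci_high:
                raise ValueError(
                    f"interval ({self.ci_low}, {self.ci_high}) does not "
                    f"bracket the point estimate {self.rr}")

    def to_dict(self) -> dict:
        return {"rr": self.rr, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "method": self.method, "n": self.n,
                "diagnostics": dict(self.diagnostics)}
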