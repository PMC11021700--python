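"""Approach (c): combining model risks with externally reported effects.

Risk under intervention is the two-stage identity

    risk_intervention = risk_original * RR,

with the relative risk taken from published evidence syntheses of
primary-prevention trials rather than estimated from the cohort in hand.
The effect is applied as a constant on the relative scale for every person
(heterogeneity on the absolute scale then comes only from baseline risk),
and interval propagation multiplies the risk by the RR's interval limits —
which deliberately ignores the prediction model's own uncertainty.

The built-in registry carries the published overview-of-systematic-reviews
estimates used by the Million Hearts tool: smoking cessation 0.73
(0.62-0.85); lifestyle SBP lowering 0.65 (0.57-0.75) per 10 mmHg; BP
medication 0.73 (0.67-0.81); lipid lowering through lifestyle 0.75
(0.70-0.80) per 1 mmol/L LDL; statins 0.75 (0.70-0.81). The per-10-mmHg and
per-mmol/L effects are mapped onto the categorical scenarios without dose
adjustment, mirroring how the source tool uses them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class ExternalEffect:
    scenario_id: str
    rr: float
    ci_low: float
    ci_high: float
    source: str = ""

    def __post_init__(self):
        if self.rr <= 0 or self.ci_low <= 0 or self.ci_high <= 0:
            raise ValueError("relative risks must be positive")
        if not self.ci_low <= self.rr <= self.ci_high:
            raise ValueError("interval must bracket the point estimate")


_BUILTIN = {
    "I": ExternalEffect("I", 0.73, 0.62, 0.85,
                        "overview of systematic reviews: smoking cessation"),
    "IIa": ExternalEffect("IIa", 0.65, 0.57, 0.75,
                          "per 10 mmHg actual SBP lowering"),
    "IIb": ExternalEffect("IIb", 0.73, 0.67, 0.81,
                          "BP-lowering therapy"),
    "IIIa": ExternalEffect("IIIa", 0.75, 0.70, 0.80,
                           "per 1 mmol/L LDL-cholesterol reduction"),
    "IIIb": ExternalEffect("IIIb", 0.75, 0.70, 0.81,
                           "lipid-lowering medication (statins)"),
}


def builtin_effects() -> dict[str, ExternalEffect]:
    """The five published effects, keyed by scenario id."""
    return dict(_BUILTIN)


def get_effect(scenario_id: str,
               registry: dict[str, ExternalEffect] | None = None) -> ExternalEffect:
    reg = registry if registry is not None else _BUILTIN
    try:
        return reg[scenario_id]
    except KeyError:
        raise KeyError(f"no external effect registered for scenario "
                       f"{scenario_id!r}; known: {sorted(reg)}") from None


def effects_from_yaml(path: str) -> dict[str, ExternalEffect]:
    """Load an effects table from YAML: ``{id: {rr, ci_low, ci_high, source}}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {sid: ExternalEffect(scenario_id=sid, **vals) for sid, vals in raw.items()}


def combine(risks: pd.DataFrame, effect: ExternalEffect) -> pd.DataFrame:
    """Apply ``risk_intervention = risk * RR`` per person (capped at 1).

    ``risks`` needs columns ``id`` and ``risk``. Returns the standard
    pair table (id, risk_original, risk_intervention, individual_rr, arc);
    ``individual_rr`` equals the external RR for everyone below the cap.
    """
    risk0 = risks["risk"].to_numpy(dtype=float)
    if ((risk0 < 0) | (risk0 > 1)).any():
        raise ValueError("risks must lie in [0, 1]")
    risk1 = risk0 * effect.rr
    capped = risk1 > 1.0
    if capped.any():
        warnings.warn(f"{int(capped.sum())} intervention risks exceeded 1 "
                      f"and were capped", RuntimeWarning, stacklevel=2)
        risk1 = np.minimum(risk1, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        irr = np.where(risk0 > 0, risk1 / risk0, np.nan)
    return pd.DataFrame({
        "id": risks["id"].to_numpy(),
        "risk_original": risk0,
        "risk_intervention": risk1,
        "individual_rr": irr,
        "arc": risk0 - risk1,
    })
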