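"""The five intervention scenarios: eligibility, covariate modification,
and follow-up-based treatment derivation.

Scenarios (thresholds inclusive as printed in clinical guidance):

* ``I``    smoking cessation — current smokers; smoking set to ``ex``.
* ``IIa``  lowering SBP without medication — SBP >= 140; SBP set to 130.
* ``IIb``  starting BP-lowering medication — SBP >= 140 and BPLM = 0;
           BPLM set to 1 and (default variant) SBP set to 130.
* ``IIIa`` lowering TC/HDL without medication — TC/HDL >= 5; set to 3.5.
* ``IIIb`` starting lipid-lowering medication — TC/HDL >= 5 and LLM = 0;
           LLM set to 1 and (default variant) TC/HDL set to 3.5.

For the IPW approach, treatment status is read off one index visit within a
two-year window after baseline: the visit closest to the two-year mark by
default, or the first visit in the sensitivity mode. Participants with no
visit in the window are excluded (a state, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

VARIANTS = ("with_factor_change", "medication_only")


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    description: str
    window_months: float = 24.0
    #: for IIb/IIIb: whether modification also imposes the factor change
    variant: str = "with_factor_change"
    sbp_threshold: float = 140.0
    tchdl_threshold: float = 5.0
    sbp_target: float = 130.0
    tchdl_target: float = 3.5

    def __post_init__(self):
        if self.window_months <= 0:
            raise ValueError("window_months must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


SCENARIOS: dict[str, ScenarioSpec] = {
    "I": ScenarioSpec("I", "smoking cessation"),
    "IIa": ScenarioSpec("IIa", "lowering SBP through lifestyle"),
    "IIb": ScenarioSpec("IIb", "BP-lowering medication initiation"),
    "IIIa": ScenarioSpec("IIIa", "lowering TC/HDL through lifestyle"),
    "IIIb": ScenarioSpec("IIIb", "lipid-lowering medication initiation"),
}


def get_scenario(scenario_id: str, **overrides) -> ScenarioSpec:
    """Built-in scenario, optionally with overridden window/variant/thresholds."""
    try:
        spec = SCENARIOS[scenario_id]
    except KeyError:
        raise KeyError(f"unknown scenario {scenario_id!r}; "
                       f"known: {sorted(SCENARIOS)}") from None
    return replace(spec, **overrides) if overrides else spec


def scenarios_from_yaml(path: str) -> dict[str, ScenarioSpec]:
    """Load scenario overrides from a YAML mapping ``{id: {field: value}}``;
    unmentioned scenarios keep their built-in definitions."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(SCENARIOS)
    for sid, over in raw.items():
        out[sid] = get_scenario(sid, **(over or {}))
    return out


def eligible(baseline: pd.DataFrame, spec: ScenarioSpec) -> pd.Series:
    """Boolean target-population indicator, vectorised over the table."""
    if spec.id == "I":
        m = baseline["smoking"] == "current"
    elif spec.id == "IIa":
        m = baseline["sbp"] >= spec.sbp_threshold
    elif spec.id == "IIb":
        m = (baseline["sbp"] >= spec.sbp_threshold) & (baseline["bplm"] == 0)
    elif spec.id == "IIIa":
        m = baseline["tchdl"] >= spec.tchdl_threshold
    elif spec.id == "IIIb":
        m = (baseline["tchdl"] >= spec.tchdl_threshold) & (baseline["llm"] == 0)
    else:
        raise ValueError(f"unknown scenario id {spec.id!r}")
    return m.rename("eligible")


def _at_target(baseline: pd.DataFrame, spec: ScenarioSpec) -> pd.Series:
    """Rows already carrying the scenario's intervened values (for which
    modification is a no-op, making ``modify`` idempotent)."""
    if spec.id == "I":
        return baseline["smoking"] == "ex"
    if spec.id == "IIa":
        return baseline["sbp"] == spec.sbp_target
    if spec.id == "IIb":
        at = baseline["bplm"] == 1
        if spec.variant == "with_factor_change":
            at &= baseline["sbp"] == spec.sbp_target
        return at
    if spec.id == "IIIa":
        return baseline["tchdl"] == spec.tchdl_target
    if spec.id == "IIIb":
        at = baseline["llm"] == 1
        if spec.variant == "with_factor_change":
            at &= baseline["tchdl"] == spec.tchdl_target
        return at
    raise ValueError(f"unknown scenario id {spec.id!r}")


def modify(baseline: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Return a copy with the intervention written into the covariates.

    Only the scenario's own fields change; every other column is untouched.
    Raises if any row is outside the target population, except rows already
    at the intervened values, which pass through unchanged (so applying
    ``modify`` twice equals applying it once).
    """
    ok = eligible(baseline, spec) | _at_target(baseline, spec)
    if not ok.all():
        bad = baseline.loc[~ok, "id"].tolist()[:5]
        raise ValueError(f"records not eligible for scenario {spec.id}: ids {bad}")
    out = baseline.copy()
    if spec.id == "I":
        out["smoking"] = "ex"
    elif spec.id == "IIa":
        out["sbp"] = spec.sbp_target
    elif spec.id == "IIb":
        out["bplm"] = 1
        if spec.variant == "with_factor_change":
            out["sbp"] = spec.sbp_target
    elif spec.id == "IIIa":
        out["tchdl"] = spec.tchdl_target
    elif spec.id == "IIIb":
        out["llm"] = 1
        if spec.variant == "with_factor_change":
            out["tchdl"] = spec.tchdl_target
    return out


def treated_at_visit(visits: pd.DataFrame, spec: ScenarioSpec) -> np.ndarray:
    """Treatment indicator read off follow-up visit rows (A = 1 condition)."""
    if spec.id == "I":
        return (visits["smoking"] == "ex").to_numpy()
    if spec.id == "IIa":
        return (visits["sbp"] <= spec.sbp_target).to_numpy()
    if spec.id == "IIb":
        return (visits["bplm"] == 1).to_numpy()
    if spec.id == "IIIa":
        return (visits["tchdl"] <= spec.tchdl_target).to_numpy()
    if spec.id == "IIIb":
        return (visits["llm"] == 1).to_numpy()
    raise ValueError(f"unknown scenario id {spec.id!r}")


def derive_treatment(baseline: pd.DataFrame, followups: pd.DataFrame,
                     spec: ScenarioSpec, mode: str = "latest") -> pd.DataFrame:
    """Assign treatment status from one index visit per participant.

    Parameters
    ----------
    baseline : target-population rows (must all be eligible).
    followups : visit table for the cohort (superset of ids is fine).
    mode : ``"latest"`` uses the visit closest to the window's end (the
        default index-date rule); ``"first"`` is the sensitivity analysis.

    Returns
    -------
    DataFrame with columns ``id``, ``included`` (had a visit within the
    window), ``A`` (0/1 among included, NaN otherwise) and ``index_time``.
    """
    ok = eligible(baseline, spec)
    if not ok.all():
        raise ValueError(f"baseline rows not eligible for scenario {spec.id}")
    if mode not in ("latest", "first"):
        raise ValueError("mode must be 'latest' or 'first'")

    ids = baseline["id"].to_numpy()
    fu = followups[(followups["id"].isin(ids))
                   & (followups["visit_time"] > 0)
                   & (followups["visit_time"] <= spec.window_months)]
    if len(fu):
        fu = fu.sort_values(["id", "visit_time"], kind="mergesort")
        idx = fu.groupby("id", sort=False).tail(1) if mode == "latest" else \
            fu.groupby("id", sort=False).head(1)
        a_vals = treated_at_visit(idx, spec).astype(float)
        found = pd.DataFrame({"id": idx["id"].to_numpy(),
                              "A": a_vals,
                              "index_time": idx["visit_time"].to_numpy()})
    else:
        found = pd.DataFrame({"id": [], "A": [], "index_time": []})

    out = pd.DataFrame({"id": ids}).merge(found, on="id", how="left")
    out["included"] = out["A"].notna()
    return out[["id", "included", "A", "index_time"]]
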