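"""Approach (a): conditioning on interventions in a non-causal model.

Risk under intervention is obtained by editing the intervened covariates in
the fitted prediction model and re-predicting. This is *not* grounded in
causal theory: it implicitly treats the model coefficients as causal
effects, which holds only under restrictive assumptions (the remaining
predictors would have to form a valid adjustment set). It is implemented
because it is widely used in practice, and because its disagreement with
the weighting-based estimate is itself informative.

The overall relative risk is the arithmetic mean of the individual risk
ratios. The reported 95% band is mean +/- 1.96 SD of the individual ratios
— a descriptive spread of the per-person ratios across the target
population, documented as a convention rather than a sampling-based
confidence interval.
"""

from __future__ import annotations

import pandas as pd

from .cpm import CoxRiskModel, predict_risk_cohort
from .effects import EffectEstimate
from .scenarios import ScenarioSpec, eligible, modify

PAIR_COLUMNS = ["id", "risk_original", "risk_intervention", "individual_rr", "arc"]


def risk_pairs(models: dict[str, CoxRiskModel], baseline: pd.DataFrame,
               spec: ScenarioSpec) -> pd.DataFrame:
    """Per-person risks with and without the intervention, for the target
    population rows of ``baseline``.

    Returns columns ``id, risk_original, risk_intervention, individual_rr,
    arc`` where ``arc = risk_original - risk_intervention`` (benefit
    positive) and ``individual_rr = risk_intervention / risk_original``.
    """
    target = baseline[eligible(baseline, spec)]
    if len(target) == 0:
        raise ValueError(f"no records eligible for scenario {spec.id}")
    risk0 = predict_risk_cohort(models, target).to_numpy()
    risk1 = predict_risk_cohort(models, modify(target, spec)).to_numpy()
    return pd.DataFrame({
        "id": target["id"].to_numpy(),
        "risk_original": risk0,
        "risk_intervention": risk1,
        "individual_rr": risk1 / risk0,
        "arc": risk0 - risk1,
    })


def mean_rr(pairs: pd.DataFrame) -> EffectEstimate:
    """Average the individual risk ratios into one overall relative risk."""
    if len(pairs) == 0:
        raise ValueError("cannot average an empty set of risk pairs")
    rr = pairs["individual_rr"].to_numpy(dtype=float)
    point = float(rr.mean())
    sd = float(rr.std(ddof=1)) if rr.size > 1 else 0.0
    return EffectEstimate(
        rr=point, ci_low=point - 1.96 * sd, ci_high=point + 1.96 * sd,
        method="noncausal", n=int(rr.size),
        diagnostics={"sd_individual_rr": sd})


def write_pairs(pairs: pd.DataFrame, path: str) -> None:
    pairs[PAIR_COLUMNS].to_csv(path, index=False)
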