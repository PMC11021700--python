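"""Published case-study summary inputs.

The original analysis ran on a restricted-access New Zealand primary-care
cohort; its participant-level data cannot ship here. What can ship are the
published summary surfaces — the per-scenario current-risk quantiles, the
per-approach relative risks, and the follow-up quit counts — which the
two-stage identity ``risk_int = risk_orig * RR`` can act on directly. These
serve as worked-example inputs and as cross-checks for the pipeline's
reporting conventions.

All risks are percentages (3.89 means 3.89%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .effects import EffectEstimate

#: current (no-intervention) five-year absolute risk across each scenario's
#: target population: median and lower/upper quartiles, in percent
_CURRENT_RISK = {
    "I": (3.89, 2.30, 7.11),
    "IIa": (4.88, 2.97, 7.96),
    "IIb": (3.91, 2.47, 6.20),
    "IIIa": (3.06, 1.74, 5.69),
    "IIIb": (2.79, 1.65, 5.02),
}

#: per-approach relative risks (point, 95% interval) from the case study
_PUBLISHED_RR = {
    "noncausal": {
        "I": (0.63, 0.56, 0.70), "IIa": (0.70, 0.47, 0.94),
        "IIb": (1.12, 0.85, 1.40), "IIIa": (0.73, 0.58, 0.88),
        "IIIb": (0.71, 0.57, 0.86),
    },
    "ipw": {
        "I": (0.70, 0.20, 1.20), "IIa": (0.93, 0.54, 1.31),
        "IIb": (1.16, 0.69, 1.62), "IIIa": (0.91, 0.24, 1.53),
        "IIIb": (1.02, 0.43, 1.58),
    },
    "external": {
        "I": (0.73, 0.62, 0.85), "IIa": (0.65, 0.57, 0.75),
        "IIb": (0.73, 0.67, 0.81), "IIIa": (0.75, 0.70, 0.80),
        "IIIb": (0.75, 0.70, 0.81),
    },
}

#: among included baseline current smokers: quitters / total
QUIT_COUNTS = (2019, 18258)


def published_current_risk() -> pd.DataFrame:
    """Current-risk quantiles per scenario (percent): median, lq, uq."""
    rows = [{"scenario": sid, "median": m, "lq": lq, "uq": uq}
            for sid, (m, lq, uq) in _CURRENT_RISK.items()]
    return pd.DataFrame(rows)


def published_rr(method: str) -> dict[str, EffectEstimate]:
    """Published per-scenario relative risks for one approach."""
    try:
        table = _PUBLISHED_RR[method]
    except KeyError:
        raise KeyError(f"no published estimates for method {method!r}; "
                       f"known: {sorted(_PUBLISHED_RR)}") from None
    return {sid: EffectEstimate(rr=v[0], ci_low=v[1], ci_high=v[2],
                                method=method)
            for sid, v in table.items()}


def scaled_risk_quantiles(method: str) -> pd.DataFrame:
    """Apply the two-stage identity to the published current-risk quantiles.

    Because multiplying by a positive constant commutes with order
    statistics, the risk-under-intervention median and quartiles are the
    current-risk quantiles times the approach's relative risk. Returns
    percent-scale columns ``median, lq, uq`` per scenario.
    """
    rrs = published_rr(method)
    base = published_current_risk()
    out = base.copy()
    factors = np.array([rrs[s].rr for s in base["scenario"]])
    for col in ("median", "lq", "uq"):
        out[col] = base[col].to_numpy() * factors
    return out
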