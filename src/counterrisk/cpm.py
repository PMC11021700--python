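"""Sex-specific proportional-hazards clinical prediction model.

Fits a Cox model per sex stratum (Efron ties, via lifelines) on the baseline
table and turns it into a portable five-year absolute risk equation

    risk = 1 - S_ref(60) ** exp(beta' (x - x_ref)),

where ``S_ref(60)`` is the 60-month survival of an explicit reference
profile (covariate means for continuous predictors, modal values for
indicators). Storing the reference profile and its survival makes predicted
risks reproducible from the serialized model alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

#: default main-effects predictor specification (design-column names)
DEFAULT_PREDICTORS = [
    "age", "sbp", "tchdl", "smoking_ex", "smoking_current", "diabetes", "af",
    "family_history", "nzdep", "ethnicity_other", "bplm", "llm", "atm",
]

_DUMMY_SOURCES = {
    "smoking_ex": ("smoking", "ex"),
    "smoking_current": ("smoking", "current"),
    "ethnicity_other": ("ethnicity", "Other"),
    "sex_male": ("sex", "male"),
}


def design_matrix(df: pd.DataFrame, predictor_spec: list[str]) -> pd.DataFrame:
    """Expand a baseline table into numeric design columns.

    A term is either a raw numeric column, a known dummy name (e.g.
    ``smoking_current``), or a product ``a:b`` of two such terms.
    """
    cols = {}

    def col(term: str) -> np.ndarray:
        if term in _DUMMY_SOURCES:
            src, level = _DUMMY_SOURCES[term]
            return (df[src].to_numpy() == level).astype(float)
        if term in df.columns:
            vals = df[term]
            if not pd.api.types.is_numeric_dtype(vals):
                raise KeyError(f"predictor {term!r} is not numeric")
            return vals.to_numpy(dtype=float)
        raise KeyError(f"unknown predictor {term!r}")

    for term in predictor_spec:
        if ":" in term:
            a, b_ = term.split(":", 1)
            cols[term] = col(a) * col(b_)
        else:
            cols[term] = col(term)
    return pd.DataFrame(cols, index=df.index)


@dataclass
class CoxRiskModel:
    """One sex stratum of the prediction model."""

    sex: str
    coefficients: dict[str, float]
    baseline_survival: float          #: S_ref at ``horizon_months``
    reference_profile: dict[str, float]
    predictor_spec: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    horizon_months: int = 60

    def __post_init__(self):
        if not 0.0 < self.baseline_survival <= 1.0:
            raise ValueError("baseline survival must be in (0, 1]")
        for name, v in self.coefficients.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient for {name!r}")
        missing = set(self.coefficients) - set(self.predictor_spec)
        if missing:
            raise ValueError(f"coefficients {sorted(missing)} not in predictor_spec")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=False)

    @classmethod
    def from_json(cls, path: str) -> "CoxRiskModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in rank deficiency (dropping them restores rank)."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    bad = []
    keep = list(range(X.shape[1]))
    for j in range(X.shape[1]):
        trial = [c for c in keep if c != j]
        if np.linalg.matrix_rank(X[:, trial]) == rank:
            bad.append(names[j])
            keep = trial
            rank = np.linalg.matrix_rank(X[:, keep])
            if rank == len(keep):
                break
    return bad


def fit_cpm(baseline: pd.DataFrame, predictor_spec: list[str] | None = None,
            horizon_months: int = 60) -> dict[str, CoxRiskModel]:
    """Fit female and male proportional-hazards models on a baseline table.

    Returns ``{"female": model, "male": model}``. The event is a CVD
    hospitalisation/death (``event_type == "cvd"``); other-cause death and
    administrative end of follow-up are censoring.
    """
    spec = list(predictor_spec) if predictor_spec is not None else list(DEFAULT_PREDICTORS)
    models = {}
    for sex in ("female", "male"):
        sub = baseline[baseline["sex"] == sex]
        X = design_matrix(sub, spec)
        events = (sub["event_type"] == "cvd").astype(int)
        if events.sum() < 2:
            raise ValueError(f"stratum {sex!r} has fewer than 2 CVD events")
        bad = _collinear_columns(X.to_numpy(), spec)
        if bad:
            raise ValueError(f"singular design in stratum {sex!r}; "
                             f"collinear predictors: {bad}")
        fit_df = X.copy()
        fit_df["event_time"] = sub["event_time"].to_numpy()
        fit_df["event"] = events.to_numpy()
        cph = CoxPHFitter()
        cph.fit(fit_df, duration_col="event_time", event_col="event")

        ref = {}
        for term in spec:
            vals = X[term].to_numpy()
            uniq = np.unique(vals)
            if uniq.size <= 2:  # indicator: modal value
                ref[term] = float(np.bincount(vals.astype(int)).argmax()) if \
                    np.array_equal(uniq, uniq.astype(int)) else float(np.median(vals))
            else:
                ref[term] = float(vals.mean())
        sf = cph.predict_survival_function(pd.DataFrame([ref]))
        times = sf.index.to_numpy(dtype=float)
        at = times[times <= horizon_months]
        s_ref = float(sf.iloc[-1, 0]) if at.size == 0 else float(
            sf.loc[at[-1]].iloc[0])
        if at.size == 0:
            raise ValueError("no event times at or before the horizon")

        models[sex] = CoxRiskModel(
            sex=sex,
            coefficients={t: float(cph.params_[t]) for t in spec},
            baseline_survival=s_ref,
            reference_profile=ref,
            predictor_spec=spec,
            horizon_months=horizon_months,
        )
    return models


def predict_risk(model: CoxRiskModel, baseline: pd.DataFrame) -> np.ndarray:
    """Absolute risk at the model horizon for each row of ``baseline``.

    Rows must belong to the model's sex stratum.
    """
    if "sex" in baseline.columns and not (baseline["sex"] == model.sex).all():
        raise ValueError(f"records do not all match model stratum {model.sex!r}")
    X = design_matrix(baseline, model.predictor_spec)
    lp = np.zeros(len(baseline))
    for term, beta in model.coefficients.items():
        lp += beta * (X[term].to_numpy() - model.reference_profile[term])
    return 1.0 - model.baseline_survival ** np.exp(lp)


def predict_risk_cohort(models: dict[str, CoxRiskModel], baseline: pd.DataFrame) -> pd.Series:
    """Combine the two strata into one risk per participant (indexed like
    ``baseline``, named ``risk``)."""
    out = pd.Series(np.nan, index=baseline.index, name="risk")
    for sex, model in models.items():
        mask = baseline["sex"] == sex
        if mask.any():
            out[mask] = predict_risk(model, baseline[mask])
    return out
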