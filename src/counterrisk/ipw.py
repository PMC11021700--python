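"""Approach (b): average treatment effects by inverse probability weighting.

The estimator chains four pieces:

1. *Selection weights.* Only people who return for a follow-up visit within
   the two-year window contribute, and returners differ systematically from
   non-returners. A logistic model of inclusion on baseline covariates,
   fitted on the full target population, supplies inverse-probability-of-
   selection weights ``1 / Pr(included | X)`` for the included.

2. *Stabilised treatment weights.* ``W(A) = Pr(A) / Pr(A | L)`` for the
   treated and the complement ratio for the untreated, with ``Pr(A | L)``
   from a logistic model on the scenario's confounder set L. Linear and
   restricted-cubic-spline specifications for continuous confounders are
   both fitted and the lower-AIC one is used. The sample mean of the
   stabilised weight should sit near 1; a deviation beyond 0.05 is flagged.

3. *Censoring weights.* Loss to follow-up (other-cause death, competing
   events, administrative cut-off before the horizon) is treated as a
   time-varying "treatment": pooled logistic models of remaining uncensored
   given (A, L, X0, month) and, for the stabiliser, (A, month) give a
   cumulative stabilised weight per person-month, taken over months strictly
   before the current one (so the month-0 weight is exactly 1).

4. *Marginal structural hazard model.* A pooled logistic discrete-time
   hazard ``logit Pr(D_{k+1}=1 | D_k=0) = b0 + b1 k + b2 a + b3 a k`` fitted
   with the product of the three weights. Counterfactual survival curves are
   the products of ``1 - hazard`` over months, and the effect estimate is
   the ratio of 60-month cumulative risks, with a person-level nonparametric
   bootstrap (weights and hazard model refitted per replicate) for the
   interval.

Time is measured in months from the index visit, where treatment status is
defined. Identification rests on exchangeability given L, consistency, and
positivity; fitted treatment probabilities at the positivity boundary raise
a warning rather than being silently truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._logistic import LogitFit, fit_logistic, rcs_basis, default_knots
from .cpm import design_matrix
from .effects import EffectEstimate
from .scenarios import ScenarioSpec, derive_treatment

#: continuous baseline fields that receive spline terms in the treatment model
CONTINUOUS_TERMS = ("age", "sbp", "tchdl", "nzdep")

_COMMON_L = ["sex_male", "age", "ethnicity_other", "nzdep", "family_history",
             "diabetes", "af", "sbp", "tchdl", "atm", "llm", "bplm"]
_SMOKING = ["smoking_ex", "smoking_current"]

#: confounder set L per scenario (baseline smoking enters except for scenario
#: I, where the target population is uniformly current smokers; the
#: treatment-defining medication is excluded from its own confounder set)
CONFOUNDERS: dict[str, list[str]] = {
    "I": list(_COMMON_L),
    "IIa": _COMMON_L + _SMOKING,
    "IIb": [t for t in _COMMON_L if t != "bplm"] + _SMOKING,
    "IIIa": _COMMON_L + _SMOKING,
    "IIIb": [t for t in _COMMON_L if t != "llm"] + _SMOKING,
}

#: additional prognostic factors X0 for the censoring model
X0_TERMS: dict[str, list[str]] = {
    "I": ["diabetes", "af", "sbp", "tchdl", "bplm", "atm", "llm"],
    "IIa": ["diabetes", "af", "atm", "llm"],
    "IIb": ["diabetes", "af", "atm", "llm"],
    "IIIa": ["diabetes", "af", "atm", "bplm"],
    "IIIb": ["diabetes", "af", "bplm", "atm"],
}

#: default covariates of the return-visit selection model
SELECTION_COVARIATES = ["sex_male", "age", "ethnicity_other", "nzdep",
                        "smoking_ex", "smoking_current", "family_history",
                        "diabetes", "af", "sbp", "tchdl", "bplm", "llm", "atm"]


def _design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + design columns, with constant columns dropped (a scenario's
    eligibility can make a covariate degenerate, e.g. BPLM=0 under IIb)."""
    X = design_matrix(df, terms)
    keep = [t for t in terms if X[t].nunique() > 1]
    mat = np.column_stack([np.ones(len(df))] + [X[t].to_numpy(float) for t in keep])
    return mat, ["intercept"] + keep


@dataclass
class SelectionModel:
    coefficients: dict[str, float]
    fit: LogitFit


@dataclass
class TreatmentModel:
    intercept_marginal: float            #: logit of the marginal Pr(A=1)
    coefficients: dict[str, float]       #: chosen specification
    aic_linear: float
    aic_spline: float
    chosen: str                          #: "linear" or "spline"
    spline_knots: dict[str, np.ndarray] = field(default_factory=dict)
    fit: LogitFit | None = None


@dataclass
class CensoringModel:
    coefficients: dict[str, float]       #: pooled denominator model
    stabilizer_coefficients: dict[str, float]
    n_censoring_events: int


@dataclass
class MSMFit:
    """Pooled logistic marginal structural hazard model parameters."""
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    cov: np.ndarray | None = None

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    def __post_init__(self):
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite MSM coefficients")


@dataclass
class SurvivalCurve:
    level: int                           #: intervention level (0 or 1)
    s: np.ndarray                        #: survival at months 0..horizon

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if s[0] != 1.0 or np.any(np.diff(s) > 1e-15) or np.any(s <= 0) or np.any(s > 1):
            raise ValueError("survival curve must start at 1, be non-increasing "
                             "and stay in (0, 1]")
        self.s = s


def fit_selection_weights(baseline: pd.DataFrame, included: np.ndarray,
                          covariates: list[str] | None = None
                          ) -> tuple[SelectionModel, pd.Series]:
    """Inverse-probability-of-selection weights for the included subgroup.

    The logistic model of inclusion is fitted on every row of ``baseline``
    (the full target population); the returned Series holds ``1 / p_hat``
    indexed by id for included rows only.
    """
    included = np.asarray(included, dtype=bool)
    terms = covariates if covariates is not None else SELECTION_COVARIATES
    X, names = _design(baseline, terms)
    try:
        fit = fit_logistic(X, included.astype(float))
    except Exception as err:
        raise RuntimeError(
            "selection model failed to fit (possible separation); consider "
            f"reducing the covariate set {terms}") from err
    p = fit.predict(X)
    if np.any(p[included] < 1e-10):
        raise RuntimeError("selection probabilities numerically zero for some "
                           "included rows; reduce the covariate set")
    model = SelectionModel(dict(zip(names, fit.coef)), fit)
    w = pd.Series(1.0 / p[included], index=baseline.loc[included, "id"].to_numpy(),
                  name="selection_weight")
    return model, w


def _treatment_designs(df: pd.DataFrame, confounders: list[str]):
    X_lin, names_lin = _design(df, confounders)
    spline_cols, knots_map = [], {}
    present = set(names_lin)
    for term in CONTINUOUS_TERMS:
        if term in present:
            knots = default_knots(df[term].to_numpy(float))
            if knots.size >= 3:
                spline_cols.append(rcs_basis(df[term].to_numpy(float), knots))
                knots_map[term] = knots
    X_spl = np.column_stack([X_lin] + spline_cols) if spline_cols else X_lin
    return X_lin, names_lin, X_spl, knots_map


def fit_treatment_weights(included: pd.DataFrame, A: np.ndarray,
                          confounders: list[str]
                          ) -> tuple[TreatmentModel, np.ndarray]:
    """Stabilised treatment weights for the included, index-dated sample.

    Both a linear and a restricted-cubic-spline (4 knots at the 5/35/65/95th
    percentiles) specification of ``Pr(A=1 | L)`` are fitted; the lower-AIC
    one supplies the conditional probabilities. With an empty confounder set
    every weight is exactly 1.
    """
    A = np.asarray(A, dtype=float)
    if not (0 < A.sum() < A.size):
        raise ValueError("both treatment groups must be non-empty")
    p_marg = A.mean()

    if not confounders:
        model = TreatmentModel(intercept_marginal=float(np.log(p_marg / (1 - p_marg))),
                               coefficients={}, aic_linear=np.nan,
                               aic_spline=np.nan, chosen="linear")
        return model, np.ones(A.size)

    X_lin, names_lin, X_spl, knots_map = _treatment_designs(included, confounders)
    fit_lin = fit_logistic(X_lin, A)
    fit_spl = fit_logistic(X_spl, A) if X_spl.shape[1] > X_lin.shape[1] else fit_lin
    chosen = "linear" if fit_lin.aic <= fit_spl.aic else "spline"
    fit = fit_lin if chosen == "linear" else fit_spl
    X = X_lin if chosen == "linear" else X_spl

    p_cond = fit.predict(X)
    n_lo = int((p_cond <= 1e-6).sum())
    n_hi = int((p_cond >= 1 - 1e-6).sum())
    if n_lo or n_hi:
        warnings.warn(
            f"positivity violation: {n_lo} fitted treatment probabilities "
            f"<= 1e-6 and {n_hi} >= 1-1e-6", RuntimeWarning, stacklevel=2)

    sw = np.where(A == 1, p_marg / p_cond, (1 - p_marg) / (1 - p_cond))
    if abs(sw.mean() - 1.0) > 0.05:
        warnings.warn(f"mean stabilised treatment weight {sw.mean():.3f} "
                      f"deviates from 1 by more than 0.05", RuntimeWarning,
                      stacklevel=2)
    model = TreatmentModel(
        intercept_marginal=float(np.log(p_marg / (1 - p_marg))),
        coefficients=dict(zip(names_lin, fit_lin.coef)) if chosen == "linear"
        else {f"c{i}": float(v) for i, v in enumerate(fit.coef)},
        aic_linear=fit_lin.aic, aic_spline=fit_spl.aic, chosen=chosen,
        spline_knots=knots_map, fit=fit)
    return model, sw


def expand_person_months(included: pd.DataFrame, horizon: int = 60) -> pd.DataFrame:
    """One row per person-month from the index visit.

    ``included`` needs ``id, A, index_time, event_time, event_type``; the
    time origin is the index visit, so a person contributes
    ``ceil(min(event_time - index_time, horizon))`` rows. ``D = 1`` only in
    the month of a CVD event; ``C = 1`` in the month follow-up is lost
    (other-cause death or administrative cut-off), which is also the last
    row. Persons whose event precedes the index visit are rejected.
    """
    t_rem = (included["event_time"] - included["index_time"]).to_numpy(float)
    if np.any(t_rem < 0):
        raise ValueError("negative time from index to event")
    if np.any(t_rem == 0):
        raise ValueError("event at the index visit; exclude such rows upstream")
    is_cvd = (included["event_type"] == "cvd").to_numpy()

    n_rows = np.ceil(np.minimum(t_rem, horizon)).astype(int)
    terminal_in_horizon = t_rem <= horizon
    ids = np.repeat(included["id"].to_numpy(), n_rows)
    A = np.repeat(included["A"].to_numpy(float), n_rows)
    offsets = np.concatenate([[0], np.cumsum(n_rows)])
    k = np.arange(offsets[-1]) - np.repeat(offsets[:-1], n_rows)
    D = np.zeros(offsets[-1], dtype=np.int64)
    C = np.zeros(offsets[-1], dtype=np.int64)
    last = offsets[1:] - 1
    D[last[terminal_in_horizon & is_cvd]] = 1
    C[last[terminal_in_horizon & ~is_cvd]] = 1
    return pd.DataFrame({"id": ids, "k": k, "A": A, "D": D, "C": C})


def _cum_exclusive_product(values: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Per-group exclusive cumulative product over contiguous groups."""
    lv = np.log(values)
    cs = np.cumsum(lv)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    before_group = cs[starts] - lv[starts]
    inclusive = cs - np.repeat(before_group, lengths)
    out = np.exp(inclusive - lv)
    out[starts] = 1.0   # exclusive product over an empty set, exactly
    return out


def fit_censoring_weights(pm: pd.DataFrame, covariates: pd.DataFrame,
                          terms: list[str]
                          ) -> tuple[CensoringModel, np.ndarray]:
    """Cumulative stabilised censoring weights per person-month row.

    ``covariates`` holds one baseline row per included person, aligned with
    the person order of ``pm`` (its ``id`` order); ``terms`` is the union of
    the confounder set L and the prognostic set X0. With no censoring events
    every weight is exactly 1.
    """
    C = pm["C"].to_numpy()
    lengths = pm.groupby("id", sort=False).size().to_numpy()
    if C.sum() == 0:
        model = CensoringModel({}, {}, 0)
        return model, np.ones(len(pm))

    Xp, names = _design(covariates, terms)
    rep = np.repeat(np.arange(len(covariates)), lengths)
    k = pm["k"].to_numpy(float)
    A = pm["A"].to_numpy(float)
    y = 1.0 - C

    X_den = np.column_stack([Xp[rep], A, k])
    fit_den = fit_logistic(X_den, y)
    p_den = fit_den.predict(X_den)

    # stabiliser on (A, k): collapse rows into (A, k) cells, exact for ML
    cell = (k.astype(int) * 2 + A.astype(int))
    n_cell = np.bincount(cell)
    y_cell = np.bincount(cell, weights=y)
    live = n_cell > 0
    kk = np.arange(n_cell.size) // 2
    aa = np.arange(n_cell.size) % 2
    X_num_cells = np.column_stack([np.ones(live.sum()), aa[live], kk[live]])
    fit_num = fit_logistic(X_num_cells, (y_cell[live] / n_cell[live]),
                           weights=n_cell[live].astype(float))
    p_num = fit_num.predict(np.column_stack([np.ones(len(pm)), A, k]))

    sw = _cum_exclusive_product(p_num / p_den, lengths)
    model = CensoringModel(
        coefficients=dict(zip(names + ["A", "k"], fit_den.coef)),
        stabilizer_coefficients=dict(zip(["intercept", "A", "k"], fit_num.coef)),
        n_censoring_events=int(C.sum()))
    return model, sw


def fit_msm(pm: pd.DataFrame, weights: np.ndarray) -> MSMFit:
    """Weighted pooled logistic fit of the marginal structural hazard model.

    Rows with ``C = 1`` (the month follow-up is lost) are excluded from the
    outcome likelihood. Rows are collapsed over (month, level) cells with
    summed weights, which leaves the weighted ML estimate unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    use = pm["C"].to_numpy() == 0
    k = pm["k"].to_numpy()[use]
    A = pm["A"].to_numpy()[use].astype(int)
    D = pm["D"].to_numpy()[use]
    w = w[use]

    cell = k * 2 + A
    sw_ = np.bincount(cell, weights=w)
    swd = np.bincount(cell, weights=w * D)
    live = sw_ > 0
    kk = (np.arange(sw_.size) // 2)[live].astype(float)
    aa = (np.arange(sw_.size) % 2)[live].astype(float)
    X = np.column_stack([np.ones(live.sum()), kk, aa, kk * aa])
    try:
        fit = fit_logistic(X, swd[live] / sw_[live], weights=sw_[live],
                           compute_cov=True)
    except Exception as err:
        raise RuntimeError(f"marginal structural model did not converge: {err}") from err
    b = fit.coef
    return MSMFit(beta0=float(b[0]), beta1=float(b[1]), beta2=float(b[2]),
                  beta3=float(b[3]), cov=fit.cov)


def marginal_survival(fit: MSMFit, level: int, horizon: int = 60) -> SurvivalCurve:
    """Counterfactual survival by multiplying ``1 - hazard`` over months."""
    k = np.arange(horizon, dtype=float)
    hazard = expit(fit.beta0 + fit.beta1 * k + fit.beta2 * level + fit.beta3 * level * k)
    s = np.concatenate([[1.0], np.cumprod(1.0 - hazard)])
    return SurvivalCurve(level=level, s=s)


def rr_at_horizon(fit: MSMFit, horizon: int = 60) -> EffectEstimate:
    """Point estimate of the cumulative risk ratio at the horizon.

    Interval estimation requires the data (person-level bootstrap); use
    :func:`estimate_ipw_rr` for an effect with a confidence interval.
    """
    risk1 = 1.0 - marginal_survival(fit, 1, horizon).s[-1]
    risk0 = 1.0 - marginal_survival(fit, 0, horizon).s[-1]
    if risk0 <= 0:
        raise ZeroDivisionError("untreated cumulative risk is zero")
    return EffectEstimate(rr=risk1 / risk0, ci_low=np.nan, ci_high=np.nan,
                          method="ipw")


# ---------------------------------------------------------------------------
# full pipeline with person-level bootstrap


@dataclass
class IPWResult:
    effect: EffectEstimate
    msm: MSMFit
    curves: dict[int, SurvivalCurve]
    treatment_model: TreatmentModel
    selection_model: SelectionModel
    censoring_model: CensoringModel
    weights: pd.DataFrame                 #: per included person: the three weights
    diagnostics: dict


class _PipelineData:
    """Pre-built numpy arrays for the eligible cohort, so bootstrap
    replicates are pure index-gather plus warm-started Newton fits."""

    def __init__(self, elig: pd.DataFrame, assign: pd.DataFrame,
                 spec: ScenarioSpec, confounders, x0_terms, selection_covariates,
                 horizon: int):
        self.horizon = horizon
        merged = elig.merge(assign, on="id")
        # drop included persons whose event precedes (or meets) the index visit
        bad = merged["included"] & (merged["event_time"] <= merged["index_time"])
        self.n_dropped_pre_index = int(bad.sum())
        merged = merged[~bad].reset_index(drop=True)
        self.elig = merged
        self.X_sel, self.sel_names = _design(merged, selection_covariates)
        self.included = merged["included"].to_numpy()
        self.inc = merged[self.included].reset_index(drop=True)
        self.pos_in_inc = np.full(len(merged), -1)
        self.pos_in_inc[np.flatnonzero(self.included)] = np.arange(len(self.inc))
        self.A = self.inc["A"].to_numpy(float)
        self.confounders = confounders
        (self.Xt_lin, self.t_names, self.Xt_spl, self.t_knots) = \
            _treatment_designs(self.inc, confounders)
        self.pm = expand_person_months(self.inc, horizon)
        self.lengths = np.ceil(np.minimum(
            (self.inc["event_time"] - self.inc["index_time"]).to_numpy(float),
            horizon)).astype(int)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.k = self.pm["k"].to_numpy(float)
        self.D = self.pm["D"].to_numpy(float)
        self.C = self.pm["C"].to_numpy(float)
        cterms = list(dict.fromkeys(list(confounders) + list(x0_terms)))
        self.Xc_person, self.c_names = _design(self.inc, cterms)
        # person-month censoring design, built once; bootstrap gathers rows
        rep = np.repeat(np.arange(len(self.inc)), self.lengths)
        self.A_rows = self.A[rep]
        self.X_den = np.column_stack([self.Xc_person[rep], self.A_rows, self.k])
        self.X_den32 = self.X_den.astype(np.float32)
        self.cell = self.k.astype(np.int64) * 2 + self.A_rows.astype(np.int64)
        self.truncate_percentiles: tuple[float, float] | None = None


def _gather_rows(data: _PipelineData, persons: np.ndarray):
    """Row indices of the person-month blocks for ``persons`` (with repeats)."""
    lens = data.lengths[persons]
    tot = int(lens.sum())
    starts = data.offsets[persons]
    within = np.arange(tot) - np.repeat(np.concatenate([[0], np.cumsum(lens)[:-1]]), lens)
    return np.repeat(starts, lens) + within, lens


def _pipeline_once(data: _PipelineData, elig_idx: np.ndarray,
                   chosen: str, warm: dict, tol: float = 1e-9,
                   fast: bool = False) -> tuple[float, dict] | None:
    """One pass of the full estimator on a (re)sampled eligible cohort.

    Returns (rr, weight summaries) or None when the replicate is degenerate
    (an empty arm or no events in an arm).
    """
    inc_mask = data.included[elig_idx]
    y = inc_mask.astype(float)
    if not (0 < y.sum() < y.size):
        return None
    fit_sel = fit_logistic(data.X_sel[elig_idx], y, start=warm.get("sel"), tol=tol,
                           line_search=not fast)
    warm.setdefault("sel", fit_sel.coef)
    p_sel = fit_sel.predict(data.X_sel[elig_idx][inc_mask])
    sel_w = 1.0 / np.clip(p_sel, 1e-10, None)

    persons = data.pos_in_inc[elig_idx[inc_mask]]
    A = data.A[persons]
    if not (0 < A.sum() < A.size):
        return None
    Xt = data.Xt_lin if chosen == "linear" else data.Xt_spl
    fit_trt = fit_logistic(Xt[persons], A, start=warm.get("trt"), tol=tol,
                           line_search=not fast)
    warm.setdefault("trt", fit_trt.coef)
    p_marg = A.mean()
    p_cond = np.clip(fit_trt.predict(Xt[persons]), 1e-10, 1 - 1e-10)
    sw_t = np.where(A == 1, p_marg / p_cond, (1 - p_marg) / (1 - p_cond))

    rows, lens = _gather_rows(data, persons)
    k, D, C = data.k[rows], data.D[rows], data.C[rows]
    A_rows = data.A_rows[rows]
    if C.sum() > 0:
        X_den = data.X_den32[rows] if fast else data.X_den[rows]
        fit_den = fit_logistic(X_den, 1.0 - C, start=warm.get("cden"), tol=tol,
                               line_search=not fast)
        warm.setdefault("cden", fit_den.coef)
        p_den = np.clip(fit_den.predict(X_den), 1e-10, None)
        cell = data.cell[rows]
        n_cell = np.bincount(cell)
        y_cell = np.bincount(cell, weights=1.0 - C)
        live = n_cell > 0
        kk = np.arange(n_cell.size) // 2
        aa = np.arange(n_cell.size) % 2
        fit_num = fit_logistic(
            np.column_stack([np.ones(int(live.sum())), aa[live], kk[live]]),
            y_cell[live] / n_cell[live], weights=n_cell[live].astype(float),
            start=warm.get("cnum"), tol=tol, line_search=not fast)
        warm.setdefault("cnum", fit_num.coef)
        cnum = fit_num.coef
        p_num = expit(cnum[0] + cnum[1] * A_rows + cnum[2] * k)
        sw_c = _cum_exclusive_product(p_num / p_den, lens)
    else:
        sw_c = np.ones(k.size)

    combined = np.repeat(sel_w * sw_t, lens) * sw_c
    if data.truncate_percentiles is not None:
        lo, hi = np.percentile(combined, data.truncate_percentiles)
        combined = np.clip(combined, lo, hi)
    use = C == 0
    cell = (k[use].astype(int) * 2 + A_rows[use].astype(int))
    sw_ = np.bincount(cell, weights=combined[use], minlength=2 * data.horizon)
    swd = np.bincount(cell, weights=combined[use] * D[use], minlength=2 * data.horizon)
    live = sw_ > 0
    # degenerate replicate: an arm with no events cannot identify the RR
    if swd[live][(np.arange(sw_.size) % 2)[live] == 1].sum() <= 0 or \
       swd[live][(np.arange(sw_.size) % 2)[live] == 0].sum() <= 0:
        return None
    kk = (np.arange(sw_.size) // 2)[live].astype(float)
    aa = (np.arange(sw_.size) % 2)[live].astype(float)
    X = np.column_stack([np.ones(int(live.sum())), kk, aa, kk * aa])
    fit = fit_logistic(X, swd[live] / sw_[live], weights=sw_[live],
                       start=warm.get("msm"), tol=min(tol, 1e-8))
    warm.setdefault("msm", fit.coef)
    msm = MSMFit(*[float(v) for v in fit.coef])
    risk1 = 1.0 - marginal_survival(msm, 1, data.horizon).s[-1]
    risk0 = 1.0 - marginal_survival(msm, 0, data.horizon).s[-1]
    if risk0 <= 0:
        return None
    summaries = {
        "sel_w": sel_w, "sw_t": sw_t, "sw_c": sw_c, "persons": persons,
        "msm": msm, "risk1": risk1, "risk0": risk0,
    }
    return risk1 / risk0, summaries


def estimate_ipw_rr(baseline: pd.DataFrame, followups: pd.DataFrame,
                    spec: ScenarioSpec, mode: str = "latest",
                    confounders: list[str] | None = None,
                    x0_terms: list[str] | None = None,
                    selection_covariates: list[str] | None = None,
                    horizon: int = 60, n_boot: int = 200, seed: int = 0,
                    truncate_percentiles: tuple[float, float] | None = None
                    ) -> IPWResult:
    """Run the full IPW estimator for one scenario and bootstrap its interval.

    ``baseline``/``followups`` are cohort tables (the eligible subset is
    taken internally). ``truncate_percentiles`` optionally truncates the
    combined weights (off by default so positivity problems stay visible).
    The bootstrap resamples eligible persons with replacement and refits the
    selection, treatment, censoring and hazard models per replicate; the
    interval is the 2.5/97.5 percentile of the replicate risk ratios.
    """
    from .scenarios import eligible as _eligible

    elig = baseline[_eligible(baseline, spec)].reset_index(drop=True)
    if len(elig) == 0:
        raise ValueError(f"no eligible records for scenario {spec.id}")
    assign = derive_treatment(elig, followups, spec, mode=mode)
    conf = confounders if confounders is not None else CONFOUNDERS[spec.id]
    x0 = x0_terms if x0_terms is not None else X0_TERMS[spec.id]
    selcov = selection_covariates if selection_covariates is not None \
        else SELECTION_COVARIATES
    data = _PipelineData(elig, assign, spec, conf, x0, selcov, horizon)
    data.truncate_percentiles = truncate_percentiles

    # model selection (AIC, linear vs spline) happens once, on the full sample
    tmodel, sw_t_full = fit_treatment_weights(data.inc, data.A, conf)
    chosen = tmodel.chosen

    warm: dict = {}
    full_idx = np.arange(len(data.elig))
    out = _pipeline_once(data, full_idx, chosen, warm)
    if out is None:
        raise RuntimeError("estimator degenerate on the full sample "
                           "(empty arm or no events in an arm)")
    rr, summ = out

    rng = np.random.default_rng(seed)
    boots = []
    n_skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(data.elig), len(data.elig))
        res = _pipeline_once(data, idx, chosen, dict(warm), tol=1e-3, fast=True)
        if res is None:
            n_skipped += 1
        else:
            boots.append(res[0])
    if boots:
        ci_low, ci_high = np.quantile(boots, [0.025, 0.975])
        ci_low, ci_high = float(min(ci_low, rr)), float(max(ci_high, rr))
    else:
        ci_low = ci_high = np.nan

    msm = summ["msm"]
    sel_model, sel_w = fit_selection_weights(data.elig, data.included, selcov)
    cmodel, sw_c = fit_censoring_weights(
        data.pm, data.inc, list(dict.fromkeys(list(conf) + list(x0))))
    weights = pd.DataFrame({
        "id": data.inc["id"].to_numpy(),
        "selection_weight": sel_w.to_numpy(),
        "sw_treatment": sw_t_full,
        "sw_censor_final": sw_c[data.offsets[1:] - 1],
    })
    diag = {
        "n_eligible": int(len(data.elig)),
        "n_included": int(len(data.inc)),
        "n_treated": int(data.A.sum()),
        "n_dropped_pre_index": data.n_dropped_pre_index,
        "mean_sw_treatment": float(sw_t_full.mean()),
        "max_sw_treatment": float(sw_t_full.max()),
        "aic_linear": float(tmodel.aic_linear),
        "aic_spline": float(tmodel.aic_spline),
        "chosen_treatment_model": chosen,
        "n_boot_skipped": n_skipped,
        "risk_treated_60m": summ["risk1"],
        "risk_untreated_60m": summ["risk0"],
    }
    effect = EffectEstimate(rr=float(rr), ci_low=ci_low, ci_high=ci_high,
                            method="ipw", n=int(len(data.inc)), diagnostics=diag)
    return IPWResult(effect=effect, msm=msm,
                     curves={a: marginal_survival(msm, a, horizon) for a in (0, 1)},
                     treatment_model=tmodel, selection_model=sel_model,
                     censoring_model=cmodel, weights=weights, diagnostics=diag)


def write_ipw_result(result: IPWResult, out_dir: str, prefix: str = "ipw") -> dict:
    """Write an :class:`IPWResult` as machine-readable files.

    ``<prefix>_effect.json`` (effect estimate + diagnostics),
    ``<prefix>_weights.csv`` (per-person selection/treatment/censoring
    weights) and ``<prefix>_survival.csv`` (counterfactual survival curves
    by month and intervention level). Returns the paths written.
    """
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    paths["effect"] = os.path.join(out_dir, f"{prefix}_effect.json")
    with open(paths["effect"], "w") as fh:
        json.dump(result.effect.to_dict(), fh, indent=2, default=float)
    paths["weights"] = os.path.join(out_dir, f"{prefix}_weights.csv")
    result.weights.to_csv(paths["weights"], index=False)
    paths["survival"] = os.path.join(out_dir, f"{prefix}_survival.csv")
    frames = []
    for level, curve in sorted(result.curves.items()):
        frames.append(pd.DataFrame({"level": level,
                                    "month": np.arange(curve.s.size),
                                    "survival": curve.s}))
    pd.concat(frames, ignore_index=True).to_csv(paths["survival"], index=False)
    return paths
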