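"""Synthetic primary-care CVD cohorts with known intervention effects.

The generator emulates the statistical structure that the three
risk-under-intervention approaches rely on:

* baseline risk-factor marginals calibrated to a large New Zealand
  primary-care risk-assessment cohort (~15% current smokers, SBP 130 (15)
  mmHg, TC/HDL 4.1 (1.2), ~3% five-year CVD incidence, ~24% returning for a
  follow-up visit within two years);
* covariate-dependent return-to-follow-up (so the included subgroup differs
  from the excluded one, e.g. diabetes prevalence is much higher among
  returners);
* confounded treatment uptake at follow-up (quitting smoking, lowering blood
  pressure, starting medication) driven by deprivation, diabetes and age;
* proportional-hazards time-to-CVD outcomes in which the intervention
  multiplies the hazard from the first follow-up visit onward by a factor
  chosen, by numeric root finding, so the five-year risk ratio equals a
  configured true value.

Correlation between covariates is induced by a single shared latent factor
(only marginals are calibrated). All randomness flows from one seed; a given
config reproduces a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import validate_baseline, validate_followups

SCENARIO_IDS = ("I", "IIa", "IIb", "IIIa", "IIIb")


@dataclass
class CovariateParams:
    """Marginal distributions (and latent-factor loadings) of baseline fields."""

    age_mean: float = 53.0
    age_sd: float = 9.8
    age_min: float = 30.0
    age_max: float = 74.0
    male_prop: float = 0.56
    european_prop: float = 0.54
    nzdep_mean: float = 3.0
    nzdep_sd: float = 1.5
    smoking_current: float = 0.15
    smoking_ex: float = 0.17
    family_history: float = 0.10
    diabetes: float = 0.11
    af: float = 0.013
    sbp_mean: float = 130.0
    sbp_sd: float = 15.0
    tchdl_mean: float = 4.1
    tchdl_sd: float = 1.2
    bplm: float = 0.233
    llm: float = 0.166
    atm: float = 0.10
    #: loading of the shared latent factor on the deprivation cluster
    latent_rho: float = 0.35
    #: slope of the current-smoker probability per SD of deprivation
    dep_smoking_shift: float = 0.06


@dataclass
class OutcomeParams:
    """Five-year risk targets and log-hazard coefficients (per SD for
    continuous covariates, per level for indicators)."""

    five_year_risk_female: float = 0.025
    five_year_risk_male: float = 0.035
    b_age: float = 0.60
    b_sbp: float = 0.25
    b_tchdl: float = 0.22
    b_smoking_current: float = 0.65
    #: used for scenarios other than I; under scenario I the ex-smoker
    #: coefficient is tied to the quit effect (current + log hazard ratio)
    b_smoking_ex: float = 0.18
    b_diabetes: float = 0.50
    b_af: float = 0.70
    b_family_history: float = 0.25
    b_nzdep: float = 0.20
    b_ethnicity_other: float = 0.15
    b_bplm: float = 0.15
    b_llm: float = 0.05
    b_atm: float = 0.10
    #: other-cause death: five-year probability and its deprivation loading
    death_rate_5yr: float = 0.018
    death_covariate_coef: float = 0.0


@dataclass
class SelectionParams:
    """Log-odds coefficients of the return-visit (selection) model."""

    strength: float = 1.0
    diabetes: float = 1.8
    bplm: float = 0.5
    llm: float = 0.4
    atm: float = 0.3
    age: float = 0.15
    smoking_current: float = 0.2
    smoking_ex: float = 0.1
    tchdl: float = 0.1


def _default_true_rr() -> dict:
    return {"I": 0.73, "IIa": 0.65, "IIb": 0.73, "IIIa": 0.75, "IIIb": 0.75}


def _default_uptake() -> dict:
    return {"I": 0.11, "IIa": 0.20, "IIb": 0.25, "IIIa": 0.15, "IIIb": 0.20}


@dataclass
class GeneratorConfig:
    n_participants: int = 10_000
    seed: int = 0
    #: the scenario whose intervention is embedded in the outcome process
    scenario: str = "I"
    true_rr_by_scenario: dict = field(default_factory=_default_true_rr)
    #: log-odds of uptake per unit of the (deprivation/diabetes/age)
    #: confounder score; 0 switches confounding off
    confounding_strength: float = 0.6
    #: composition of the uptake confounder score (deprivation z, centred
    #: diabetes indicator, age z); override to restrict the confounder set
    confounder_weights: dict = field(
        default_factory=lambda: {"nzdep": 1.0, "diabetes": 1.0, "age": 0.5})
    followup_prob_base: float = 0.243
    uptake_prob_base: dict = field(default_factory=_default_uptake)
    horizon_months: int = 60
    admin_censor_months: int = 84
    window_months: int = 24
    max_visits: int = 3
    covariates: CovariateParams = field(default_factory=CovariateParams)
    outcome: OutcomeParams = field(default_factory=OutcomeParams)
    selection: SelectionParams = field(default_factory=SelectionParams)

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.scenario not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for sid, rr in self.true_rr_by_scenario.items():
            if rr <= 0:
                raise ValueError(f"true RR for scenario {sid} must be > 0")
        for name, p in [
            ("followup_prob_base", self.followup_prob_base),
            *[(f"uptake_prob_base[{k}]", v) for k, v in self.uptake_prob_base.items()],
            ("smoking_current", self.covariates.smoking_current),
            ("smoking_ex", self.covariates.smoking_ex),
            ("diabetes", self.covariates.diabetes),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if self.horizon_months < 1 or self.admin_censor_months < 1:
            raise ValueError("time horizons must be positive")


class Cohort(NamedTuple):
    baseline: pd.DataFrame
    followups: pd.DataFrame
    #: generator-side ground truth: embedded hazard ratio, target RR, etc.
    truth: dict


def config_from_yaml(path: str) -> GeneratorConfig:
    """Load a :class:`GeneratorConfig` from a YAML mapping; nested sections
    ``covariates``/``outcome``/``selection`` override individual fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key, cls in [("covariates", CovariateParams), ("outcome", OutcomeParams),
                     ("selection", SelectionParams)]:
        if key in kwargs:
            kwargs[key] = cls(**kwargs[key])
    return GeneratorConfig(**kwargs)


def config_to_yaml(config: GeneratorConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def _solve_intercept(score: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + score)) == target (exact calibration)."""
    if target <= 0.0 or target >= 1.0:
        raise ValueError("target probability must be in (0, 1)")
    f = lambda c: float(np.mean(expit(c + score))) - target
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _solve_log_h0(lp: np.ndarray, horizon: float, target_risk: float) -> float:
    """log h0 with mean five-year risk == target under exponential hazards."""
    f = lambda lh: float(np.mean(-np.expm1(-horizon * np.exp(lh + lp)))) - target_risk
    return brentq(f, -25.0, 5.0, xtol=1e-12)


def _solve_log_hr(h: np.ndarray, horizon: float, true_rr: float) -> float:
    """log hazard ratio reproducing the target from-index five-year risk ratio.

    ``h`` are the monthly hazards of the population over which the marginal
    (treat-everyone vs treat-no-one) contrast is defined.
    """
    base = float(np.mean(-np.expm1(-horizon * h)))

    def f(lhr):
        return float(np.mean(-np.expm1(-horizon * h * np.exp(lhr)))) / base - true_rr

    return brentq(f, -6.0, 4.0, xtol=1e-12)


def _eligible_mask(b: dict, scenario: str) -> np.ndarray:
    if scenario == "I":
        return b["smoking"] == "current"
    if scenario == "IIa":
        return b["sbp"] >= 140.0
    if scenario == "IIb":
        return (b["sbp"] >= 140.0) & (b["bplm"] == 0)
    if scenario == "IIIa":
        return b["tchdl"] >= 5.0
    if scenario == "IIIb":
        return (b["tchdl"] >= 5.0) & (b["llm"] == 0)
    raise ValueError(scenario)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate baseline and follow-up tables with embedded ground truth.

    Deterministic given ``config.seed``. See the module docstring for the
    data-generating process; ``Cohort.truth`` records the root-found hazard
    ratio, the target risk ratio, and bookkeeping counts.
    """
    cv, oc, sel = config.covariates, config.outcome, config.selection
    n = config.n_participants
    rng = np.random.default_rng(config.seed)
    horizon = float(config.horizon_months)

    # --- baseline covariates (shared latent factor U drives correlation) ---
    U = rng.standard_normal(n)
    male = rng.random(n) < cv.male_prop
    a, bnd = (cv.age_min - cv.age_mean) / cv.age_sd, (cv.age_max - cv.age_mean) / cv.age_sd
    age = truncnorm.rvs(a, bnd, loc=cv.age_mean, scale=cv.age_sd, size=n, random_state=rng)
    zage = (age - cv.age_mean) / cv.age_sd

    rho = cv.latent_rho
    dep_latent = rho * U + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    nzdep = np.clip(np.rint(cv.nzdep_mean + cv.nzdep_sd * dep_latent), 1, 5).astype(int)
    zdep = (nzdep - cv.nzdep_mean) / cv.nzdep_sd

    p_cur = np.clip(cv.smoking_current + cv.dep_smoking_shift * zdep, 0.01, 0.60)
    u = rng.random(n)
    smoking = np.where(u < p_cur, "current", np.where(u < p_cur + cv.smoking_ex, "ex", "never"))
    cur = (smoking == "current").astype(float)
    ex = (smoking == "ex").astype(float)

    family_history = (rng.random(n) < cv.family_history).astype(int)
    s_diab = 0.5 * U + 0.35 * zage
    diabetes = (rng.random(n) < expit(_solve_intercept(s_diab, cv.diabetes) + s_diab)).astype(int)
    s_af = 0.8 * zage
    af = (rng.random(n) < expit(_solve_intercept(s_af, cv.af) + s_af)).astype(int)

    sbp = cv.sbp_mean + cv.sbp_sd * (
        0.30 * zage + 0.20 * U + np.sqrt(1 - 0.30**2 - 0.20**2) * rng.standard_normal(n))
    sbp = np.clip(sbp, 70.0, None)
    tchdl = cv.tchdl_mean + cv.tchdl_sd * (
        0.20 * zage + 0.25 * U + np.sqrt(1 - 0.20**2 - 0.25**2) * rng.standard_normal(n))
    tchdl = np.clip(tchdl, 0.5, None)
    zsbp = (sbp - cv.sbp_mean) / cv.sbp_sd
    ztchdl = (tchdl - cv.tchdl_mean) / cv.tchdl_sd

    s_bplm = 0.5 * zage + 0.4 * zsbp + 0.9 * diabetes + 0.2 * U
    bplm = (rng.random(n) < expit(_solve_intercept(s_bplm, cv.bplm) + s_bplm)).astype(int)
    s_llm = 0.4 * zage + 0.4 * ztchdl + 1.1 * diabetes + 0.2 * U
    llm = (rng.random(n) < expit(_solve_intercept(s_llm, cv.llm) + s_llm)).astype(int)
    s_atm = 0.5 * zage + 0.8 * diabetes + 0.2 * U
    atm = (rng.random(n) < expit(_solve_intercept(s_atm, cv.atm) + s_atm)).astype(int)
    s_eur = -0.3 * U
    european = rng.random(n) < expit(_solve_intercept(s_eur, cv.european_prop) + s_eur)
    ethnicity = np.where(european, "European", "Other")
    other = (~european).astype(float)

    # --- return-to-follow-up selection and visit schedule ---
    s_sel = sel.strength * (
        sel.diabetes * diabetes + sel.bplm * bplm + sel.llm * llm + sel.atm * atm
        + sel.age * zage + sel.smoking_current * cur + sel.smoking_ex * ex
        + sel.tchdl * ztchdl)
    returner = rng.random(n) < expit(_solve_intercept(s_sel, config.followup_prob_base) + s_sel)

    n_visits = np.zeros(n, dtype=int)
    n_visits[returner] = np.minimum(1 + rng.poisson(1.0, returner.sum()), config.max_visits)
    vid = np.repeat(np.arange(n), n_visits)
    vt = rng.uniform(0.0, config.window_months, size=vid.size)
    order = np.lexsort((vt, vid))
    vid, vt = vid[order], vt[order]
    first_visit = np.full(n, np.inf)
    # lexsorted, so the first row of each id block is its earliest visit
    first_idx = np.unique(vid, return_index=True)
    first_visit[first_idx[0]] = vt[first_idx[1]]

    # --- treatment uptake among eligible returners (confounded) ---
    b = {"smoking": smoking, "sbp": sbp, "tchdl": tchdl, "bplm": bplm, "llm": llm}
    eligible = _eligible_mask(b, config.scenario)
    cw = config.confounder_weights
    conf_score = (cw.get("nzdep", 0.0) * zdep
                  + cw.get("diabetes", 0.0) * (diabetes - cv.diabetes)
                  + cw.get("age", 0.0) * zage)
    pool = eligible & returner
    uptake = np.zeros(n, dtype=bool)
    if pool.sum() > 0:
        s_up = config.confounding_strength * conf_score[pool]
        p_up = expit(_solve_intercept(s_up, config.uptake_prob_base[config.scenario]) + s_up)
        uptake[pool] = rng.random(pool.sum()) < p_up

    # --- outcome hazards; root-find the embedded effect -------------------
    true_rr = config.true_rr_by_scenario[config.scenario]
    base_lp = (oc.b_age * zage + oc.b_sbp * zsbp + oc.b_tchdl * ztchdl
               + oc.b_diabetes * diabetes + oc.b_af * af
               + oc.b_family_history * family_history + oc.b_nzdep * zdep
               + oc.b_ethnicity_other * other + oc.b_bplm * bplm
               + oc.b_llm * llm + oc.b_atm * atm)

    log_hr = np.log(true_rr)
    for _ in range(4):
        b_ex_eff = oc.b_smoking_current + log_hr if config.scenario == "I" else oc.b_smoking_ex
        lp = base_lp + oc.b_smoking_current * cur + b_ex_eff * ex
        h = np.empty(n)
        for is_male, target in [(True, oc.five_year_risk_male),
                                (False, oc.five_year_risk_female)]:
            m = male == is_male
            h[m] = np.exp(_solve_log_h0(lp[m], horizon, target) + lp[m])
        new_log_hr = _solve_log_hr(h[pool], horizon, true_rr) if pool.sum() else np.log(true_rr)
        if abs(new_log_hr - log_hr) < 1e-10:
            log_hr = new_log_hr
            break
        log_hr = new_log_hr
    hr = float(np.exp(log_hr))

    # step change in hazard from the first visit for uptakers
    t0 = rng.exponential(1.0, n) / h
    t_effect = np.where(uptake, first_visit, np.inf)
    effective = t0 > t_effect
    t_cvd = np.where(effective, t_effect + rng.exponential(1.0, n) / (h * hr), t0)

    s_death = oc.death_covariate_coef * zdep
    lh_death = _solve_log_h0(s_death, horizon, oc.death_rate_5yr)
    t_death = rng.exponential(1.0, n) / np.exp(lh_death + s_death)

    admin = float(config.admin_censor_months)
    event_time = np.minimum(np.minimum(t_cvd, t_death), admin)
    event_type = np.where(t_cvd <= event_time, "cvd",
                          np.where(t_death <= event_time, "death_other", "admin_censor"))

    baseline = pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "age": age, "sex": np.where(male, "male", "female"), "ethnicity": ethnicity,
        "nzdep": nzdep, "smoking": smoking, "family_history": family_history,
        "diabetes": diabetes, "af": af, "sbp": sbp, "tchdl": tchdl,
        "bplm": bplm, "llm": llm, "atm": atm,
        "event_time": event_time, "event_type": event_type,
    })

    # --- follow-up visit table (visits before the event only) -------------
    keep = vt < event_time[vid]
    fid, ft = vid[keep], vt[keep]
    m = fid.size
    f_smoking = smoking[fid].copy()
    f_sbp = sbp[fid] + rng.normal(0.0, 6.0, m)
    f_tchdl = np.clip(tchdl[fid] + rng.normal(0.0, 0.35, m), 0.5, None)
    f_bplm, f_llm, f_atm = bplm[fid].copy(), llm[fid].copy(), atm[fid].copy()

    up_row = uptake[fid]
    scen = config.scenario
    if scen == "I":
        f_smoking[up_row] = "ex"
    elif scen == "IIa":
        f_sbp[up_row] = 130.0 - np.abs(rng.normal(0.0, 5.0, int(up_row.sum())))
        nt = eligible[fid] & ~up_row  # non-adopters stay above threshold
        f_sbp[nt] = np.maximum(f_sbp[nt], 131.0)
    elif scen == "IIb":
        f_bplm[up_row] = 1
        f_sbp[up_row] = f_sbp[up_row] - 8.0
    elif scen == "IIIa":
        f_tchdl[up_row] = np.clip(3.5 - np.abs(rng.normal(0.0, 0.4, int(up_row.sum()))), 0.5, None)
        nt = eligible[fid] & ~up_row
        f_tchdl[nt] = np.maximum(f_tchdl[nt], 3.6)
    elif scen == "IIIb":
        f_llm[up_row] = 1
        f_tchdl[up_row] = np.clip(f_tchdl[up_row] - 0.8, 0.5, None)
    f_sbp = np.clip(f_sbp, 60.0, None)

    followups = pd.DataFrame({
        "id": fid.astype(np.int64), "visit_time": ft, "smoking": f_smoking,
        "sbp": f_sbp, "tchdl": f_tchdl, "bplm": f_bplm, "llm": f_llm, "atm": f_atm,
    })

    truth = {
        "scenario": scen, "true_rr": true_rr, "hazard_ratio": hr,
        "n_eligible": int(eligible.sum()), "n_returner": int(returner.sum()),
        "n_uptake": int(uptake.sum()),
        "confounder_score": conf_score,  # the uptake confounder (for oracles)
    }
    return Cohort(validate_baseline(baseline), validate_followups(followups), truth)
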