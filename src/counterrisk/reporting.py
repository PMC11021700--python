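"""Comparison surfaces: per-approach effect tables, absolute-risk and
absolute-risk-change summaries, subgroup breakdowns, and ARC histograms.

Quantiles use the linear-interpolation convention (numpy's default,
"type 7") throughout — quartile values are part of the reported output, so
the convention is fixed and documented. The absolute risk change is
``risk_without - risk_under`` (benefit positive), and its summaries are
computed on the per-person differences, not as differences of summaries.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

SUBGROUPS = ("all", "female", "male", "age<=50", "age>50",
             "European", "non-European")
QUANTITIES = ("risk_original", "risk_intervention", "arc")

SUMMARY_COLUMNS = ["scenario", "method", "subgroup", "quantity", "n",
                   "median", "lq", "uq"]


def _subgroup_mask(info: pd.DataFrame, label: str) -> np.ndarray:
    if label == "all":
        return np.ones(len(info), dtype=bool)
    if label in ("female", "male"):
        return (info["sex"] == label).to_numpy()
    if label == "age<=50":
        return (info["age"] <= 50).to_numpy()
    if label == "age>50":
        return (info["age"] > 50).to_numpy()
    if label == "European":
        return (info["ethnicity"] == "European").to_numpy()
    if label == "non-European":
        return (info["ethnicity"] != "European").to_numpy()
    raise ValueError(f"unknown subgroup {label!r}")


def summarize(pairs: pd.DataFrame, baseline: pd.DataFrame | None = None,
              scenario: str = "", method: str = "",
              by_subgroup: bool = False) -> pd.DataFrame:
    """Median and quartiles of risks and ARC across the target population.

    ``baseline`` supplies age/sex/ethnicity for subgroup splits (merged on
    ``id``); it is only required when ``by_subgroup`` is set. Empty
    subgroups yield a row with ``n = 0`` and null statistics.
    """
    if len(pairs) == 0:
        raise ValueError("cannot summarise an empty pair table")
    groups = list(SUBGROUPS) if by_subgroup else ["all"]
    if by_subgroup:
        if baseline is None:
            raise ValueError("subgroup summaries need the baseline table")
        info = pairs[["id"]].merge(
            baseline[["id", "age", "sex", "ethnicity"]], on="id", how="left")
    else:
        info = pairs[["id"]]

    rows = []
    for label in groups:
        mask = _subgroup_mask(info, label)
        for qty in QUANTITIES:
            vals = pairs.loc[mask, qty].to_numpy(dtype=float)
            if vals.size == 0:
                med = lq = uq = np.nan
            else:
                lq, med, uq = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append({"scenario": scenario, "method": method,
                         "subgroup": label, "quantity": qty,
                         "n": int(vals.size), "median": med, "lq": lq, "uq": uq})
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def arc_quartiles(pairs: pd.DataFrame) -> dict[str, float]:
    """The median/quartile rules drawn on an ARC histogram."""
    lq, med, uq = np.quantile(pairs["arc"].to_numpy(dtype=float), [0.25, 0.5, 0.75])
    return {"lq": float(lq), "median": float(med), "uq": float(uq)}


def render_report(summaries: pd.DataFrame, effects: dict, out_dir: str,
                  pairs_by_scenario: dict[str, pd.DataFrame] | None = None
                  ) -> dict:
    """Write machine-readable tables and per-scenario ARC histograms.

    ``summaries`` is a concatenation of :func:`summarize` outputs;
    ``effects`` maps ``(scenario, method)``-style keys (any str key) to
    :class:`~counterrisk.effects.EffectEstimate`-like objects or plain
    dicts. Returns the histogram annotation values (quartile/median rules)
    per scenario so callers can cross-check them against the tables.
    Regenerating from identical inputs is byte-identical (figures aside).
    """
    try:
        os.makedirs(out_dir, exist_ok=True)
        probe = os.path.join(out_dir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as err:
        raise OSError(f"report path {out_dir!r} is not writable: {err}") from err

    tidy = summaries[SUMMARY_COLUMNS].sort_values(
        ["scenario", "method", "subgroup", "quantity"], kind="mergesort")
    tidy.to_csv(os.path.join(out_dir, "summaries.csv"), index=False)

    eff_payload = {}
    for key, eff in effects.items():
        eff_payload[str(key)] = eff.to_dict() if hasattr(eff, "to_dict") else dict(eff)
    with open(os.path.join(out_dir, "effects.json"), "w") as fh:
        json.dump(eff_payload, fh, indent=2, sort_keys=True, default=float)

    rules = {}
    if pairs_by_scenario:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for sid, pairs in pairs_by_scenario.items():
            q = arc_quartiles(pairs)
            rules[sid] = q
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.hist(pairs["arc"].to_numpy(dtype=float) * 100, bins=40,
                    color="#9ecae1", edgecolor="white")
            ax.axvline(q["median"] * 100, color="tab:blue", lw=1.5)
            for v in (q["lq"], q["uq"]):
                ax.axvline(v * 100, color="tab:red", ls="--", lw=1.2)
            ax.set_xlabel("absolute risk change (percentage points)")
            ax.set_ylabel("participants")
            ax.set_title(f"scenario {sid}")
            fig.tight_layout()
            fig.savefig(os.path.join(out_dir, f"arc_{sid}.png"), dpi=120)
            plt.close(fig)
        with open(os.path.join(out_dir, "arc_rules.json"), "w") as fh:
            json.dump(rules, fh, indent=2, sort_keys=True)
    return rules
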