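"""Assemble the behavioural results report from fitted measures.

Mirrors the study's behavioural-results structure: the date premium
(BEST posterior + paired t on ln k point estimates), RT condition effects,
strategy-index comparisons, the dwell ANOVA, and the between-subject
regression of the date/delay effect on strategy difference measures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .discounting import date_premium
from .eyetracking import outlier_trim

__all__ = ["behavioural_report"]


def _trim(values: np.ndarray, z: float = 2.5) -> np.ndarray:
    kept, removed = outlier_trim(values, z)
    out = np.asarray(values, dtype=float).copy()
    out[removed] = np.nan
    return out


def behavioural_report(discount_table: pd.DataFrame,
                       gaze_measures: pd.DataFrame | None = None,
                       rt_table: pd.DataFrame | None = None,
                       seed: int = 0, trim_z: float = 2.5) -> dict:
    """Compute the study's behavioural statistics from measure tables.

    ``discount_table``: participant, lnk_delay, lnk_date.
    ``gaze_measures`` (optional): one row per participant x condition with
    payne, fixation_focus, mean_reward_dwell_ms, mean_time_dwell_ms.
    ``rt_table`` (optional): participant, condition, rt_ms (means).
    Individual values beyond ``trim_z`` SDs of the sample mean are excluded
    per variable before testing.
    """
    report: dict = {}

    t = stats.paired_t(discount_table["lnk_date"], discount_table["lnk_delay"])
    best = date_premium(discount_table, seed=seed)
    report["discounting"] = {
        "mean_lnk_delay": float(discount_table["lnk_delay"].mean()),
        "mean_lnk_date": float(discount_table["lnk_date"].mean()),
        "paired_t": t.__dict__,
        "premium_mean": best.mean,
        "premium_hdi": [best.hdi_low, best.hdi_high],
        "premium_p_less_zero": best.p_less_zero,
    }

    if rt_table is not None:
        wide = rt_table.pivot(index="participant", columns="condition",
                              values="rt_ms").dropna()
        t_rt = stats.paired_t(wide["date"], wide["delay"])
        t_lrt = stats.paired_t(np.log(wide["date"]), np.log(wide["delay"]))
        report["rt"] = {"paired_t": t_rt.__dict__,
                        "paired_t_log": t_lrt.__dict__}

    if gaze_measures is not None:
        gm = gaze_measures.copy()
        wide = gm.pivot(index="participant", columns="condition")
        payne = pd.DataFrame({
            "date": _trim(wide[("payne", "date")].to_numpy(), trim_z),
            "delay": _trim(wide[("payne", "delay")].to_numpy(), trim_z),
        }).dropna()
        report["payne"] = stats.paired_t(payne["date"], payne["delay"]).__dict__

        long = gm.melt(id_vars=["participant", "condition"],
                       value_vars=["mean_reward_dwell_ms",
                                   "mean_time_dwell_ms"],
                       var_name="attribute", value_name="dwell_ms")
        long["attribute"] = long["attribute"].map(
            {"mean_reward_dwell_ms": "reward", "mean_time_dwell_ms": "time"})
        anova = stats.rm_anova(long, "dwell_ms", ["condition", "attribute"])
        report["dwell_anova"] = anova.table.reset_index().to_dict("records")

        merged = discount_table.set_index("participant")
        dde = (merged["lnk_date"] - merged["lnk_delay"]).reindex(wide.index)
        d_payne = wide[("payne", "date")] - wide[("payne", "delay")]
        d_focus = (wide[("fixation_focus", "date")]
                   - wide[("fixation_focus", "delay")])
        complete = pd.DataFrame({"dde": dde, "d_payne": d_payne,
                                 "d_focus": d_focus}).dropna()
        if len(complete) >= 5:
            report["dde_regression"] = stats.dde_regression(
                complete["dde"], complete["d_payne"], complete["d_focus"])
    return report
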