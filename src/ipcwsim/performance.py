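"""ADEMP performance measures with Monte-Carlo standard errors.

For each (scenario, method) cell the five measures are computed from the
per-repetition risk-difference estimates against the scenario's
counterfactual truth:

bias      mean(RD_hat) - RD_true                    (stored signed)
EmpSE     sample SD of RD_hat
ModSE     sqrt(mean(SE^2))
RMSE      sqrt(mean((RD_hat - RD_true)^2))
coverage  % of repetitions whose 95% CI contains RD_true

each with the standard MCSE: EmpSE/sqrt(n) for bias, EmpSE/sqrt(2(n-1))
for EmpSE, sqrt(Var(SE^2)/(4 n ModSE^2)) for ModSE, the MSE MCSE divided
by 2*RMSE for RMSE, and sqrt(c(100-c)/n) for coverage.  Repetitions whose
fits did not converge are excluded pairwise per method, with counts kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["summarize", "compare_table", "MEASURES"]

MEASURES = ("bias", "empse", "modse", "rmse", "coverage")


def _cell(rd: np.ndarray, se: np.ndarray, lo: np.ndarray, hi: np.ndarray,
          truth: float) -> dict[str, float]:
    n = rd.size
    bias = rd.mean() - truth
    empse = rd.std(ddof=1)
    se2 = se ** 2
    modse = float(np.sqrt(se2.mean()))
    err2 = (rd - truth) ** 2
    mse = err2.mean()
    rmse = float(np.sqrt(mse))
    cover = 100.0 * float(((lo <= truth) & (truth <= hi)).mean())
    mcse_mse = err2.std(ddof=1) / np.sqrt(n)
    return {
        "bias": float(bias), "mcse_bias": float(empse / np.sqrt(n)),
        "empse": float(empse), "mcse_empse": float(empse / np.sqrt(2 * (n - 1))),
        "modse": modse,
        "mcse_modse": float(np.sqrt(se2.var(ddof=1) / (4 * n * modse ** 2)))
        if modse > 0 else 0.0,
        "rmse": rmse,
        "mcse_rmse": float(mcse_mse / (2 * rmse)) if rmse > 0 else 0.0,
        "coverage": cover,
        "mcse_coverage": float(np.sqrt(cover * (100.0 - cover) / n)),
    }


def summarize(estimates: pd.DataFrame, truth: pd.DataFrame | dict[int, float]
              ) -> pd.DataFrame:
    """Per (scenario, method) performance summary.

    ``estimates`` needs columns scenario_id, method, rd, se, ci_low,
    ci_high, converged; ``truth`` maps scenario_id -> true risk difference
    (or is a frame with scenario_id / rd_true columns).
    """
    if isinstance(truth, pd.DataFrame):
        truth_map = dict(zip(truth["scenario_id"], truth["rd_true"]))
    else:
        truth_map = dict(truth)
    rows = []
    for (sid, method), g in estimates.groupby(["scenario_id", "method"],
                                              sort=False):
        ok = g["converged"].astype(bool) & np.isfinite(g["rd"]) & np.isfinite(g["se"])
        used = g.loc[ok]
        n_used, n_excl = len(used), int((~ok).sum())
        if sid not in truth_map:
            raise KeyError(f"no truth value for scenario {sid}")
        row = {"scenario_id": sid, "method": method,
               "n_used": n_used, "n_excluded": n_excl,
               "usable": n_used >= 2}
        if n_used >= 2:
            row.update(_cell(used["rd"].to_numpy(), used["se"].to_numpy(),
                             used["ci_low"].to_numpy(), used["ci_high"].to_numpy(),
                             float(truth_map[sid])))
        else:
            row.update({m: np.nan for m in MEASURES})
            row.update({f"mcse_{m}": np.nan for m in MEASURES})
        rows.append(row)
    out = pd.DataFrame(rows)
    out["abs_bias"] = out["bias"].abs()
    return out


def summaries_tidy(summaries: pd.DataFrame) -> pd.DataFrame:
    """One row per scenario x method x measure (value + MCSE) for export."""
    rows = []
    for _, r in summaries.iterrows():
        for m in MEASURES:
            rows.append({"scenario_id": r["scenario_id"], "method": r["method"],
                         "measure": m, "value": r[m], "mcse": r[f"mcse_{m}"],
                         "n_used": r["n_used"]})
    return pd.DataFrame(rows)


def compare_table(summaries: pd.DataFrame,
                  scenario_order: list[int] | None = None,
                  method_order: list[str] | None = None) -> pd.DataFrame:
    """Nested-loop-style comparison table.

    One block per performance measure; within a block one row per scenario
    (in grid order) and one column per method (in catalogue order) --
    ready for nested-loop plotting or tabulation.
    """
    if summaries.empty:
        raise ValueError("no summaries to tabulate")
    if scenario_order is None:
        scenario_order = sorted(summaries["scenario_id"].unique())
    if method_order is None:
        method_order = list(dict.fromkeys(summaries["method"]))
    blocks = []
    for m in MEASURES:
        piv = summaries.pivot(index="scenario_id", columns="method", values=m)
        piv = piv.reindex(index=scenario_order, columns=method_order)
        piv.insert(0, "measure", m)
        blocks.append(piv.reset_index())
    out = pd.concat(blocks, ignore_index=True)
    return out[["measure", "scenario_id"] + method_order]
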