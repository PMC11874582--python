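"""Risk-difference estimators: ITT, per-protocol censoring, and IPCW.

All three share one outcome analysis: a pooled logistic model of the
discrete failure hazard on the stacked person-visit records,

    logit lambda(Y_v = 1 | survived to v [, uncensored]) = alpha Z + gamma(v) + psi Z v,

with per-visit indicators for gamma(v) by default (a flexible baseline
hazard that nests the generating model) and a linear arm-by-visit
interaction.  The cumulative incidence in each arm is the product-limit
transform F(V) = 1 - prod_v (1 - lambda_v), the estimand is
RD = F_experimental(V) - F_control(V), and its standard error comes from
the delta method through the product-limit form, with a cluster-robust
(by individual) sandwich covariance whenever the fit is weighted.

The methods differ only in which records enter and how they are weighted:
ITT uses every record, PP censors at the first intervention deviation, and
IPCW censors and weights by the inverse probability of remaining
deviation-free (see :mod:`ipcwsim.weighting`).

Estimator classes follow the scikit-learn protocol (``fit`` on a panel,
fitted attributes with trailing underscores, ``get_params``/``set_params``);
:func:`run_method` is the functional entry point used by the study engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .weighting import (MethodSpec, PositivityError, WeightTable,
                        compute_weights, fit_pooled_logistic, parse_method_name)

__all__ = [
    "censor_at_id", "OutcomeFit", "fit_outcome_model", "cumulative_incidence",
    "risk_difference", "delta_se", "bootstrap_se", "run_method",
    "EstimateRecord", "ITTEstimator", "PPEstimator", "IPCWEstimator",
]


def censor_at_id(panel: pd.DataFrame) -> pd.DataFrame:
    """Restrict a panel to deviation-free records (C_to = 0).

    The visit at which deviation first occurs is excluded -- the outcome
    model conditions on being uncensored at the current visit -- while all
    earlier visits are retained.
    """
    return panel.loc[panel["C_to"] == 0].copy()


# ----------------------------------------------------------------------
# outcome model
# ----------------------------------------------------------------------

@dataclass
class OutcomeFit:
    """Pooled logistic outcome fit plus everything the delta method needs."""

    params: np.ndarray
    cov: np.ndarray
    columns: list[str]
    visit_levels: list[int]
    n_visits: int
    visit_terms: str                    # "indicator" | "linear"
    weighted: bool
    converged: bool
    flags: list[str] = field(default_factory=list)

    def design_row(self, visit: int, arm: int) -> np.ndarray:
        if self.visit_terms == "indicator":
            row = [1.0 if visit == lv else 0.0 for lv in self.visit_levels]
        else:
            row = [1.0, float(visit)]
        row += [float(arm), float(arm) * visit]
        return np.asarray(row)

    def hazard(self, visit: int, arm: int) -> float:
        return float(expit(self.design_row(visit, arm) @ self.params))


def _outcome_design(records: pd.DataFrame, visit_terms: str,
                    visit_levels: list[int]) -> tuple[np.ndarray, list[str]]:
    v = records["visit"].to_numpy(dtype=float)
    z = records["Z"].to_numpy(dtype=float)
    if visit_terms == "indicator":
        cols = [(v == lv).astype(float) for lv in visit_levels]
        names = [f"gamma_{lv}" for lv in visit_levels]
    elif visit_terms == "linear":
        cols = [np.ones(len(v)), v]
        names = ["gamma_0", "gamma_v"]
    else:
        raise ValueError("visit_terms must be 'indicator' or 'linear'")
    cols += [z, z * v]
    names += ["alpha_Z", "psi_Zv"]
    return np.column_stack(cols), names


def _cluster_sandwich(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                      p: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Sandwich covariance with scores summed within individuals.

    Bread from the weighted information; meat from per-cluster score outer
    products with a G/(G-1) correction.
    """
    info = X.T @ (X * (w * p * (1.0 - p))[:, None])
    scores = X * (w * (y - p))[:, None]
    df = pd.DataFrame(scores)
    df["_g"] = groups
    G = df["_g"].nunique()
    S = df.groupby("_g", sort=False).sum().to_numpy()
    meat = S.T @ S * (G / max(G - 1, 1))
    bread = np.linalg.pinv(info)
    return bread @ meat @ bread


def fit_outcome_model(records: pd.DataFrame,
                      weights: pd.Series | np.ndarray | None = None,
                      visit_terms: str = "indicator",
                      n_visits: int = 8,
                      cluster_robust: bool | None = None) -> OutcomeFit:
    """Fit the (possibly weighted) pooled logistic outcome model.

    ``records`` must hold one row per person-visit with ``Y``, ``visit``
    (>= 1), ``Z`` and ``id``.  When ``weights`` is given the fit solves the
    weighted score equations and -- unless overridden -- the covariance is
    the cluster-robust sandwich grouped by individual; unweighted fits use
    the model-based covariance.
    """
    rec = records.loc[records["visit"] >= 1]
    flags: list[str] = []
    visit_levels = sorted(int(v) for v in rec["visit"].unique())
    if visit_terms == "indicator" and visit_levels != list(range(1, n_visits + 1)):
        flags.append("missing_visit_levels")
    X, names = _outcome_design(rec, visit_terms, visit_levels)
    y = rec["Y"].to_numpy(dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    fit = fit_pooled_logistic(X, y, weights=w, columns=names)
    flags += fit.flags

    weighted = w is not None
    if cluster_robust is None:
        cluster_robust = weighted
    cov = fit.cov
    if cluster_robust:
        p = fit.predict(X)
        ww = w if w is not None else np.ones(len(y))
        cov = _cluster_sandwich(X, y, ww, p, rec["id"].to_numpy())

    converged = fit.converged and "missing_visit_levels" not in flags
    return OutcomeFit(params=fit.params, cov=cov, columns=names,
                      visit_levels=visit_levels, n_visits=n_visits,
                      visit_terms=visit_terms, weighted=weighted,
                      converged=converged, flags=flags)


# ----------------------------------------------------------------------
# risk difference and its standard error
# ----------------------------------------------------------------------

def cumulative_incidence(fit: OutcomeFit, arm: int) -> float:
    """F(V) = 1 - prod_{v=1..V} (1 - lambda_v(arm))."""
    surv = 1.0
    for v in range(1, fit.n_visits + 1):
        surv *= 1.0 - fit.hazard(v, arm)
    return 1.0 - surv


def risk_difference(fit: OutcomeFit) -> float:
    """RD = F(V | experimental) - F(V | control)."""
    return cumulative_incidence(fit, 1) - cumulative_incidence(fit, 0)


def _incidence_gradient(fit: OutcomeFit, arm: int) -> np.ndarray:
    """dF/dbeta = S(V) * sum_v lambda_v x_v  (product-limit chain rule)."""
    lam = np.array([fit.hazard(v, arm) for v in range(1, fit.n_visits + 1)])
    Xv = np.stack([fit.design_row(v, arm) for v in range(1, fit.n_visits + 1)])
    S = np.prod(1.0 - lam)
    return S * (lam @ Xv)


def delta_se(fit: OutcomeFit, alpha: float = 0.05
             ) -> tuple[float, tuple[float, float]]:
    """Delta-method SE of the risk difference and a Normal-theory CI."""
    g = _incidence_gradient(fit, 1) - _incidence_gradient(fit, 0)
    var = float(g @ fit.cov @ g)
    if not np.isfinite(var) or var < 0:
        return np.nan, (np.nan, np.nan)
    se = float(np.sqrt(var))
    rd = risk_difference(fit)
    zq = norm.ppf(1 - alpha / 2)
    return se, (rd - zq * se, rd + zq * se)


# ----------------------------------------------------------------------
# method application
# ----------------------------------------------------------------------

@dataclass
class EstimateRecord:
    """One (scenario, repetition, method) estimate."""

    scenario_id: int
    rep: int
    method: str
    rd: float
    se: float
    ci_low: float
    ci_high: float
    converged: bool
    n_censored: int
    mean_weight: float
    max_weight: float
    flags: str = ""


def run_method(panel: pd.DataFrame, method: MethodSpec | str,
               scenario_id: int = 0, rep: int = 0,
               visit_terms: str = "indicator", f_visit: str = "linear",
               n_visits: int = 8,
               _weights: WeightTable | None = None) -> EstimateRecord:
    """Apply one analysis method to a trial panel.

    ITT fits the outcome model on the full panel; PP censors at the first
    deviation; IPCW censors and weights with the method's covariate set and
    stabilisation flag.  Failures are recorded in the convergence flag, not
    raised.
    """
    if isinstance(method, str):
        method = parse_method_name(method)
    n_censored = int(panel.groupby("id")["C_to"].max().gt(0).sum())
    weights = None
    wt: WeightTable | None = None
    flags: list[str] = []
    mean_w = max_w = 1.0

    try:
        if method.kind == "ITT":
            records = panel
        else:
            records = censor_at_id(panel)
        if method.kind == "IPCW":
            wt = _weights if _weights is not None else compute_weights(
                panel, method, f_visit=f_visit)
            wcol = "SW" if method.stabilised else "W"
            rec = records.loc[records["visit"] >= 1]
            merged = rec.merge(wt.table[["id", "visit", wcol]],
                               on=["id", "visit"], how="left", validate="1:1")
            if merged[wcol].isna().any():
                flags.append("unmatched_weights")
                merged[wcol] = merged[wcol].fillna(1.0)
            records = merged
            weights = merged[wcol].to_numpy()
            mean_w = float(np.mean(weights))
            max_w = float(np.max(weights))
            flags += wt.flags
        fit = fit_outcome_model(records, weights=weights,
                                visit_terms=visit_terms, n_visits=n_visits)
        rd = risk_difference(fit)
        se, (lo, hi) = delta_se(fit)
        converged = fit.converged and (wt.converged if wt is not None else True)
        flags += [f for f in fit.flags if f not in flags]
    except (PositivityError, ValueError, np.linalg.LinAlgError) as exc:
        rd = se = lo = hi = np.nan
        converged = False
        flags.append(f"error:{type(exc).__name__}")

    return EstimateRecord(scenario_id=scenario_id, rep=rep, method=method.name,
                          rd=rd, se=se, ci_low=lo, ci_high=hi,
                          converged=bool(converged), n_censored=n_censored,
                          mean_weight=mean_w, max_weight=max_w,
                          flags=";".join(flags))


def run_methods(panel: pd.DataFrame, methods, scenario_id: int = 0,
                rep: int = 0, visit_terms: str = "indicator",
                f_visit: str = "linear", n_visits: int = 8
                ) -> list[EstimateRecord]:
    """Apply a catalogue of methods to one panel, sharing censoring-model
    fits between the stabilised and unstabilised variant of each
    covariate set (both weight columns come from one :class:`WeightTable`)."""
    cache: dict[tuple, WeightTable] = {}
    out = []
    for m in methods:
        if isinstance(m, str):
            m = parse_method_name(m)
        wt = None
        if m.kind == "IPCW":
            key = (m.covariates, m.baseline)
            if key not in cache:
                try:
                    cache[key] = compute_weights(panel, m, f_visit=f_visit)
                except (PositivityError, ValueError) as exc:
                    cache[key] = exc  # type: ignore[assignment]
            wt = cache[key]
            if isinstance(wt, Exception):
                out.append(EstimateRecord(
                    scenario_id=scenario_id, rep=rep, method=m.name,
                    rd=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                    converged=False, n_censored=0, mean_weight=np.nan,
                    max_weight=np.nan, flags=f"error:{type(wt).__name__}"))
                continue
        out.append(run_method(panel, m, scenario_id=scenario_id, rep=rep,
                              visit_terms=visit_terms, f_visit=f_visit,
                              n_visits=n_visits, _weights=wt))
    return out


def bootstrap_se(panel: pd.DataFrame, method: MethodSpec | str, B: int = 1000,
                 rng=None, alpha: float = 0.05, **kwargs
                 ) -> dict[str, float | tuple[float, float] | int]:
    """Nonparametric bootstrap over individuals.

    Individuals (not rows) are resampled with replacement and the *entire*
    method -- censoring-model fitting included -- is re-run on each
    resample.  Non-convergent resamples are dropped and counted.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(rng)
    ids = panel["id"].unique()
    by_id = {i: g for i, g in panel.groupby("id", sort=False)}
    rds = []
    dropped = 0
    for _ in range(B):
        pick = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, old in enumerate(pick):
            g = by_id[old].copy()
            g["id"] = new_id
            parts.append(g)
        bpanel = pd.concat(parts, ignore_index=True)
        est = run_method(bpanel, method, **kwargs)
        if est.converged and np.isfinite(est.rd):
            rds.append(est.rd)
        else:
            dropped += 1
    rds = np.asarray(rds)
    lo, hi = np.percentile(rds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return {"se": float(rds.std(ddof=1)), "ci": (float(lo), float(hi)),
            "n_used": int(rds.size), "n_dropped": dropped}


# ----------------------------------------------------------------------
# scikit-learn-style wrappers
# ----------------------------------------------------------------------

class _RiskDifferenceBase(BaseEstimator):
    """Shared fit logic: subclasses define `_method_spec`."""

    def __init__(self, visit_terms: str = "indicator", n_visits: int = 8):
        self.visit_terms = visit_terms
        self.n_visits = n_visits

    def _method_spec(self) -> MethodSpec:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, panel: pd.DataFrame, y=None):
        for col in ("id", "visit", "Z", "C_to", "Y"):
            if col not in panel.columns:
                raise ValueError(f"panel lacks required column {col!r}")
        est = run_method(panel, self._method_spec(),
                         visit_terms=self.visit_terms, n_visits=self.n_visits,
                         **getattr(self, "_run_kwargs", lambda: {})())
        self.risk_difference_ = est.rd
        self.se_ = est.se
        self.conf_int_ = (est.ci_low, est.ci_high)
        self.converged_ = est.converged
        self.estimate_record_ = est
        return self


class ITTEstimator(_RiskDifferenceBase):
    """Intention-to-treat: compare arms as randomised, ignoring deviation.

    Targets the treatment-policy estimand; under the hypothetical estimand
    it absorbs whatever the post-deviation regimen does to the hazard.
    """

    def _method_spec(self) -> MethodSpec:
        return parse_method_name("ITT")


class PPEstimator(_RiskDifferenceBase):
    """Per-protocol by censoring at the first intervention deviation.

    Unbiased for the hypothetical estimand only when censoring is
    non-informative; with confounder-driven deviation it selects
    better-prognosis individuals and is biased.
    """

    def _method_spec(self) -> MethodSpec:
        return parse_method_name("PP")


class IPCWEstimator(_RiskDifferenceBase):
    """Censor at deviation and re-weight by inverse censoring probabilities.

    Parameters
    ----------
    covariates : tuple of str
        TVCs entering the censoring model; a trailing ``*`` selects the
        delayed (mismeasured) version, e.g. ``("L1*", "L2*")``.
    stabilised : bool
        Use stabilised weights (marginal-probability numerator).
    f_visit : str
        Visit term of the censoring model: ``"linear"`` or ``"indicator"``.
    """

    def __init__(self, covariates: tuple[str, ...] = ("L1", "L2"),
                 stabilised: bool = True, f_visit: str = "linear",
                 visit_terms: str = "indicator", n_visits: int = 8):
        super().__init__(visit_terms=visit_terms, n_visits=n_visits)
        self.covariates = covariates
        self.stabilised = stabilised
        self.f_visit = f_visit

    def _run_kwargs(self):
        return {"f_visit": self.f_visit}

    def _method_spec(self) -> MethodSpec:
        tag = "s" if self.stabilised else "u"
        name = f"IPCW{tag}" + "".join(self.covariates)
        return MethodSpec(name, "IPCW", covariates=tuple(self.covariates),
                          stabilised=self.stabilised)

    def fit(self, panel: pd.DataFrame, y=None):
        super().fit(panel)
        wt = compute_weights(panel, self._method_spec(), f_visit=self.f_visit)
        self.weights_ = wt.table
        return self
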