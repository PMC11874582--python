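"""Censoring-model fitting and inverse-probability-of-censoring weights.

Censoring here means censoring at the first intervention deviation.  For
each person-visit still free of deviation at the previous visit we model

    logit P(C_v = 1 | C_{v-1} = 0, B, K_v) = eta.B + zeta.K_v + iota f(v) + vartheta Z

by pooled logistic regression, where ``K_v`` is the analyst-chosen TVC
subset (possibly the delayed, starred versions).  Unstabilised weights
multiply inverse probabilities of remaining deviation-free,

    W_v = prod_{k=1..v} 1 / (1 - p_k),

and stabilised weights replace the numerator with the marginal probability
from a covariate-free model (visit trend and arm only),

    SW_v = prod_{k=1..v} (1 - p0_k) / (1 - p_k).

Arms in which no deviation ever occurs (single-arm-deviation designs) get
p = p0 = 0, i.e. unit weights, and the arm term is dropped from the models
when only one arm has events -- the pooled fit would otherwise be separated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MethodSpec", "parse_method_name", "default_catalogue",
    "build_censoring_risk_set", "fit_pooled_logistic", "PooledLogitFit",
    "predict_id_probability", "compute_unstabilised_weights",
    "compute_stabilised_weights", "mismeasure_covariates", "compute_weights",
    "PositivityError",
]

BASELINE_COVARIATES = ("B1", "B2", "B3")
TVC_NAMES = ("L1", "L2", "L3", "L4", "L5")


class PositivityError(RuntimeError):
    """A fitted deviation probability of one on an uncensored record."""


@dataclass(frozen=True)
class MethodSpec:
    """One analysis method: censoring rule, covariate set, stabilisation.

    ``kind`` is ITT (no censoring), PP (censor at deviation, no weights) or
    IPCW (censor and weight).  ``covariates`` lists TVC names, with a ``*``
    suffix marking the delayed (mismeasured) version, e.g. ``("L1*", "L2*")``.
    """

    name: str
    kind: str                                   # "ITT" | "PP" | "IPCW"
    covariates: tuple[str, ...] = ()
    baseline: tuple[str, ...] = BASELINE_COVARIATES
    stabilised: bool = False

    def __post_init__(self):
        if self.kind not in ("ITT", "PP", "IPCW"):
            raise ValueError(f"unknown method kind {self.kind!r}")
        if self.kind in ("ITT", "PP") and self.covariates:
            raise ValueError(f"{self.kind} must carry an empty covariate set")
        if self.kind == "IPCW" and not self.covariates:
            raise ValueError("IPCW requires a non-empty covariate set")
        for c in self.covariates:
            if c.rstrip("*") not in TVC_NAMES:
                raise ValueError(f"unknown TVC {c!r}")


def parse_method_name(name: str) -> MethodSpec:
    """Parse catalogue names: ``ITT``, ``PP``, ``IPCW[u|s]<L-set>``.

    The L-set is a concatenation like ``L1L2`` or ``L1*L2*``.
    """
    if name == "ITT":
        return MethodSpec(name, "ITT")
    if name == "PP":
        return MethodSpec(name, "PP")
    m = re.fullmatch(r"IPCW([us])((?:L[1-5]\*?)+)", name)
    if not m:
        raise ValueError(f"cannot parse method name {name!r}")
    covs = tuple(re.findall(r"L[1-5]\*?", m.group(2)))
    return MethodSpec(name, "IPCW", covariates=covs,
                      stabilised=(m.group(1) == "s"))


def default_catalogue() -> list[MethodSpec]:
    """ITT, PP, and {unstabilised, stabilised} x six weighting-model
    covariate sets (correct, under-, over- and mis-specified, delayed)."""
    sets = ["L1L2", "L1", "L2", "L1L3L4L5", "L1L2L3L4L5", "L1*L2*"]
    out = [parse_method_name("ITT"), parse_method_name("PP")]
    out += [parse_method_name(f"IPCW{u}{s}") for u in "us" for s in sets]
    return out


# ----------------------------------------------------------------------
# risk set and measurement delay
# ----------------------------------------------------------------------

def build_censoring_risk_set(panel: pd.DataFrame) -> pd.DataFrame:
    """Person-visits at risk of deviation: v >= 1 and no deviation before v.

    The visit of the first deviation is included (response 1); later visits
    are excluded.  Post-event visits never appear because the panel stops at
    failure.
    """
    eligible = (panel["visit"] >= 1) & ((panel["C_to"] - panel["C"]) == 0)
    out = panel.loc[eligible].copy()
    if out.empty:
        raise ValueError("empty censoring risk set")
    return out


def mismeasure_covariates(panel: pd.DataFrame,
                          covariates: tuple[str, ...] = ("L1", "L2")
                          ) -> pd.DataFrame:
    """Add delayed columns ``L1*``... : the value observed one visit late.

    ``L*_v = L_{v-1}`` for v >= 1; the baseline row reuses the baseline
    value (nothing earlier exists to report).
    """
    out = panel.sort_values(["id", "visit"], kind="stable").copy()
    for c in covariates:
        lag = out.groupby("id", sort=False)[c].shift(1)
        out[c + "*"] = lag.fillna(out[c])
    return out


# ----------------------------------------------------------------------
# pooled logistic regression
# ----------------------------------------------------------------------

@dataclass
class PooledLogitFit:
    """Pooled logistic fit with convergence/separation diagnostics."""

    params: np.ndarray
    cov: np.ndarray
    columns: list[str]
    converged: bool
    separation: bool
    n_obs: int
    loglik: float
    flags: list[str] = field(default_factory=list)

    def linpred(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params

    def predict(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit
        return expit(self.linpred(X))


def fit_pooled_logistic(X: np.ndarray, y: np.ndarray,
                        weights: np.ndarray | None = None,
                        columns: list[str] | None = None,
                        maxiter: int = 100, tol: float = 1e-8
                        ) -> PooledLogitFit:
    """Maximum-likelihood logistic fit on stacked person-visit records.

    Backed by IRLS (statsmodels GLM, Binomial/logit); convergence is judged
    on the relative log-likelihood change with a capped iteration count and
    reported as a flag -- non-convergence and separation never raise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    flags: list[str] = []
    cols = columns if columns is not None else [f"x{j}" for j in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X) if X.size else 0
    if rank < X.shape[1]:
        flags.append("rank_deficient")
    kw = {"freq_weights": weights} if weights is not None else {}
    model = sm.GLM(y, X, family=sm.families.Binomial(), **kw)
    converged = True
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=maxiter, tol=tol, tol_criterion="deviance")
        converged = bool(getattr(res, "converged", True))
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        llf = float(res.llf)
    except Exception as exc:  # noqa: BLE001 - contract: flag, don't raise
        flags.append(f"fit_error:{type(exc).__name__}")
        beta = np.zeros(X.shape[1])
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        llf = np.nan
        converged = False
    lp = X @ beta
    separation = bool(np.any(np.abs(lp) > 30) or np.any(np.abs(beta) > 50))
    if y.min() == y.max():
        separation = True
        flags.append("degenerate_response")
    if separation:
        flags.append("separation")
    if not converged:
        flags.append("not_converged")
    return PooledLogitFit(params=beta, cov=cov, columns=cols,
                          converged=converged, separation=separation,
                          n_obs=len(y), loglik=llf, flags=flags)


def _design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for t in terms:
        cols.append(df[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def predict_id_probability(fit: PooledLogitFit, risk_set: pd.DataFrame,
                           terms: list[str]) -> np.ndarray:
    """Fitted deviation probabilities p_hat on risk-set rows."""
    return fit.predict(_design(risk_set, terms))


# ----------------------------------------------------------------------
# weight computation
# ----------------------------------------------------------------------

def compute_unstabilised_weights(p_hat: np.ndarray) -> np.ndarray:
    """W_v = prod_{k<=v} 1/(1 - p_k) along one individual's visit sequence."""
    p = np.asarray(p_hat, dtype=float)
    if np.any(p >= 1.0):
        raise PositivityError("fitted deviation probability of 1 on an "
                              "uncensored record")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1)")
    return 1.0 / np.cumprod(1.0 - p)


def compute_stabilised_weights(p_hat: np.ndarray, p0_hat: np.ndarray
                               ) -> np.ndarray:
    """SW_v = prod_{k<=v} (1 - p0_k)/(1 - p_k) along one visit sequence."""
    p = np.asarray(p_hat, dtype=float)
    p0 = np.asarray(p0_hat, dtype=float)
    if np.any(p >= 1.0):
        raise PositivityError("fitted deviation probability of 1 on an "
                              "uncensored record")
    return np.cumprod(1.0 - p0) / np.cumprod(1.0 - p)


def _grouped_cumprod(x: np.ndarray, first: np.ndarray) -> np.ndarray:
    """Cumulative product of ``x`` restarting wherever ``first`` is True."""
    logx = np.log(x)
    cs = np.cumsum(logx)
    offset = np.zeros_like(cs)
    idx = np.flatnonzero(first)
    offset[idx] = cs[idx] - logx[idx]
    running = np.maximum.accumulate(np.where(first, np.arange(len(x)), -1))
    return np.exp(cs - offset[running])


@dataclass
class WeightTable:
    """Per uncensored person-visit (v >= 1): probabilities and weights."""

    table: pd.DataFrame                 # id, visit, p_hat, p0_hat, W, SW
    denominator_fit: PooledLogitFit | None   # None when no arm has events
    numerator_fit: PooledLogitFit | None
    arms_with_events: tuple[int, ...]
    flags: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        if self.denominator_fit is None:     # no deviations: unit weights
            return True
        ok = self.denominator_fit.converged and not self.denominator_fit.separation
        if self.numerator_fit is not None:
            ok = ok and self.numerator_fit.converged and not self.numerator_fit.separation
        return ok


def compute_weights(panel: pd.DataFrame, method: MethodSpec,
                    f_visit: str = "linear",
                    numerator_includes_arm: bool = True,
                    truncate_percentile: float | None = None) -> WeightTable:
    """Fit the censoring models for ``method`` and build W and SW.

    ``f_visit`` selects the visit term f(v) of the censoring model:
    ``"linear"`` (default, matches the generating hazard) or
    ``"indicator"`` for per-visit dummies.  The stabilising numerator model
    keeps f(v) and, by default, the randomised arm.  Arms with zero
    deviation events receive p = p0 = 0 (unit weights).  Optional
    percentile truncation is a diagnostic only and off by default.
    """
    if method.kind != "IPCW":
        raise ValueError("weights are defined for IPCW methods only")
    needed_stars = tuple(sorted({c.rstrip("*") for c in method.covariates if c.endswith("*")}))
    work = mismeasure_covariates(panel, needed_stars) if needed_stars else panel
    risk = build_censoring_risk_set(work)

    by_arm = risk.groupby("Z")["C"].sum()
    arms_with_events = tuple(int(a) for a in by_arm.index[by_arm > 0])
    flags: list[str] = []
    if not arms_with_events:
        flags.append("no_deviation_events")

    fit_rows = risk[risk["Z"].isin(arms_with_events)]
    include_arm = len(arms_with_events) == 2

    def visit_terms(df):
        if f_visit == "linear":
            return ["visit"], None
        dummies = sorted(df["visit"].unique())[1:]  # reference = first visit
        for v in dummies:
            df[f"visit_{v}"] = (df["visit"] == v).astype(float)
        return [f"visit_{v}" for v in dummies], dummies

    denom_terms = list(method.baseline) + list(method.covariates)
    num_terms: list[str] = []
    fit_rows = fit_rows.copy()
    vt, dummies = visit_terms(fit_rows)
    denom_terms += vt
    num_terms += vt
    if include_arm:
        denom_terms.append("Z")
        if numerator_includes_arm:
            num_terms.append("Z")

    den_fit = num_fit = None
    if arms_with_events:
        den_fit = fit_pooled_logistic(_design(fit_rows, denom_terms),
                                      fit_rows["C"].to_numpy(),
                                      columns=["const"] + denom_terms)
        num_fit = fit_pooled_logistic(_design(fit_rows, num_terms),
                                      fit_rows["C"].to_numpy(),
                                      columns=["const"] + num_terms)

    # probabilities on uncensored records (C_to == 0, v >= 1)
    unc = risk[risk["C"] == 0].copy()
    if dummies is not None:
        for v in dummies:
            unc[f"visit_{v}"] = (unc["visit"] == v).astype(float)
    p_hat = np.zeros(len(unc))
    p0_hat = np.zeros(len(unc))
    in_fit = unc["Z"].isin(arms_with_events).to_numpy()
    if den_fit is not None and in_fit.any():
        p_hat[in_fit] = predict_id_probability(den_fit, unc.loc[in_fit], denom_terms)
        if num_fit is not None:
            p0_hat[in_fit] = predict_id_probability(num_fit, unc.loc[in_fit], num_terms)
    unc["p_hat"] = p_hat
    unc["p0_hat"] = p0_hat

    unc = unc.sort_values(["id", "visit"], kind="stable")
    p = unc["p_hat"].to_numpy()
    p0 = unc["p0_hat"].to_numpy()
    if np.any(p >= 1.0):
        raise PositivityError("fitted deviation probability of 1 on an "
                              "uncensored record")
    # per-id cumulative products, vectorised: restart the running product at
    # each new individual by dividing out the value carried over the break
    first = np.r_[True, unc["id"].to_numpy()[1:] != unc["id"].to_numpy()[:-1]]
    unc["W"] = _grouped_cumprod(1.0 / (1.0 - p), first)
    unc["SW"] = _grouped_cumprod((1.0 - p0) / (1.0 - p), first)

    if truncate_percentile is not None:
        for col in ("W", "SW"):
            vals = unc[col].to_numpy()
            if np.all(np.isnan(vals)):
                continue
            cap = np.nanpercentile(vals, truncate_percentile)
            unc[col] = np.minimum(vals, cap)
        flags.append(f"truncated_at_p{truncate_percentile}")

    table = unc[["id", "visit", "p_hat", "p0_hat", "W", "SW"]].reset_index(drop=True)
    return WeightTable(table=table, denominator_fit=den_fit,
                       numerator_fit=num_fit, arms_with_events=arms_with_events,
                       flags=flags)
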