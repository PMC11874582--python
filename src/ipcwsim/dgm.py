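"""Discrete-time trial simulator with time-varying confounding.

The mechanism is sequential-conditional.  Baseline covariates are drawn from
a truncated multivariate normal (plus a logistic binary sex indicator), arms
are assigned 1:1, and then for each follow-up visit ``v = 1..8`` the
within-visit causal ordering is

    TVCs ``L_v``  ->  intervention deviation ``C_v``  ->  outcome ``Y_v``

so that deviation at visit ``v`` may depend on the current covariate values,
and the failure hazard in ``[v, v+1)`` depends on current covariates and on
the time spent on (``T_on``) and off (``T_off``) the originally assigned
treatment.  Deviation is absorbing (it is drawn only while the cumulative
indicator is zero) and failure is absorbing (no records after the first
event).  Post-deviation records continue to be generated: censoring at
deviation is a decision for the *estimators*, never for the generator.

The counterfactual truth -- the risk difference at visit 8 had deviation
never occurred -- is obtained by forward-simulating both treatment regimens
with the deviation process switched off (`simulate_truth`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .params import DGMParams, ScenarioSpec

__all__ = [
    "draw_baseline", "randomise", "step_tvcs", "step_id", "step_outcome",
    "simulate_trial", "simulate_truth", "tune_intercept", "TruthResult",
    "outcome_hazard", "ever_id_prevalence",
    "InfeasibleTruncationError", "TuneError",
]

PANEL_COLUMNS = [
    "id", "visit", "Z", "B1", "B2", "B3",
    "L1", "L2", "L3", "L4", "L5",
    "C", "C_to", "first_id_visit", "T_on", "T_off", "Y", "at_risk",
]


class InfeasibleTruncationError(RuntimeError):
    """Rejection sampling made essentially no progress: the truncation
    region has negligible mass under N(mu0, Sigma)."""


class TuneError(RuntimeError):
    """Intercept tuning could not reach the requested prevalence."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# baseline and randomisation
# ----------------------------------------------------------------------

def draw_baseline(params: DGMParams, n: int, rng,
                  max_rounds: int = 50) -> pd.DataFrame:
    """Draw baseline covariates for ``n`` individuals.

    (B1, B3, L01..L05) come from TruncNorm(mu0, Sigma, lo, hi) sampled by
    rejection (exact; the bounds in the default configuration are mild), and
    the binary B2 from a logistic model on B1, B3 and L0.  Raises
    :class:`InfeasibleTruncationError` rather than hanging when the
    truncation region has vanishing acceptance probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = _as_rng(rng)
    lo, hi = params.trunc_lo, params.trunc_hi

    accepted: list[np.ndarray] = []
    got = 0
    batch = max(n, 1000)
    for _ in range(max_rounds):
        draws = rng.multivariate_normal(params.mu0, params.Sigma, size=batch,
                                        method="svd")
        keep = draws[np.all((draws >= lo) & (draws <= hi), axis=1)]
        if keep.size:
            accepted.append(keep)
            got += keep.shape[0]
        if got >= n:
            break
        # grow the batch pessimistically from the observed acceptance rate
        rate = max(got / max(batch, 1), 1e-3)
        batch = int(min(2e6, 1.5 * (n - got) / rate))
    else:
        raise InfeasibleTruncationError(
            f"accepted {got}/{n} draws after {max_rounds} rejection rounds")
    X = np.concatenate(accepted, axis=0)[:n] if got >= n else None
    if X is None:
        raise InfeasibleTruncationError(
            f"accepted {got}/{n} draws after {max_rounds} rejection rounds")

    B1, B3 = X[:, 0], X[:, 1]
    L0 = X[:, 2:7]
    p2 = expit(params.rho1 * B1 + params.rho2 * B3 + L0 @ params.rho3)
    B2 = (rng.random(n) < p2).astype(np.int8)
    out = pd.DataFrame({"B1": B1, "B2": B2, "B3": B3})
    for q in range(5):
        out[f"L0{q + 1}"] = L0[:, q]
    return out


def randomise(n: int, rng) -> np.ndarray:
    """1:1 randomisation: Z ~ Bernoulli(0.5), iid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng)
    return (rng.random(n) < 0.5).astype(np.int8)


# ----------------------------------------------------------------------
# one-visit transition kernels (vectorised over individuals)
# ----------------------------------------------------------------------

def _tvc_innovations(params: DGMParams, n: int, rng) -> np.ndarray:
    """Innovations (n, 5): (eps1, eps2) jointly normal with covariance
    Lambda via Cholesky-style factorisation, eps3..eps5 independent."""
    eps = np.empty((n, 5))
    # use an eigen-safe square root so a singular Lambda is allowed
    w, V = np.linalg.eigh(params.Lambda)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    eps[:, :2] = rng.standard_normal((n, 2)) @ root.T
    eps[:, 2] = params.sd3 * rng.standard_normal(n)
    eps[:, 3] = params.sd4 * rng.standard_normal(n)
    eps[:, 4] = params.sd5 * rng.standard_normal(n)
    return eps + params.xi


def step_tvcs(L_prev: np.ndarray, Z: np.ndarray, C_to_prev: np.ndarray,
              B: np.ndarray, params: DGMParams, rng) -> np.ndarray:
    """Advance the five TVCs one visit (AR(1) with covariate shifts).

    L_qv = b_q0 + b_q1 Z + (b_q2 + b_q3 Z) C_to(v-1) + b_q4 . B
           + b_q5 L_q(v-1) + eps_q
    """
    rng = _as_rng(rng)
    n = L_prev.shape[0]
    eps = _tvc_innovations(params, n, rng)
    Zc = np.asarray(Z, dtype=float)[:, None]
    Cc = np.asarray(C_to_prev, dtype=float)[:, None]
    mean = (params.beta0[None, :]
            + params.beta1[None, :] * Zc
            + (params.beta2[None, :] + params.beta3[None, :] * Zc) * Cc
            + B @ params.beta4.T
            + params.beta5[None, :] * L_prev)
    return mean + eps


def step_id(v: int, Z: np.ndarray, B: np.ndarray, L: np.ndarray,
            C_to_prev: np.ndarray, params: DGMParams, rng,
            allow_id: bool = True) -> np.ndarray:
    """Draw the deviation indicator at visit ``v``.

    Only individuals with no prior deviation and an arm in ``id_arms`` are
    at risk of deviating; in single-arm configurations the other arm's
    indicator is structurally zero.  In deterministic mode deviation fires
    with probability one when the configured covariate crosses its
    threshold.
    """
    rng = _as_rng(rng)
    Z = np.asarray(Z)
    eligible = (np.asarray(C_to_prev) == 0) & np.isin(Z, params.id_arms)
    u = rng.random(Z.shape[0])  # always consumed: keeps streams aligned
    if not allow_id:
        return np.zeros(Z.shape[0], dtype=np.int8)
    if params.deterministic_id is not None:
        rule = params.deterministic_id
        hit = rule.triggered(L) & np.isin(Z, rule.arms)
        return (hit & eligible).astype(np.int8)
    lp = (params.theta0 + params.theta1 * v + params.theta2 * Z
          + B @ params.theta3 + L @ params.theta4)
    return ((u < expit(lp)) & eligible).astype(np.int8)


def outcome_hazard(v: int, Z: np.ndarray, B: np.ndarray, L: np.ndarray,
                   first_id: np.ndarray, params: DGMParams) -> np.ndarray:
    """Discrete hazard of failure in [v, v+1) given survival to visit v.

    T_on = min(v, first_id_visit) counts periods on the assigned regimen,
    T_off = max(v - first_id_visit, 0) periods after deviating; with no
    deviation T_on = v and T_off = 0.
    """
    Z = np.asarray(Z, dtype=float)
    t_on = np.minimum(float(v), first_id)
    t_off = np.maximum(float(v) - first_id, 0.0)
    lp = (params.mu_out0 + params.mu_out1 * Z
          + (params.mu_out2 + params.mu_out3 * Z) * t_on
          + (params.mu_out4 + params.mu_out5 * Z) * t_off
          + B @ params.mu_out6 + L @ params.mu_out7)
    return expit(lp)


def step_outcome(v: int, Z: np.ndarray, B: np.ndarray, L: np.ndarray,
                 first_id: np.ndarray, params: DGMParams, rng
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw the failure indicator for interval [v, v+1); returns (Y, hazard)."""
    rng = _as_rng(rng)
    lam = outcome_hazard(v, Z, B, L, first_id, params)
    Y = (rng.random(len(lam)) < lam).astype(np.int8)
    return Y, lam


# ----------------------------------------------------------------------
# whole-trial simulation
# ----------------------------------------------------------------------

def simulate_trial(scenario: ScenarioSpec | DGMParams, seed, n: int | None = None,
                   allow_id: bool = True) -> pd.DataFrame:
    """Simulate one trial panel (long format, one row per person-visit).

    Rows exist for visit 0 (baseline) and for every follow-up visit at which
    the individual is still event-free at the start of the visit; ``Y = 1``
    marks failure in ``[v, v+1)`` and is absorbing.  Post-deviation rows are
    generated as usual -- censoring is left to the analysis methods.
    """
    if isinstance(scenario, ScenarioSpec):
        params = scenario.params
        n = n if n is not None else scenario.n_obs
    else:
        params = scenario
        if n is None:
            raise ValueError("n is required when passing raw DGMParams")
    rng = _as_rng(seed)
    params.validate()

    base = draw_baseline(params, n, rng)
    Z = randomise(n, rng)
    return _forward_panel(params, base, Z, rng, allow_id=allow_id)


def _forward_panel(params: DGMParams, base: pd.DataFrame, Z: np.ndarray,
                   rng, allow_id: bool = True) -> pd.DataFrame:
    n = len(base)
    B = base[["B1", "B2", "B3"]].to_numpy(dtype=float)
    L = base[[f"L0{q}" for q in range(1, 6)]].to_numpy(dtype=float)
    ids = np.arange(n)
    C_to = np.zeros(n, dtype=np.int8)
    first_id = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)

    chunks = [_rows(ids, 0, Z, B, L, np.zeros(n, np.int8), C_to, first_id,
                    np.zeros(n, np.int8), alive)]
    for v in range(1, params.n_visits + 1):
        L = step_tvcs(L, Z, C_to, B, params, rng)
        C = step_id(v, Z, B, L, C_to, params, rng, allow_id=allow_id)
        C = np.where(alive, C, 0).astype(np.int8)
        C_to = (C_to + C).astype(np.int8)
        first_id = np.where((C == 1) & ~np.isfinite(first_id), v, first_id)
        Y, _ = step_outcome(v, Z, B, L, first_id, params, rng)
        Y = np.where(alive, Y, 0).astype(np.int8)
        chunks.append(_rows(ids[alive], v, Z[alive], B[alive], L[alive],
                            C[alive], C_to[alive], first_id[alive],
                            Y[alive], alive[alive]))
        alive = alive & (Y == 0)

    panel = pd.concat(chunks, ignore_index=True)
    return panel.sort_values(["id", "visit"], kind="stable").reset_index(drop=True)


def _rows(ids, v, Z, B, L, C, C_to, first_id, Y, at_risk) -> pd.DataFrame:
    vv = float(v)
    return pd.DataFrame({
        "id": ids, "visit": v, "Z": Z.astype(np.int8),
        "B1": B[:, 0], "B2": B[:, 1].astype(np.int8), "B3": B[:, 2],
        "L1": L[:, 0], "L2": L[:, 1], "L3": L[:, 2], "L4": L[:, 3], "L5": L[:, 4],
        "C": C, "C_to": C_to, "first_id_visit": first_id,
        "T_on": np.minimum(vv, first_id), "T_off": np.maximum(vv - first_id, 0.0),
        "Y": Y, "at_risk": at_risk,
    })


# ----------------------------------------------------------------------
# counterfactual truth
# ----------------------------------------------------------------------

@dataclass
class TruthResult:
    rd: float                   # F1(8) - F0(8) under the no-deviation regimens
    mcse: float                 # Monte-Carlo SE of rd
    incidence_control: float
    incidence_experimental: float
    n: int

    def __float__(self) -> float:
        return self.rd


def simulate_truth(scenario: ScenarioSpec | DGMParams, N: int = 2_000_000,
                   seed=None, chunk: int = 250_000) -> TruthResult:
    """Counterfactual risk difference at the final visit.

    Both no-deviation regimens are forward-simulated with the deviation
    process switched off, sharing baseline covariates and shock draws across
    the two arms (common random numbers), and the difference in the
    proportion failing by visit ``n_visits`` is returned with its MC
    standard error.
    """
    params = scenario.params if isinstance(scenario, ScenarioSpec) else scenario
    params.validate()
    rng = _as_rng(seed)
    diff_sum = 0.0
    diff_sq = 0.0
    fail = np.zeros(2)
    done = 0
    while done < N:
        m = min(chunk, N - done)
        f0, f1 = _truth_chunk(params, m, rng)
        d = f1.astype(float) - f0.astype(float)
        diff_sum += d.sum()
        diff_sq += (d * d).sum()
        fail += (f0.sum(), f1.sum())
        done += m
    rd = diff_sum / N
    var = max(diff_sq / N - rd * rd, 0.0)
    return TruthResult(rd=rd, mcse=float(np.sqrt(var / N)),
                       incidence_control=fail[0] / N,
                       incidence_experimental=fail[1] / N, n=N)


def _truth_chunk(params: DGMParams, n: int, rng):
    base = draw_baseline(params, n, rng)
    B = base[["B1", "B2", "B3"]].to_numpy(dtype=float)
    L0 = base[[f"L0{q}" for q in range(1, 6)]].to_numpy(dtype=float)
    first_id = np.full(n, np.inf)
    La = {0: L0.copy(), 1: L0.copy()}
    alive = {0: np.ones(n, dtype=bool), 1: np.ones(n, dtype=bool)}
    Zarm = {0: np.zeros(n, dtype=np.int8), 1: np.ones(n, dtype=np.int8)}
    for v in range(1, params.n_visits + 1):
        eps = _tvc_innovations(params, n, rng)
        u_y = rng.random(n)
        for a in (0, 1):
            Zc = float(a)
            mean = (params.beta0[None, :] + params.beta1[None, :] * Zc
                    + B @ params.beta4.T + params.beta5[None, :] * La[a])
            La[a] = mean + eps
            lam = outcome_hazard(v, Zarm[a], B, La[a], first_id, params)
            died = u_y < lam
            alive[a] = alive[a] & ~(died & alive[a])
    return ~alive[0], ~alive[1]


# ----------------------------------------------------------------------
# intercept tuning (reconstructing prevalence levels)
# ----------------------------------------------------------------------

def ever_id_prevalence(params: DGMParams, arm: int, n: int = 50_000,
                       seed=0) -> float:
    """Proportion of individuals in ``arm`` who ever deviate, with mortality
    and the deviation risk-set respected."""
    rng = _as_rng(seed)
    base = draw_baseline(params, n, rng)
    B = base[["B1", "B2", "B3"]].to_numpy(dtype=float)
    L = base[[f"L0{q}" for q in range(1, 6)]].to_numpy(dtype=float)
    Z = np.full(n, arm, dtype=np.int8)
    C_to = np.zeros(n, dtype=np.int8)
    first_id = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    for v in range(1, params.n_visits + 1):
        L = step_tvcs(L, Z, C_to, B, params, rng)
        C = step_id(v, Z, B, L, C_to, params, rng)
        C = np.where(alive, C, 0).astype(np.int8)
        C_to = (C_to + C).astype(np.int8)
        first_id = np.where((C == 1) & ~np.isfinite(first_id), v, first_id)
        Y, _ = step_outcome(v, Z, B, L, first_id, params, rng)
        alive = alive & ~((Y == 1) & alive)
    return float((C_to > 0).mean())


def tune_intercept(params: DGMParams, target: float, arm: int = 0,
                   n: int = 50_000, seed: int = 0,
                   bracket: tuple[float, float] = (-9.0, 5.0),
                   xtol: float = 1e-3) -> float:
    """Root-find the deviation-model intercept theta0 so that the ever-ID
    prevalence in ``arm`` matches ``target``.

    The prevalence is evaluated with a fixed internal seed so the objective
    is a deterministic, monotone function of theta0.  Raises
    :class:`TuneError` when the target is outside the achievable range on
    the bracket.
    """
    if arm not in params.id_arms:
        raise TuneError(f"arm {arm} cannot deviate under id_arms={params.id_arms}")
    if not 0.0 < target < 1.0:
        raise TuneError(f"target prevalence {target} needs theta0 at infinity")

    def f(t0: float) -> float:
        return ever_id_prevalence(params.replace(theta0=t0), arm, n=n,
                                  seed=seed) - target

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise TuneError(
            f"target prevalence {target} unreachable on theta0 in {bracket}: "
            f"range [{flo + target:.4f}, {fhi + target:.4f}]")
    return float(brentq(f, lo, hi, xtol=xtol))
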