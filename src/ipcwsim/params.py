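"""Parameter containers for the trial data-generating mechanism.

The generator emulates a two-arm 1:1 randomised trial with 8 post-baseline
visits (12-week spacing, so visit 8 is week 96).  Individuals carry three
baseline covariates -- age ``B1``, a binary sex indicator ``B2`` and a
disease-severity (WHO-stage-like) score ``B3`` -- and five time-varying
covariates (TVCs):

``L1``
    log CD4 count: a time-varying confounder (drives both intervention
    deviation and failure).
``L2``
    log CD4/CD8 ratio: the second time-varying confounder, correlated with
    ``L1`` through the innovation terms.
``L3``
    log viral load: an outcome risk factor that does not predict deviation.
``L4``, ``L5``
    total cholesterol and triglycerides: deviation risk factors with no
    direct effect on the outcome.

Intervention deviation (ID) -- the intercurrent event handled by the
hypothetical strategy -- occurs in discrete time from visit 1 onwards with a
logistic hazard, and the failure outcome follows a discrete-time logistic
hazard conditional on survival.  Everything is parameterised here;
:mod:`ipcwsim.dgm` performs the sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

N_BASELINE = 7  # B1, B3, L01..L05 (B2 is generated separately)
N_TVC = 5


class ParameterError(ValueError):
    """Raised when a parameter set violates its structural invariants."""


@dataclass
class DeterministicIDRule:
    """Threshold rule for deterministic intervention deviation.

    Deviation occurs with probability one as soon as the configured TVC
    crosses the threshold, in the configured arms.  This structurally
    violates positivity.
    """

    covariate: int = 0          # index into L1..L5 (0-based)
    threshold: float = 0.0
    direction: str = "below"    # "below": deviate iff L < threshold
    arms: tuple[int, ...] = (0,)

    def triggered(self, L: np.ndarray) -> np.ndarray:
        x = L[:, self.covariate]
        return x < self.threshold if self.direction == "below" else x > self.threshold


@dataclass
class DGMParams:
    """Full numeric parameter set of the data-generating mechanism."""

    # baseline: truncated multivariate normal for (B1, B3, L01..L05)
    mu0: np.ndarray
    Sigma: np.ndarray
    trunc_lo: np.ndarray
    trunc_hi: np.ndarray
    # logistic model for binary B2: expit(rho1*B1 + rho2*B3 + rho3 . L0)
    rho1: float
    rho2: float
    rho3: np.ndarray
    # TVC model, one row per q = 1..5:
    #   L_qv = b0 + b1*Z + (b2 + b3*Z)*C_to(v-1) + b4 . B + b5*L_q(v-1) + eps_q
    beta0: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray
    beta4: np.ndarray           # (5, 3) over (B1, B2, B3)
    beta5: np.ndarray
    xi: np.ndarray              # innovation means, length 5
    Lambda: np.ndarray          # 2x2 innovation covariance of (eps1, eps2)
    sd3: float
    sd4: float
    sd5: float
    # ID hazard: expit(theta0 + theta1*v + theta2*Z + theta3 . B + theta4 . L_v)
    theta0: float
    theta1: float
    theta2: float
    theta3: np.ndarray          # length 3
    theta4: np.ndarray          # length 5 (theta4[2] = 0: L3 never drives ID)
    # outcome hazard:
    #   expit(m0 + m1*Z + (m2 + m3*Z)*T_on + (m4 + m5*Z)*T_off + m6 . B + m7 . L_v)
    mu_out0: float
    mu_out1: float
    mu_out2: float
    mu_out3: float
    mu_out4: float
    mu_out5: float
    mu_out6: np.ndarray         # length 3
    mu_out7: np.ndarray         # length 5 (entries 3, 4 = 0: L4, L5 outcome-inert)
    n_visits: int = 8
    id_arms: tuple[int, ...] = (0,)
    deterministic_id: DeterministicIDRule | None = None

    def __post_init__(self) -> None:
        for name in ("mu0", "Sigma", "trunc_lo", "trunc_hi", "rho3", "beta0",
                     "beta1", "beta2", "beta3", "beta4", "beta5", "xi",
                     "Lambda", "theta3", "theta4", "mu_out6", "mu_out7"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.id_arms = tuple(int(a) for a in self.id_arms)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.mu0.shape != (N_BASELINE,):
            raise ParameterError(f"mu0 must have length {N_BASELINE}")
        if self.Sigma.shape != (N_BASELINE, N_BASELINE):
            raise ParameterError("Sigma must be 7x7")
        _check_psd(self.Sigma, "Sigma")
        _check_psd(self.Lambda, "Lambda")
        if self.Lambda.shape != (2, 2):
            raise ParameterError("Lambda must be 2x2")
        if not np.all(self.trunc_lo < self.trunc_hi):
            raise ParameterError("trunc_lo must be elementwise below trunc_hi")
        if min(self.sd3, self.sd4, self.sd5) < 0:
            raise ParameterError("innovation SDs must be non-negative")
        if self.beta4.shape != (N_TVC, 3):
            raise ParameterError("beta4 must be 5x3")
        for v, n in (("theta3", 3), ("theta4", 5), ("mu_out6", 3), ("mu_out7", 5)):
            if getattr(self, v).shape != (n,):
                raise ParameterError(f"{v} must have length {n}")
        if self.n_visits < 1:
            raise ParameterError("n_visits must be >= 1")
        if not self.id_arms or not set(self.id_arms) <= {0, 1}:
            raise ParameterError("id_arms must be a non-empty subset of {0, 1}")

    def replace(self, **kwargs) -> "DGMParams":
        return replace(self, **kwargs)


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-10) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ParameterError(f"{name} must be a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ParameterError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ParameterError(f"{name} must be positive semi-definite")


# factor names of the one-factor-at-a-time grid; "arm_config" is the composite
# arm factor (arms of ID, arm effect on ID hazard, between-arm post-ID
# differences) that the grid varies as a unit
FACTOR_NAMES = (
    "corr",                 # correlation level between L1 and L2
    "arm_config",           # ctrl | both0 | both_minus | both_plus
    "id_prevalence",        # low | medium | high (calibrated theta0)
    "confounder_id",        # low | medium | high magnitude of (theta41, theta42)
    "confounder_id_sign",   # same | opposite (sign of theta42)
    "deterministic_id",     # no | yes
    "arm_outcome",          # low | medium | high direct arm effect mu1
    "confounder_outcome",   # low | medium | high magnitude of (mu71, mu72)
    "n_obs",                # 200 | 500 | 1000
)


@dataclass
class ScenarioSpec:
    """One simulation scenario: factor levels plus the resolved parameters."""

    scenario_id: int
    factors: dict[str, object]
    params: DGMParams
    n_obs: int = 1000
    label: str = ""

    def differing_factors(self, other: "ScenarioSpec") -> list[str]:
        out = [n for n in FACTOR_NAMES if self.factors.get(n) != other.factors.get(n)]
        return out


def default_method_names() -> list[str]:
    """Names of the default analysis-method catalogue."""
    sets = ["L1L2", "L1", "L2", "L1L3L4L5", "L1L2L3L4L5", "L1*L2*"]
    out = ["ITT", "PP"]
    for s in sets:
        out.append("IPCWu" + s)
    for s in sets:
        out.append("IPCWs" + s)
    return out
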