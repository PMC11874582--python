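"""Scenario configuration: factor levels -> resolved DGM parameter sets.

The shipped default configuration (``config/default.yaml``) encodes the
base-case trial and the level values of every varied factor.  Intercept-like
quantities (deviation-model intercept per prevalence level, outcome
intercept and arm effect, innovation correlation per correlation level, the
deterministic-deviation threshold) were calibrated once against the
base-case data characteristics the framework targets -- see the values
stored under ``calibration_targets`` in the YAML -- using
:func:`ipcwsim.dgm.tune_intercept` and grid search, and are shipped as
plain numbers.

The 18-scenario grid is one-factor-at-a-time: scenario 1 is the base case
and every other scenario changes exactly one factor (the arm configuration
-- which arms deviate, the arm effect on the deviation hazard and the
between-arm post-deviation differences -- counts as a single composite
factor).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .params import (FACTOR_NAMES, DGMParams, DeterministicIDRule,
                     ScenarioSpec)

__all__ = [
    "load_config", "build_params", "scenario_grid", "get_scenario",
    "null_params", "discontinuation_params", "ConfigError",
]

_IDX = {"B1": 0, "B3": 1, "L01": 2, "L02": 3, "L03": 4, "L04": 5, "L05": 6}


class ConfigError(ValueError):
    """Missing or malformed entry in a scenario configuration."""


def load_config(path: str | Path | None = None) -> dict:
    """Load a scenario configuration (the packaged default when no path)."""
    if path is None:
        ref = resources.files("ipcwsim").joinpath("config/default.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def _level(config: dict, group: str, name: object, factor: str):
    levels = config.get("levels", {}).get(group)
    if levels is None:
        raise ConfigError(f"config lacks levels for factor {factor!r}")
    if name not in levels:
        raise ConfigError(f"no value for level {name!r} of factor {factor!r}")
    return levels[name]


def _sigma(base: dict, corr_l1l2: float) -> np.ndarray:
    sd = np.asarray(base["sd0"], dtype=float)
    R = np.eye(7)
    for i_name, j_name, r in base.get("corr0", []):
        i, j = _IDX[i_name], _IDX[j_name]
        R[i, j] = R[j, i] = float(r)
    i, j = _IDX["L01"], _IDX["L02"]
    R[i, j] = R[j, i] = corr_l1l2
    return np.outer(sd, sd) * R


def build_params(config: dict, *, corr: str = "medium",
                 arm_config: str = "ctrl", id_prevalence: str = "medium",
                 confounder_id: str = "medium", confounder_id_sign: str = "same",
                 deterministic_id: str = "no", arm_outcome: str = "medium",
                 confounder_outcome: str = "medium") -> DGMParams:
    """Resolve factor levels into a full numeric parameter set."""
    base = config["base"]
    c = float(_level(config, "corr", corr, "corr"))

    theta4 = np.asarray(base["theta4_base"], dtype=float).copy()
    mag = float(_level(config, "confounder_id", confounder_id, "confounder_id"))
    theta4[0] *= mag
    theta4[1] *= mag
    if confounder_id_sign == "opposite":
        theta4[1] = -theta4[1]
    elif confounder_id_sign != "same":
        raise ConfigError(f"unknown confounder_id_sign {confounder_id_sign!r}")

    mu7 = np.asarray(base["mu7_base"], dtype=float).copy()
    omag = float(_level(config, "confounder_outcome", confounder_outcome,
                        "confounder_outcome"))
    mu7[0] *= omag
    mu7[1] *= omag

    if arm_config == "ctrl":
        id_arms: tuple[int, ...] = (0,)
        theta2 = 0.0
    elif arm_config in ("both0", "both_minus", "both_plus"):
        id_arms = (0, 1)
        key = {"both0": "zero", "both_minus": "minus", "both_plus": "plus"}[arm_config]
        theta2 = float(_level(config, "arm_id", key, "arm_config"))
    else:
        raise ConfigError(f"unknown arm_config {arm_config!r}")

    det = None
    if deterministic_id == "yes":
        d = config.get("levels", {}).get("deterministic")
        if d is None:
            raise ConfigError("config lacks levels for factor 'deterministic_id'")
        det = DeterministicIDRule(covariate=int(d["covariate"]),
                                  threshold=float(d["threshold"]),
                                  direction=d.get("direction", "below"),
                                  arms=tuple(id_arms))
    elif deterministic_id != "no":
        raise ConfigError(f"unknown deterministic_id {deterministic_id!r}")

    sds = np.asarray(base["innovation_sd"], dtype=float)
    Lambda = np.array([[sds[0] ** 2, c * sds[0] * sds[1]],
                       [c * sds[0] * sds[1], sds[1] ** 2]])

    params = DGMParams(
        mu0=base["mu0"], Sigma=_sigma(base, c),
        trunc_lo=base["trunc_lo"], trunc_hi=base["trunc_hi"],
        rho1=base["rho"]["rho1"], rho2=base["rho"]["rho2"],
        rho3=base["rho"]["rho3"],
        beta0=base["beta0"], beta1=base["beta1"], beta2=base["beta2"],
        beta3=base["beta3"], beta4=base["beta4"], beta5=base["beta5"],
        xi=base["xi"], Lambda=Lambda,
        sd3=sds[2], sd4=sds[3], sd5=sds[4],
        theta0=float(_level(config, "id_prevalence", id_prevalence,
                            "id_prevalence")),
        theta1=base["theta1"], theta2=theta2,
        theta3=base["theta3"], theta4=theta4,
        mu_out0=base["mu_out0"],
        mu_out1=float(_level(config, "arm_outcome", arm_outcome, "arm_outcome")),
        mu_out2=base["mu_out2"], mu_out3=base.get("mu_out3", 0.0),
        mu_out4=base["mu_out4"], mu_out5=base.get("mu_out5", 0.0),
        mu_out6=base["mu_out6"], mu_out7=mu7,
        n_visits=int(base.get("n_visits", 8)),
        id_arms=id_arms, deterministic_id=det,
    )
    params.validate()
    return params


def _scenario_from_row(config: dict, row: dict) -> ScenarioSpec:
    factors = {name: row.get(name) for name in FACTOR_NAMES}
    missing = [k for k, v in factors.items() if v is None]
    if missing:
        raise ConfigError(f"scenario {row.get('id')}: missing factor(s) {missing}")
    params = build_params(
        config, corr=factors["corr"], arm_config=factors["arm_config"],
        id_prevalence=factors["id_prevalence"],
        confounder_id=factors["confounder_id"],
        confounder_id_sign=factors["confounder_id_sign"],
        deterministic_id=factors["deterministic_id"],
        arm_outcome=factors["arm_outcome"],
        confounder_outcome=factors["confounder_outcome"])
    return ScenarioSpec(scenario_id=int(row["id"]), factors=factors,
                        params=params, n_obs=int(factors["n_obs"]),
                        label=row.get("label", ""))


def scenario_grid(config: dict | None = None) -> list[ScenarioSpec]:
    """All scenarios of the configured grid, ordered by scenario id."""
    if config is None:
        config = load_config()
    rows = config.get("scenarios")
    if not rows:
        raise ConfigError("config lists no scenarios")
    grid = [_scenario_from_row(config, row) for row in rows]
    return sorted(grid, key=lambda s: s.scenario_id)


def get_scenario(scenario_id: int, config: dict | None = None) -> ScenarioSpec:
    for s in scenario_grid(config):
        if s.scenario_id == scenario_id:
            return s
    raise ConfigError(f"no scenario with id {scenario_id}")


# ----------------------------------------------------------------------
# special parameterisations used for validation studies
# ----------------------------------------------------------------------

def null_params(config: dict | None = None) -> DGMParams:
    """Fully null trial: no treatment effect anywhere and non-informative,
    outcome-inert deviation.

    All arm effects (TVCs, deviation hazard, outcome hazard) are zero, the
    deviation hazard depends on nothing but its intercept and visit, and
    deviating changes neither the covariate paths nor the failure hazard
    (on- and off-treatment time act identically).  Under this mechanism the
    true risk difference is zero and ITT, PP and every IPCW variant are all
    unbiased, which makes it the natural calibration check for the whole
    pipeline.
    """
    if config is None:
        config = load_config()
    p = build_params(config)
    return p.replace(
        beta1=np.zeros(5), beta2=np.zeros(5), beta3=np.zeros(5),
        theta2=0.0, theta3=np.zeros(3), theta4=np.zeros(5),
        theta0=-3.0,   # keeps ever-deviation prevalence near the base case
        mu_out1=0.0, mu_out2=p.mu_out2, mu_out3=0.0,
        mu_out4=p.mu_out2, mu_out5=0.0,   # off-treatment time acts like on-
        id_arms=(0, 1),
    )


def discontinuation_params(config: dict | None = None) -> DGMParams:
    """Confounded single-arm-deviation variant where deviation means
    stopping effective therapy.

    Deviation remains driven by the confounders (worse prognosis -> more
    likely to stop), but after deviating the covariate paths deteriorate
    and time off treatment carries a *higher* hazard than time on.  Under
    this mechanism the observed control arm does worse than its
    no-deviation counterfactual, so ITT is biased downward (negative),
    while per-protocol censoring still selects better-prognosis survivors
    and is biased upward; correctly specified IPCW remains unbiased.
    """
    if config is None:
        config = load_config()
    p = build_params(config)
    return p.replace(
        beta2=np.array([-0.15, -0.10, 0.30, -0.05, -0.05]),
        mu_out4=p.mu_out2 + float(config["base"].get("discontinuation_mu4_shift", 0.12)),
    )
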