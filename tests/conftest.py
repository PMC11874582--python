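import numpy as np
import pandas as pd
import pytest

from ipcwsim import config as config_mod
from ipcwsim.params import DGMParams


@pytest.fixture(scope="session")
def cfg():
    return config_mod.load_config()


@pytest.fixture(scope="session")
def base_scenario(cfg):
    return config_mod.get_scenario(1, cfg)


@pytest.fixture(scope="session")
def base_panel(base_scenario):
    """One base-case panel, shared across read-only tests."""
    from ipcwsim.dgm import simulate_trial
    return simulate_trial(base_scenario, seed=20240901)


def make_params(**overrides) -> DGMParams:
    """Minimal, fully inert parameter set; tests override what they probe."""
    defaults = dict(
        mu0=np.zeros(7), Sigma=np.zeros((7, 7)),
        trunc_lo=np.full(7, -np.inf), trunc_hi=np.full(7, np.inf),
        rho1=0.0, rho2=0.0, rho3=np.zeros(5),
        beta0=np.zeros(5), beta1=np.zeros(5), beta2=np.zeros(5),
        beta3=np.zeros(5), beta4=np.zeros((5, 3)), beta5=np.zeros(5),
        xi=np.zeros(5), Lambda=np.zeros((2, 2)), sd3=0.0, sd4=0.0, sd5=0.0,
        theta0=-50.0, theta1=0.0, theta2=0.0, theta3=np.zeros(3),
        theta4=np.zeros(5),
        mu_out0=-50.0, mu_out1=0.0, mu_out2=0.0, mu_out3=0.0,
        mu_out4=0.0, mu_out5=0.0, mu_out6=np.zeros(3), mu_out7=np.zeros(5),
        n_visits=8, id_arms=(0, 1),
    )
    defaults.update(overrides)
    return DGMParams(**defaults)


def toy_panel(rows: list[dict]) -> pd.DataFrame:
    """Build a hand-written panel; missing columns are filled inertly."""
    df = pd.DataFrame(rows)
    defaults = {"Z": 0, "B1": 0.0, "B2": 0, "B3": 0.0,
                "L1": 0.0, "L2": 0.0, "L3": 0.0, "L4": 0.0, "L5": 0.0,
                "C": 0, "C_to": 0, "first_id_visit": np.inf,
                "Y": 0, "at_risk": True}
    for col, val in defaults.items():
        if col not in df:
            df[col] = val
    df["T_on"] = np.minimum(df["visit"], df["first_id_visit"])
    df["T_off"] = np.maximum(df["visit"] - df["first_id_visit"], 0)
    return df
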