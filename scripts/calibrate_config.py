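"""Re-derive the calibrated intercepts in config/default.yaml.

Maintainer tool: root-finds the deviation-model intercepts, outcome
intercept and arm effects, innovation correlations and the deterministic
threshold against the data-characteristic targets stored under
``calibration_targets`` in the YAML, and prints the values to transcribe.
Not part of the test or acceptance path.
"""
import numpy as np
from scipy.optimize import brentq

from ipcwsim import config as cm
from ipcwsim.dgm import (_as_rng, draw_baseline, ever_id_prevalence,
                         simulate_trial, step_id, step_outcome, step_tvcs)

N = 60_000
SEED = 12345

def fail_prevalence(params, arm, n=N, seed=SEED):
    rng = _as_rng(seed)
    base = draw_baseline(params, n, rng)
    B = base[["B1","B2","B3"]].to_numpy(float)
    L = base[[f"L0{q}" for q in range(1,6)]].to_numpy(float)
    Z = np.full(n, arm, np.int8)
    C_to = np.zeros(n, np.int8); first = np.full(n, np.inf); alive = np.ones(n, bool)
    for v in range(1, params.n_visits+1):
        L = step_tvcs(L, Z, C_to, B, params, rng)
        C = step_id(v, Z, B, L, C_to, params, rng)
        C = np.where(alive, C, 0).astype(np.int8)
        C_to = (C_to + C).astype(np.int8)
        first = np.where((C==1) & ~np.isfinite(first), v, first)
        Y, _ = step_outcome(v, Z, B, L, first, params, rng)
        alive = alive & ~((Y==1) & alive)
    return float((~alive).mean())

def pooled_corr(params, n=40_000, seed=SEED):
    panel = simulate_trial(params, seed, n=n)
    fu = panel[panel.visit >= 1]
    return float(np.corrcoef(fu.L1, fu.L2)[0,1])

cfg = cm.load_config()
tgt = cfg["calibration_targets"]

# --- 1. correlation levels ---
corr_vals = {}
for lvl, target in tgt["corr_L1_L2"].items():
    def f(c):
        cfg["levels"]["corr"]["medium"] = float(c)
        p = cm.build_params(cfg, corr="medium")
        return pooled_corr(p) - target
    corr_vals[lvl] = brentq(f, -0.2, 0.995, xtol=2e-3)
    print("corr", lvl, "->", round(corr_vals[lvl], 4))
for lvl, v in corr_vals.items():
    cfg["levels"]["corr"][lvl] = float(v)

# --- 2 & 3 iterate: theta0 (medium) and mu_out0/mu_out1 ---
for it in range(2):
    p = cm.build_params(cfg)
    def fprev(t0):
        return ever_id_prevalence(p.replace(theta0=t0), 0, n=N, seed=SEED) - tgt["control_ever_id_prevalence"]["medium"]
    t0_med = brentq(fprev, -9, 4, xtol=1e-3)
    cfg["levels"]["id_prevalence"]["medium"] = float(t0_med)
    print(f"iter {it}: theta0 medium -> {t0_med:.4f}")
    p = cm.build_params(cfg)
    def f0(m0):
        return fail_prevalence(p.replace(mu_out0=m0), 0) - tgt["outcome_prevalence_control"]
    m0 = brentq(f0, -7, 0, xtol=1e-3)
    cfg["base"]["mu_out0"] = float(m0)
    print(f"iter {it}: mu_out0 -> {m0:.4f}")
    p = cm.build_params(cfg)
    def f1(m1):
        return fail_prevalence(p.replace(mu_out1=m1), 1) - tgt["outcome_prevalence_experimental"]
    m1 = brentq(f1, -2.5, 1, xtol=1e-3)
    cfg["levels"]["arm_outcome"]["medium"] = float(m1)
    print(f"iter {it}: mu_out1 medium -> {m1:.4f}")

# --- 4. theta0 low/high ---
p = cm.build_params(cfg)
for lvl in ("low", "high"):
    target = tgt["control_ever_id_prevalence"][lvl]
    t0 = brentq(lambda t: ever_id_prevalence(p.replace(theta0=t), 0, n=N, seed=SEED) - target, -9, 4, xtol=1e-3)
    cfg["levels"]["id_prevalence"][lvl] = float(t0)
    print("theta0", lvl, "->", round(t0, 4))

# --- 5. mu1 low/high: exp-arm incidence 0.146 / 0.089 ---
p = cm.build_params(cfg)
for lvl, target in (("low", 0.146), ("high", 0.089)):
    m1 = brentq(lambda m: fail_prevalence(p.replace(mu_out1=m), 1) - target, -2.5, 1, xtol=1e-3)
    cfg["levels"]["arm_outcome"][lvl] = float(m1)
    print("mu1", lvl, "->", round(m1, 4))

# --- 6. deterministic threshold: prevalence 0.387 ---
p = cm.build_params(cfg, deterministic_id="yes")
def fdet(t):
    p.deterministic_id.threshold = float(t)
    return ever_id_prevalence(p, 0, n=N, seed=SEED) - tgt["control_ever_id_prevalence"]["medium"]
thr = brentq(fdet, 3.0, 8.0, xtol=2e-3)
cfg["levels"]["deterministic"]["threshold"] = float(thr)
print("det threshold ->", round(thr, 4))

print("\nFINAL:")
print("corr:", {k: round(v,4) for k,v in cfg["levels"]["corr"].items()})
print("id_prevalence:", {k: round(v,4) for k,v in cfg["levels"]["id_prevalence"].items()})
print("arm_outcome:", {k: round(v,4) for k,v in cfg["levels"]["arm_outcome"].items()})
print("mu_out0:", round(cfg["base"]["mu_out0"], 4))
print("det threshold:", round(cfg["levels"]["deterministic"]["threshold"], 4))
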