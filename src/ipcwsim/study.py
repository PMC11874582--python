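"""Study engine: scenarios x repetitions x methods with disjoint seed streams.

Seed policy
-----------
All randomness derives from one master seed through ``numpy``'s
``SeedSequence`` spawn keys, so streams are provably disjoint:

* repetition ``r`` uses ``SeedSequence(master, spawn_key=(0, r))`` -- the
  *same* stream for every scenario, so results are correlated within a
  repetition across scenarios (common random numbers);
* the truth computation for scenario ``s`` uses
  ``SeedSequence(master, spawn_key=(1, s))``, which never overlaps any
  repetition stream.

Within a repetition one panel is simulated per scenario and every analysis
method is applied to that same panel.  Estimates are appended to
``estimates.csv`` as repetitions complete, so an interrupted run can be
resumed; a resumed run produces output identical to an uninterrupted one
because each (scenario, repetition) pair is self-seeding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as config_mod
from .dgm import simulate_trial, simulate_truth
from .estimators import run_methods
from .params import ScenarioSpec
from .weighting import MethodSpec, default_catalogue

__all__ = ["StudyConfig", "run_study", "rep_seed", "truth_seed",
           "ConfigMismatchError"]

log = logging.getLogger(__name__)

ESTIMATE_COLUMNS = ["scenario_id", "rep", "method", "rd", "se", "ci_low",
                    "ci_high", "converged", "n_censored", "mean_weight",
                    "max_weight", "flags"]


class ConfigMismatchError(RuntimeError):
    """Existing partial output was produced under a different configuration."""


def rep_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    """Stream for repetition ``rep`` (shared across scenarios)."""
    return np.random.SeedSequence(master_seed, spawn_key=(0, rep))


def truth_seed(master_seed: int, scenario_id: int) -> np.random.SeedSequence:
    """Stream for the truth computation of one scenario (disjoint from all
    repetition streams by the purpose component of the spawn key)."""
    return np.random.SeedSequence(master_seed, spawn_key=(1, scenario_id))


@dataclass
class StudyConfig:
    scenarios: list[ScenarioSpec]
    n_reps: int = 1000
    methods: list[MethodSpec] = field(default_factory=default_catalogue)
    master_seed: int = 20240901
    truth_n: int = 2_000_000
    out_dir: Path = Path("results")
    visit_terms: str = "indicator"
    f_visit: str = "linear"

    def digest(self) -> str:
        """Stable hash of everything that determines the output."""
        # n_reps is deliberately excluded: completing an interrupted run is
        # the whole point of resume, and repetitions are self-seeding
        payload = {
            "master_seed": self.master_seed,
            "truth_n": self.truth_n, "visit_terms": self.visit_terms,
            "f_visit": self.f_visit,
            "methods": [m.name for m in self.methods],
            "scenarios": [
                {"id": s.scenario_id, "n_obs": s.n_obs,
                 "params": _params_payload(s.params)}
                for s in self.scenarios],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _params_payload(p) -> dict:
    out = {}
    for name, val in vars(p).items():
        if isinstance(val, np.ndarray):
            out[name] = val.tolist()
        elif name == "deterministic_id" and val is not None:
            out[name] = vars(val).copy()
            out[name]["arms"] = list(out[name]["arms"])
        else:
            out[name] = val if not isinstance(val, tuple) else list(val)
    return out


def run_study(cfg: StudyConfig, resume: bool = False
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the full experiment; returns (estimates, truth) frames.

    Per scenario the truth is computed once; per repetition one panel is
    simulated and every catalogue method applied to it.  Repetition-level
    failures are logged and the run continues.  With ``resume=True``,
    completed (scenario, repetition) pairs found in the output directory
    are skipped after verifying the configuration hash.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hash_file = out / "study_hash.json"
    est_file = out / "estimates.csv"
    truth_file = out / "truth.csv"
    fail_log = out / "failures.log"

    digest = cfg.digest()
    done: set[tuple[int, int]] = set()
    old_rows: pd.DataFrame | None = None
    if est_file.exists():
        if not resume:
            raise FileExistsError(f"{est_file} exists; pass resume=True to continue")
        if not hash_file.exists() or json.loads(hash_file.read_text())["sha256"] != digest:
            raise ConfigMismatchError(
                "existing output was produced under a different configuration")
        old_rows = pd.read_csv(est_file)
        old_rows["flags"] = old_rows["flags"].fillna("").astype(str)
        counts = old_rows.groupby(["scenario_id", "rep"]).size()
        full = counts[counts == len(cfg.methods)]
        done = set(full.index)
        old_rows = old_rows.set_index(["scenario_id", "rep"]).loc[
            list(done)].reset_index() if done else None
    hash_file.write_text(json.dumps({"sha256": digest}))

    # truth: one disjoint stream per scenario (reused on resume if complete)
    wanted_ids = [s.scenario_id for s in cfg.scenarios]
    truth_df = None
    if resume and truth_file.exists():
        prev = pd.read_csv(truth_file)
        if sorted(prev["scenario_id"]) == sorted(wanted_ids) and \
                prev["n"].eq(cfg.truth_n).all():
            truth_df = prev
    if truth_df is None:
        truths = []
        for scn in cfg.scenarios:
            res = simulate_truth(scn, N=cfg.truth_n,
                                 seed=np.random.default_rng(
                                     truth_seed(cfg.master_seed, scn.scenario_id)))
            truths.append({"scenario_id": scn.scenario_id, "rd_true": res.rd,
                           "mcse": res.mcse,
                           "incidence_control": res.incidence_control,
                           "incidence_experimental": res.incidence_experimental,
                           "n": res.n})
            log.info("truth scenario %d: RD=%.5f (MCSE %.5f)",
                     scn.scenario_id, res.rd, res.mcse)
        truth_df = pd.DataFrame(truths)
        truth_df.to_csv(truth_file, index=False)

    method_rank = {m.name: i for i, m in enumerate(cfg.methods)}

    def _write(rows: list[dict]) -> pd.DataFrame:
        est = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
        if old_rows is not None:
            parts = [old_rows[ESTIMATE_COLUMNS]] + ([est] if len(est) else [])
            est = pd.concat(parts, ignore_index=True)
        est["_mr"] = est["method"].map(method_rank)
        est = est.sort_values(["scenario_id", "rep", "_mr"],
                              kind="stable").drop(columns="_mr").reset_index(drop=True)
        est.to_csv(est_file, index=False)
        return est

    new_rows: list[dict] = []
    failures: list[str] = []
    est = _write(new_rows)
    for scn in cfg.scenarios:
        changed = False
        for rep in range(cfg.n_reps):
            if (scn.scenario_id, rep) in done:
                continue
            rng = np.random.default_rng(rep_seed(cfg.master_seed, rep))
            panel = simulate_trial(scn, rng)
            for rec in run_methods(panel, cfg.methods,
                                   scenario_id=scn.scenario_id, rep=rep,
                                   visit_terms=cfg.visit_terms,
                                   f_visit=cfg.f_visit):
                new_rows.append(vars(rec))
                if not rec.converged:
                    failures.append(f"scenario={scn.scenario_id} rep={rep} "
                                    f"method={rec.method} flags={rec.flags}")
            changed = True
        if changed:
            est = _write(new_rows)   # checkpoint after each scenario
        log.info("scenario %d done", scn.scenario_id)
    est = _write(new_rows)
    if failures:
        fail_log.write_text("\n".join(failures) + "\n")
    return est, truth_df


def default_study(scenario_ids: list[int] | None = None, **kwargs) -> StudyConfig:
    """StudyConfig over the shipped scenario grid (optionally a subset)."""
    grid = config_mod.scenario_grid()
    if scenario_ids is not None:
        grid = [s for s in grid if s.scenario_id in scenario_ids]
    return StudyConfig(scenarios=grid, **kwargs)
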