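"""Simulated agent cohorts and parameter-recovery experiments.

The cohort generator is the package's test bed: it draws agents with
known (nu, beta, omega) and an individual psychometric threshold, runs
each through the 12 x 30 conditioning/extinction schedule, and lets the
fitting machinery try to recover the generating parameters.

Default distributions are calibrated to the scale of real data: log nu ~
Normal(log 0.6, 1), so that the fraction of agents with nu > 1 is about
30% with a majority weighting sensory evidence over the prior; log beta ~
Normal(log 8, 0.25); omega fixed at -4.2; and log10 thresholds ~
Normal(-1.05, 0.25), i.e. thresholds around 0.09 mA with right-skewed
positive spread.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitFailureError, ModelDivergenceError
from .inversion import PriorSpec, classify_weighting, default_priors, fit_map
from .psychophysics import PsychometricCurve
from .response_model import ObsParams, Session, simulate_agent
from .task_schedule import (
    default_block_compositions,
    derive_trial_intensities,
    generate_schedule,
)

__all__ = [
    "CohortSpec",
    "RecoveryReport",
    "sample_cohort",
    "generate_cohort_sessions",
    "recovery_experiment",
]


@dataclass(frozen=True)
class CohortSpec:
    """Distributional specification of a simulated cohort.

    All location/scale pairs live on the log (nu, beta) or log10
    (threshold) scale; a zero SD collapses the distribution to a point
    mass.  omega is a point mass by default.
    """

    n_agents: int = 50
    log_nu_mean: float = math.log(0.6)
    log_nu_sd: float = 1.0
    log_beta_mean: float = math.log(8.0)
    log_beta_sd: float = 0.25
    omega_mean: float = -4.2
    omega_sd: float = 0.0
    log10_threshold_mean: float = -1.05
    log10_threshold_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        for sd in (self.log_nu_sd, self.log_beta_sd, self.omega_sd,
                   self.log10_threshold_sd):
            if sd < 0:
                raise ValueError("scale parameters must be non-negative")


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw agent parameters; returns one row per agent.

    Columns: agent_id, nu, beta, omega, threshold_T (log10 mA),
    threshold_mA, label (weighting classification of the true nu).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_agents
    log_nu = spec.log_nu_mean + spec.log_nu_sd * rng.standard_normal(n)
    log_beta = spec.log_beta_mean + spec.log_beta_sd * rng.standard_normal(n)
    omega = spec.omega_mean + spec.omega_sd * rng.standard_normal(n)
    thr = (
        spec.log10_threshold_mean
        + spec.log10_threshold_sd * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "agent_id": [f"agent{i:03d}" for i in range(n)],
            "nu": np.exp(log_nu),
            "beta": np.exp(log_beta),
            "omega": omega,
            "threshold_T": thr,
            "threshold_mA": 10.0**thr,
            "label": [classify_weighting(v) for v in np.exp(log_nu)],
        }
    )


def _agent_curve(threshold_T: float) -> PsychometricCurve:
    return PsychometricCurve(threshold_T=threshold_T)


def generate_cohort_sessions(
    spec: CohortSpec,
    priors: PriorSpec | None = None,
) -> tuple[list[Session], list[PsychometricCurve], dict]:
    """Simulate one session per agent on its own derived intensities.

    Returns the sessions, the per-agent psychometric curves, and a
    ground-truth manifest pairing each session with its generating
    parameters and seeds.  The manifest is for reporting only — fitting
    code never reads it.  Agents whose simulation diverges are recorded
    in the manifest with ``diverged`` set and skipped.
    """
    priors = priors or default_priors()
    params = sample_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)
    comps = default_block_compositions()
    sessions: list[Session] = []
    curves: list[PsychometricCurve] = []
    manifest: dict = {"spec": vars(spec).copy(), "agents": []}
    for row in params.itertuples():
        curve = _agent_curve(row.threshold_T)
        sched_seed = int(rng.integers(2**31 - 1))
        resp_seed = int(rng.integers(2**31 - 1))
        schedule = generate_schedule(
            comps, derive_trial_intensities(curve), seed=sched_seed
        )
        hgf = priors.hgf_params(row.omega)
        entry = {
            "agent_id": row.agent_id,
            "nu": row.nu,
            "beta": row.beta,
            "omega": row.omega,
            "threshold_T": row.threshold_T,
            "schedule_seed": sched_seed,
            "response_seed": resp_seed,
            "diverged": False,
        }
        try:
            session, _ = simulate_agent(
                schedule, curve, hgf,
                ObsParams(nu=row.nu, beta_slope=row.beta),
                seed=resp_seed, subject_id=row.agent_id,
            )
        except ModelDivergenceError as err:
            entry["diverged"] = True
            entry["diverged_at"] = err.trial
            manifest["agents"].append(entry)
            continue
        sessions.append(session)
        curves.append(curve)
        manifest["agents"].append(entry)
    return sessions, curves, manifest


@dataclass
class RecoveryReport:
    """True-vs-recovered parameter statistics for a simulated cohort."""

    table: pd.DataFrame                  # per-agent true and recovered values
    spearman_log_nu: float
    pearson_log_nu: float
    bias_log_nu: float
    rmse_log_nu: float
    confusion: dict                      # nu > 1 classification counts
    n_fit: int
    n_failed: int
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "summary": {
                "spearman_log_nu": self.spearman_log_nu,
                "pearson_log_nu": self.pearson_log_nu,
                "bias_log_nu": self.bias_log_nu,
                "rmse_log_nu": self.rmse_log_nu,
                "confusion": self.confusion,
                "n_fit": self.n_fit,
                "n_failed": self.n_failed,
                "seed": self.seed,
            },
            "agents": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def recovery_experiment(
    spec: CohortSpec | None = None,
    priors: PriorSpec | None = None,
    *,
    n_starts: int = 4,
    fit_seed: int | None = None,
) -> RecoveryReport:
    """Generate a cohort, fit every agent, and compare true vs recovered.

    The fit never sees the ground-truth manifest; recovery quality is
    summarised by rank and linear correlations of log nu, its bias and
    RMSE, and the confusion counts of the nu > 1 classification.
    """
    spec = spec or CohortSpec()
    priors = priors or default_priors()
    sessions, curves, manifest = generate_cohort_sessions(spec, priors)
    truth = {a["agent_id"]: a for a in manifest["agents"]}
    rng = np.random.default_rng(spec.seed if fit_seed is None else fit_seed)
    rows = []
    n_failed = 0
    for session, curve in zip(sessions, curves):
        t = truth[session.subject_id]
        try:
            fit = fit_map(
                session, curve, priors,
                n_starts=n_starts, seed=int(rng.integers(2**31 - 1)),
            )
        except FitFailureError:
            n_failed += 1
            continue
        rows.append(
            {
                "agent_id": session.subject_id,
                "true_nu": t["nu"],
                "true_beta": t["beta"],
                "true_omega": t["omega"],
                "fit_nu": fit.nu,
                "fit_beta": fit.beta,
                "fit_omega": fit.omega,
                "loglik": fit.loglik,
                "lme": fit.lme,
                "aic": fit.aic,
            }
        )
    table = pd.DataFrame(rows)
    lt, lf = np.log(table.true_nu), np.log(table.fit_nu)
    rho = float(stats.spearmanr(lt, lf).statistic) if len(table) > 2 else float("nan")
    r = float(stats.pearsonr(lt, lf).statistic) if len(table) > 2 else float("nan")
    confusion = {
        "true_gt1_fit_gt1": int(((table.true_nu > 1) & (table.fit_nu > 1)).sum()),
        "true_gt1_fit_le1": int(((table.true_nu > 1) & (table.fit_nu <= 1)).sum()),
        "true_le1_fit_gt1": int(((table.true_nu <= 1) & (table.fit_nu > 1)).sum()),
        "true_le1_fit_le1": int(((table.true_nu <= 1) & (table.fit_nu <= 1)).sum()),
    }
    return RecoveryReport(
        table=table,
        spearman_log_nu=rho,
        pearson_log_nu=r,
        bias_log_nu=float((lf - lt).mean()),
        rmse_log_nu=float(np.sqrt(((lf - lt) ** 2).mean())),
        confusion=confusion,
        n_fit=len(table),
        n_failed=n_failed,
        seed=spec.seed,
    )
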