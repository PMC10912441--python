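"""End-to-end orchestration: simulate -> classify -> sample -> estimate.

Also hosts the estimation wrapper shared by the full registry path and the
fast simulated-cohort experiments (parameter recovery, null calibration).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig
from .exposure import ExposureTimeline, Taxonomy, build_exposure_timeline, default_taxonomy
from .pseudo import ModelFit, RankError, ResultRow, bonferroni_ci, fit_gee_log, pseudo_values
from .registry import RegistrySnapshot
from .sampler import SamplingLog, build_followup, cap_exposed, draw_matched_controls, find_exposed
from .synth import generate_health_events, generate_outcomes, generate_population, simulate_cohort

logger = logging.getLogger(__name__)

FULL_COVARIATES = [
    "income",
    "neighborhood_resources",
    "immigration_background",
    "refugee_status",
    "education",
    "psychiatric_disease",
    "interparental_violence",
    "substance_abuse",
    "parental_maltreatment",
]
PARSIMONIOUS_COVARIATES = [
    c for c in FULL_COVARIATES if c not in ("immigration_background", "refugee_status")
]
MODEL_KINDS = {"full": FULL_COVARIATES, "parsimonious": PARSIMONIOUS_COVARIATES}


@dataclass
class RunConfig:
    categories: list | None = None  # None -> all taxonomy categories
    model_kinds: tuple = ("full", "parsimonious")
    m_tests: int = 33
    ratio: int = 5
    cap: int = 100_000
    tau_mode: str = "grid5"  # or "single"
    seed: int = 0

    def __post_init__(self):
        if self.ratio < 1:
            raise ConfigurationError("ratio must be >= 1")
        if self.m_tests < 1:
            raise ConfigurationError("m_tests must be >= 1")
        for kind in self.model_kinds:
            if kind not in MODEL_KINDS:
                raise ConfigurationError(f"unknown model kind {kind!r}")
        if self.tau_mode not in ("grid5", "single"):
            raise ConfigurationError("tau_mode must be 'grid5' or 'single'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def choose_taus(time: np.ndarray, mode: str = "grid5") -> np.ndarray:
    """Evaluation times: {0.2,...,1.0} quantiles of follow-up times, or the
    single end-of-follow-up point."""
    time = np.asarray(time, dtype=float)
    if mode == "single":
        return np.array([float(np.max(time))])
    qs = np.quantile(time, [0.2, 0.4, 0.6, 0.8, 1.0])
    return np.unique(qs)


def _design(fu: pd.DataFrame, covariates: list) -> tuple[np.ndarray, list, list]:
    """Exposure + covariates (+ calendar-period dummies); drops constant
    columns (small synthetic cohorts routinely yield empty cells)."""
    cols = {"exposed": fu["exposed"].to_numpy(dtype=float)}
    for c in covariates:
        cols[c] = fu[c].to_numpy(dtype=float)
    if "calendar_period" in fu.columns:
        periods = np.sort(fu["calendar_period"].unique())
        for p in periods[1:]:
            cols[f"period_{int(p)}"] = (fu["calendar_period"] == p).to_numpy(dtype=float)
    dropped = [name for name, v in cols.items() if name != "exposed" and np.nanstd(v) == 0]
    kept = {k: v for k, v in cols.items() if k not in dropped}
    X = np.column_stack(list(kept.values()))
    return X, list(kept.keys()), dropped


def estimate_from_followup(
    fu: pd.DataFrame,
    category: str,
    model_kind: str,
    m_tests: int = 33,
    tau_mode: str = "grid5",
    taus: np.ndarray | None = None,
    cluster: str = "",
) -> ResultRow:
    """Fit one model on a follow-up table and package a result row."""
    row = ResultRow(category=category, model_kind=model_kind, m_tests=m_tests, cluster=cluster)
    if not len(fu):
        return row
    covariates = [c for c in MODEL_KINDS[model_kind] if c in fu.columns]
    fu = fu.dropna(subset=covariates + ["time", "event", "exposed"]).reset_index(drop=True)
    if not len(fu):
        return row
    row.n = len(fu)
    row.n_events = int((fu["event"] == 1).sum())
    if taus is None:
        taus = choose_taus(fu["time"].to_numpy(), tau_mode)
    strata = fu["calendar_period"].to_numpy() if "calendar_period" in fu.columns else None
    pv = pseudo_values(fu["time"].to_numpy(), fu["event"].to_numpy(), taus, strata=strata)
    X, names, dropped = _design(fu, covariates)
    try:
        fit = fit_gee_log(pv, X, fu["family_id"].to_numpy(), names=names, tau_grid=taus)
    except (RankError, ValueError) as exc:
        logger.warning("%s/%s: %s", category, model_kind, exc)
        row.extra["error"] = str(exc)
        return row
    row.converged = bool(fit.converged)
    row.extra["dropped_covariates"] = dropped
    row.extra["n_clusters"] = fit.n_clusters
    if fit.converged:
        beta = fit.coef("exposed")
        se = fit.se("exposed")
        row.rr = float(np.exp(beta))
        row.ci95, row.ci_corrected = bonferroni_ci(beta, se, m_tests)
        row.extra["se"] = se
    return row


def build_cohort(
    snapshot: RegistrySnapshot,
    timeline: ExposureTimeline,
    category: str,
    run_cfg: RunConfig,
    rng: np.random.Generator,
    log: SamplingLog | None = None,
) -> pd.DataFrame:
    log = log or SamplingLog()
    idx = find_exposed(timeline, snapshot, category, log=log)
    matched = draw_matched_controls(
        idx, snapshot, timeline, category, ratio=run_cfg.ratio, seed=rng, log=log
    )
    matched = cap_exposed(matched, run_cfg.cap, seed=rng)
    return build_followup(matched, snapshot.outcomes, timeline.months[-1], log=log)


def run_category(
    snapshot: RegistrySnapshot,
    timeline: ExposureTimeline,
    category: str,
    run_cfg: RunConfig,
    rng: np.random.Generator | None = None,
    taxonomy: Taxonomy | None = None,
) -> tuple[list, SamplingLog]:
    """Build the matched cohort for one category and fit all model kinds."""
    taxonomy = default_taxonomy() if taxonomy is None else taxonomy
    if category not in timeline.categories:
        raise KeyError(f"category {category!r} absent from taxonomy/timeline")
    rng = np.random.default_rng(run_cfg.seed) if rng is None else rng
    log = SamplingLog()
    fu = build_cohort(snapshot, timeline, category, run_cfg, rng, log=log)
    cluster = taxonomy.rule_for(category).cluster_name
    rows = [
        estimate_from_followup(
            fu, category, kind, m_tests=run_cfg.m_tests, tau_mode=run_cfg.tau_mode, cluster=cluster
        )
        for kind in run_cfg.model_kinds
    ]
    logger.info(
        "%s: %d sets, %d follow-up rows, %d dropped short of controls",
        category, log.n_sets, len(fu), log.n_dropped_short_of_controls,
    )
    return rows, log


def run_all(
    snapshot: RegistrySnapshot,
    timeline: ExposureTimeline,
    run_cfg: RunConfig,
    taxonomy: Taxonomy | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Report over all configured categories (one row per category x model)."""
    taxonomy = default_taxonomy() if taxonomy is None else taxonomy
    categories = run_cfg.categories or list(timeline.categories)
    rng = np.random.default_rng(run_cfg.seed)
    records = []
    for cat in categories:
        rows, log = run_category(snapshot, timeline, cat, run_cfg, rng=rng, taxonomy=taxonomy)
        for r in rows:
            records.append(
                {
                    "cluster": r.cluster,
                    "category": r.category,
                    "model": r.model_kind,
                    "rr": r.rr,
                    "lo95": r.ci95[0],
                    "hi95": r.ci95[1],
                    "lo_corrected": r.ci_corrected[0],
                    "hi_corrected": r.ci_corrected[1],
                    "n": r.n,
                    "n_events": r.n_events,
                    "converged": r.converged,
                    "significant": r.significant_uncorrected,
                    "significant_corrected": r.significant_corrected,
                }
            )
    report = pd.DataFrame(records)
    manifest = {
        "seed": run_cfg.seed,
        "m_tests": run_cfg.m_tests,
        "ratio": run_cfg.ratio,
        "cap": run_cfg.cap,
        "tau_mode": run_cfg.tau_mode,
        "categories": list(categories),
        "model_kinds": list(run_cfg.model_kinds),
    }
    return report, manifest


def simulate_registry(config: SimConfig, taxonomy: Taxonomy | None = None):
    """SimConfig -> (snapshot with events/outcomes, exposure timeline)."""
    taxonomy = default_taxonomy() if taxonomy is None else taxonomy
    rng = np.random.default_rng(config.seed)
    snapshot = generate_population(config, rng=rng)
    dx, rx = generate_health_events(snapshot, config, taxonomy=taxonomy, rng=rng)
    snapshot.diagnoses = dx
    snapshot.prescriptions = rx
    timeline = build_exposure_timeline(
        taxonomy, dx, rx, snapshot.links, config.study_start, config.study_end, config.burn_in_years
    )
    snapshot.outcomes = generate_outcomes(snapshot, timeline, config, rng=rng)
    return snapshot, timeline


# ---------------------------------------------------------------------------
# simulation experiments
# ---------------------------------------------------------------------------

def _fit_simulated_cohort(df: pd.DataFrame, tau: float, m_tests: int) -> tuple[float, float, bool]:
    """(log rr, se, converged) for one fast-path cohort at a single tau."""
    pv = pseudo_values(df["time"].to_numpy(), df["event"].to_numpy(), [tau], strata=df["stratum"].to_numpy())
    strat = df["stratum"].to_numpy()
    cols = [df["exposed"].to_numpy(dtype=float)]
    names = ["exposed"]
    for s in np.unique(strat)[1:]:
        cols.append((strat == s).astype(float))
        names.append(f"stratum_{s}")
    X = np.column_stack(cols)
    fit = fit_gee_log(pv, X, df["family_id"].to_numpy(), names=names, tau_grid=[tau])
    return fit.coef("exposed"), fit.se("exposed"), fit.converged


def recovery_experiment(
    true_rr: float,
    replicates: int = 200,
    n_exposed: int = 2000,
    seed: int = 0,
    m_tests: int = 33,
    tau: float = 8.0,
    **cohort_kwargs,
) -> pd.DataFrame:
    """Repeatedly simulate calibrated cohorts and summarise bias/coverage.

    Returns one row with the mean estimate, empirical SE, mean model SE and
    the empirical coverage of the (uncorrected) 95% CI, plus per-replicate
    estimates in the ``estimates`` column of ``attrs``.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    logs, ses, covered = [], [], []
    from scipy.stats import norm

    z = norm.ppf(0.975)
    for _ in range(replicates):
        df = simulate_cohort(n_exposed, true_rr, rng, tau=tau, **cohort_kwargs)
        b, se, conv = _fit_simulated_cohort(df, tau, m_tests)
        if not conv:
            continue
        logs.append(b)
        ses.append(se)
        covered.append(abs(b - np.log(true_rr)) <= z * se)
    logs = np.asarray(logs)
    ses = np.asarray(ses)
    table = pd.DataFrame(
        {
            "true_rr": [true_rr],
            "replicates": [len(logs)],
            "mean_rr": [float(np.exp(logs).mean())],
            "mean_log_rr": [float(logs.mean())],
            "bias_log": [float(logs.mean() - np.log(true_rr))],
            "empirical_se": [float(logs.std(ddof=1)) if len(logs) > 1 else np.nan],
            "mean_model_se": [float(ses.mean())],
            "coverage95": [float(np.mean(covered))],
            "mc_se_mean_log": [float(logs.std(ddof=1) / np.sqrt(len(logs))) if len(logs) > 1 else np.nan],
        }
    )
    table.attrs["estimates"] = np.exp(logs)
    return table


def null_calibration(
    n_categories: int = 33,
    replicates: int = 200,
    n_exposed: int = 300,
    seed: int = 0,
    m_tests: int = 33,
    tau: float = 8.0,
    **cohort_kwargs,
) -> dict:
    """Type-I error of the uncorrected CI and family-wise error of the
    Bonferroni-corrected CI across independent null categories."""
    rng = np.random.default_rng(seed)
    n_reject, n_tests = 0, 0
    familywise = 0
    for _ in range(replicates):
        any_corrected = False
        for _ in range(n_categories):
            df = simulate_cohort(n_exposed, 1.0, rng, tau=tau, **cohort_kwargs)
            b, se, conv = _fit_simulated_cohort(df, tau, m_tests)
            if not conv:
                continue
            ci95, cic = bonferroni_ci(b, se, m_tests)
            n_tests += 1
            if ci95[0] > 1 or ci95[1] < 1:
                n_reject += 1
            if cic[0] > 1 or cic[1] < 1:
                any_corrected = True
        familywise += any_corrected
    return {
        "per_test_rejection": n_reject / n_tests if n_tests else np.nan,
        "familywise_rejection": familywise / replicates,
        "n_tests": n_tests,
        "replicates": replicates,
        "n_categories": n_categories,
        "m_tests": m_tests,
    }
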