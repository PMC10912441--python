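"""Synthetic multi-register generator with known ground truth.

Families (1-2 parents, 1+ children) are generated with yearly covariates,
per-parent diagnosis/prescription Poisson streams coded so the exposure
engine can classify them, and per-child competing abuse/death hazards with
calendar-period-dependent censoring.  The abuse hazard is multiplied by
``exp(true_log_rr[category])`` during months the family is exposed, making
every downstream estimate checkable against configuration truth.

Also provides :func:`simulate_cohort`, a fast direct generator of matched
follow-up cohorts (hazards calibrated so the cumulative-incidence ratio at
the evaluation horizon equals the requested relative risk exactly), used by
the parameter-recovery and calibration experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._time import DAYS_PER_YEAR, as_date, month_starts
from .config import ConfigurationError, SimConfig
from .exposure import (
    EXCLUDED,
    OTHER,
    PSYCH,
    UNSPECIFIC,
    ExposureTimeline,
    Taxonomy,
    default_taxonomy,
)
from .registry import RegistrySnapshot

# residual ICD prefixes guaranteed to classify as OTHER under the default taxonomy
_OTHER_CODES = ("Q10", "L40", "N20", "H60", "G47", "M54", "E65", "K80")
_EXCLUDED_CODES = ("S72", "T10", "A09", "O80", "Z01")
_PSYCH_CODES = ("F32", "F41", "F60")
_UNSPECIFIC_CODES = ("R10", "R42", "R51", "R53")


def calendar_period(dates, study_start, study_end) -> np.ndarray:
    """0/1/2 calendar-time group: the study window split in three equal spans."""
    start = as_date(study_start)
    end = as_date(study_end)
    span = (end - start) / np.timedelta64(1, "D")
    frac = (np.asarray(dates, dtype="datetime64[D]") - start) / np.timedelta64(1, "D") / span
    return np.clip((frac * 3).astype(int), 0, 2)


def generate_population(config: SimConfig, rng: np.random.Generator | None = None) -> RegistrySnapshot:
    """Persons, parent-child links and yearly family covariates.

    Reproducible from ``config.seed``; covariate missingness is injected
    completely at random at the configured per-field rates.
    """
    if config.n_families < 0:
        raise ConfigurationError("n_families must be >= 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    start = as_date(config.study_start)
    end = as_date(config.study_end)
    cov = config.covariate_distributions

    persons, links = [], []
    fam_meta = []
    for i in range(config.n_families):
        fid = f"F{i:06d}"
        n_parents = 1 + (rng.random() < config.p_two_parents)
        size_bin = rng.choice(4, p=config.family_size_probs)
        n_children = [1, 2, rng.integers(3, 6), rng.integers(6, 9)][size_bin]

        first_birth = start + np.timedelta64(
            int(rng.integers(-8 * 365, (end - start) / np.timedelta64(1, "D"))), "D"
        )
        births = [first_birth]
        for _ in range(n_children - 1):
            births.append(first_birth + np.timedelta64(int(rng.integers(-4 * 365, 4 * 365)), "D"))
        parent_births = [
            first_birth - np.timedelta64(int(rng.integers(20 * 365, 38 * 365)), "D")
            for _ in range(n_parents)
        ]
        parent_ids = [f"{fid}P{j}" for j in range(n_parents)]
        for pid, pb in zip(parent_ids, parent_births):
            persons.append((pid, fid, "parent", rng.choice(["F", "M"]), pb, pd.NaT, pd.NaT))
        for j, cb in enumerate(births):
            cid = f"{fid}C{j}"
            persons.append((cid, fid, "child", rng.choice(["F", "M"]), cb, pd.NaT, pd.NaT))
            for pid in parent_ids:
                links.append((cid, pid, fid, cb, pd.NaT))
        fam_meta.append((fid, n_children, parent_births))

    persons_df = pd.DataFrame(
        persons,
        columns=["person_id", "family_id", "role", "sex", "birth_date", "death_date", "emigration_date"],
    )
    links_df = pd.DataFrame(links, columns=["child_id", "parent_id", "family_id", "start_date", "end_date"])

    years = list(range(pd.Timestamp(start).year, pd.Timestamp(end).year + 1))
    n_fam = len(fam_meta)
    rows = []
    if n_fam:
        educ = rng.random(n_fam) < cov["p_tertiary_education"]
        psych = rng.random(n_fam) < cov["p_psychiatric"]
        viol = rng.random(n_fam) < cov["p_interparental_violence"]
        subst = rng.random(n_fam) < cov["p_substance_abuse"]
        malt = rng.random(n_fam) < cov["p_parental_maltreatment"]
        immig = rng.random(n_fam) < cov["p_immigrant"]
        refu = rng.random(n_fam) < cov["p_refugee"]
        for k, year in enumerate(years):
            mid = as_date(f"{year}-07-01")
            period = int(calendar_period([mid], start, end)[0])
            income = rng.normal(cov["income_mean"], cov["income_sd"], n_fam)
            neigh = rng.normal(cov["neighborhood_mean"], cov["neighborhood_sd"], n_fam)
            recon = rng.choice(3, size=n_fam, p=cov["reconstituted_probs"])
            for f, (fid, n_children, pbs) in enumerate(fam_meta):
                ages = [(mid - pb) / np.timedelta64(1, "D") / DAYS_PER_YEAR for pb in pbs]
                nc_cat = 0 if n_children == 1 else 1 if n_children == 2 else 2 if n_children <= 5 else 3
                rows.append(
                    (
                        fid, year, income[f], neigh[f], float(np.mean(ages)),
                        int(educ[f]), int(psych[f]), int(viol[f]), int(subst[f]), int(malt[f]),
                        int(immig[f]), int(refu[f]), int(recon[f]), nc_cat, period,
                    )
                )
    cov_df = pd.DataFrame(
        rows,
        columns=[
            "family_id", "year", "income", "neighborhood_resources", "mean_parental_age",
            "education", "psychiatric_disease", "interparental_violence", "substance_abuse",
            "parental_maltreatment", "immigration_background", "refugee_status",
            "reconstituted_family", "n_children_category", "calendar_period",
        ],
    )
    # MCAR missingness, only on the fields allowed to be missing
    for col, rate in cov.get("missing_rates", {}).items():
        if rate > 0 and len(cov_df):
            mask = rng.random(len(cov_df)) < rate
            cov_df.loc[mask, col] = np.nan

    snap = RegistrySnapshot(persons=persons_df, links=links_df, covariates=cov_df)
    if config.n_families:
        snap.validate()
    return snap


def _codes_for(taxonomy: Taxonomy, key: str) -> tuple:
    if key == UNSPECIFIC:
        return tuple(taxonomy.unspecific_patterns) or _UNSPECIFIC_CODES
    if key == OTHER:
        return _OTHER_CODES
    if key == EXCLUDED:
        return tuple(taxonomy.exclusion_patterns) or _EXCLUDED_CODES
    if key == PSYCH:
        return _PSYCH_CODES
    rule = taxonomy.rule_for(key)  # KeyError -> caught by caller
    return tuple(rule.icd_patterns)


def generate_health_events(
    snapshot: RegistrySnapshot,
    config: SimConfig,
    taxonomy: Taxonomy | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Homogeneous-Poisson diagnosis/prescription streams per parent.

    Events cover ``[study_start - burn_in, study_end]``; diagnosis codes are
    drawn from the taxonomy patterns of the configured category (or the
    UNSPECIFIC / OTHER / EXCLUDED / PSYCH pools), so classification recovers
    the generating category.
    """
    taxonomy = default_taxonomy() if taxonomy is None else taxonomy
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    start = as_date(config.study_start) - np.timedelta64(int(round(config.burn_in_years * DAYS_PER_YEAR)), "D")
    end = as_date(config.study_end)
    horizon_days = int((end - start) / np.timedelta64(1, "D"))
    horizon_years = horizon_days / DAYS_PER_YEAR

    code_pools = {}
    for key in config.category_diagnosis_rates:
        try:
            code_pools[key] = _codes_for(taxonomy, key)
        except KeyError:
            raise ConfigurationError(f"unknown category key in diagnosis rates: {key!r}")
    for key in config.prescription_rates:
        from .exposure import classify_code

        if classify_code(taxonomy, key, "atc") == "":
            raise ConfigurationError(f"unknown ATC group in prescription rates: {key!r}")

    parents = snapshot.parents["person_id"].to_numpy()
    dx_rows, rx_rows = [], []
    for pid in parents:
        for key, rate in config.category_diagnosis_rates.items():
            n = rng.poisson(rate * horizon_years)
            if n:
                offs = rng.integers(0, horizon_days + 1, size=n)
                pool = code_pools[key]
                for o in offs:
                    code = pool[rng.integers(len(pool))]
                    dx_rows.append((pid, start + np.timedelta64(int(o), "D"), code))
        for key, rate in config.prescription_rates.items():
            n = rng.poisson(rate * horizon_years)
            if n:
                offs = rng.integers(0, horizon_days + 1, size=n)
                for o in offs:
                    rx_rows.append((pid, start + np.timedelta64(int(o), "D"), key))

    dx = pd.DataFrame(dx_rows, columns=["person_id", "date", "code"])
    rx = pd.DataFrame(rx_rows, columns=["person_id", "date", "atc_code"])
    return dx, rx


def generate_outcomes(
    snapshot: RegistrySnapshot,
    timeline: ExposureTimeline | None,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """First-event record per child from competing piecewise-constant hazards.

    Abuse and death race as exponentials month by month; the abuse hazard is
    scaled by exp(true_log_rr) while the child's family is exposed, and the
    emigration (censoring) hazard switches with the calendar period.  Every
    child present during the study gets exactly one record: its earliest of
    abuse, death, emigration, 18th birthday or study end.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    start = as_date(config.study_start)
    end = as_date(config.study_end)
    months = month_starts(start, end)
    n_months = len(months)
    month_len_days = np.diff(np.append(months, end + np.timedelta64(1, "D"))).astype(float)

    kids = snapshot.children
    birth = kids["birth_date"].to_numpy(dtype="datetime64[D]")
    fam = kids["family_id"].to_numpy()
    cid = kids["person_id"].to_numpy()
    age18 = birth + np.timedelta64(int(round(18 * DAYS_PER_YEAR)), "D")
    t_limit = np.minimum(age18, end)
    in_study = (birth <= end) & (age18 > start)
    limit_type = np.where(age18 <= end, "age18", "study_end")

    beta = dict(config.true_log_rr)
    cov_eff = config.covariate_distributions.get("abuse_log_hr", {}) or {}
    frailty = (
        np.exp(rng.normal(0.0, config.family_frailty_sd, len(cid)))
        if config.family_frailty_sd > 0
        else np.ones(len(cid))
    )

    exp_mats = {}
    fam_rows = None
    if timeline is not None:
        for cat, b in beta.items():
            if b != 0.0 and cat in timeline.data:
                exp_mats[cat] = timeline.exposed_matrix(cat)
        fam_rows = np.array([timeline._fam_row.get(f, -1) for f in fam])

    cov_lookup = None
    if cov_eff:
        cov_lookup = snapshot.covariates.set_index(["family_id", "year"])

    periods = calendar_period(months, start, end)
    cens = np.asarray(config.censoring_hazards_by_period, dtype=float)

    active = in_study.copy()
    out_date = np.full(len(cid), np.datetime64("NaT"), dtype="datetime64[D]")
    out_type = np.full(len(cid), "", dtype=object)

    for m in range(n_months):
        ms = months[m]
        me = ms + np.timedelta64(int(month_len_days[m]), "D")
        alive = active & (birth < me) & (t_limit > ms)
        idx = np.nonzero(alive)[0]
        if not len(idx):
            continue
        lam_a = np.full(len(idx), config.baseline_abuse_hazard) * frailty[idx]
        for cat, mat in exp_mats.items():
            rows = fam_rows[idx]
            exposed = np.where(rows >= 0, mat[np.maximum(rows, 0), m], False)
            lam_a *= np.where(exposed, np.exp(beta[cat]), 1.0)
        if cov_lookup is not None:
            year = pd.Timestamp(ms).year
            for name, coef in cov_eff.items():
                vals = np.array(
                    [cov_lookup[name].get((f, year), 0.0) for f in fam[idx]], dtype=float
                )
                lam_a *= np.exp(coef * np.nan_to_num(vals))
        lam_d = np.full(len(idx), config.death_hazard)
        lam_c = np.full(len(idx), cens[periods[m]] if len(cens) else 0.0)
        lam_tot = lam_a + lam_d + lam_c
        dt = month_len_days[m] / DAYS_PER_YEAR
        p_event = -np.expm1(-lam_tot * dt)
        u = rng.random(len(idx))
        hit = (u < p_event) & (lam_tot > 0)
        if hit.any():
            h = idx[hit]
            probs = np.column_stack([lam_a[hit], lam_d[hit], lam_c[hit]]) / lam_tot[hit, None]
            draws = rng.random(len(h))
            cum = np.cumsum(probs, axis=1)
            etype = (draws[:, None] > cum).sum(axis=1)  # 0 abuse, 1 death, 2 emigration
            day0 = np.maximum(ms, birth[h])
            span = ((me - day0) / np.timedelta64(1, "D")).astype(int)
            offs = (rng.random(len(h)) * span).astype(int)
            dates = day0 + offs.astype("timedelta64[D]")
            late = dates >= t_limit[h]
            out_date[h] = np.where(late, t_limit[h], dates)
            out_type[h] = np.where(
                late, limit_type[h], np.array(["abuse", "death", "emigration"], dtype=object)[etype]
            )
            active[h] = False
        done = active & (t_limit <= me)
        out_date[done] = t_limit[done]
        out_type[done] = limit_type[done]
        active[done] = False

    rest = active & in_study
    out_date[rest] = t_limit[rest]
    out_type[rest] = limit_type[rest]

    keep = in_study
    return pd.DataFrame({"child_id": cid[keep], "date": out_date[keep], "type": out_type[keep]})


def true_params(config: SimConfig) -> pd.DataFrame:
    """Ground-truth relative risks per category (recovery oracle)."""
    cats = sorted(config.true_log_rr)
    return pd.DataFrame(
        {
            "category": cats,
            "true_log_rr": [config.true_log_rr[c] for c in cats],
            "true_rr": [float(np.exp(config.true_log_rr[c])) for c in cats],
        }
    )


# ---------------------------------------------------------------------------
# fast direct cohort generator (recovery / calibration experiments)
# ---------------------------------------------------------------------------

def _cif_const(lam: float, death: float, tau: float) -> float:
    """CIF of cause 1 at tau under constant competing hazards (lam, death)."""
    tot = lam + death
    if tot == 0:
        return 0.0
    return lam / tot * -np.expm1(-tot * tau)


def calibrate_hazards(baseline_cif: float, true_rr: float, death_hazard: float, tau: float) -> tuple[float, float]:
    """Abuse hazards (control, exposed) such that the cause-1 CIF at ``tau``
    is ``baseline_cif`` and ``true_rr * baseline_cif`` exactly."""
    if not 0 < baseline_cif < 1 or true_rr * baseline_cif >= 1:
        raise ValueError("target cumulative incidences must lie in (0, 1)")

    def solve(target):
        return brentq(lambda lam: _cif_const(lam, death_hazard, tau) - target, 1e-12, 1e3)

    return solve(baseline_cif), solve(true_rr * baseline_cif)


def simulate_cohort(
    n_exposed: int,
    true_rr: float,
    rng: np.random.Generator,
    *,
    ratio: int = 5,
    baseline_cif: float = 0.10,
    death_hazard: float = 0.002,
    tau: float = 8.0,
    horizon: float = 9.0,
    censor_rates: tuple = (0.010, 0.025, 0.045),
    stratum_probs: tuple = (0.4, 0.3, 0.3),
) -> pd.DataFrame:
    """Matched-cohort follow-up table on the time-since-entry scale.

    ``n_exposed`` exposed children plus ``ratio`` controls each, singleton
    families, three calendar strata differing only in censoring intensity.
    The true cumulative-incidence ratio at ``tau`` equals ``true_rr``.
    """
    lam0, lam1 = calibrate_hazards(baseline_cif, true_rr, death_hazard, tau)
    n = n_exposed * (1 + ratio)
    exposed = np.zeros(n, dtype=bool)
    exposed[:n_exposed] = True
    stratum = rng.choice(len(stratum_probs), size=n, p=stratum_probs)
    lam_a = np.where(exposed, lam1, lam0)
    t_abuse = rng.exponential(1.0, n) / np.maximum(lam_a, 1e-300)
    t_death = (
        rng.exponential(1.0, n) / death_hazard if death_hazard > 0 else np.full(n, np.inf)
    )
    c_rate = np.asarray(censor_rates, dtype=float)[stratum]
    t_cens = np.where(c_rate > 0, rng.exponential(1.0, n) / np.maximum(c_rate, 1e-300), np.inf)
    t_cens = np.minimum(t_cens, horizon)
    time = np.minimum.reduce([t_abuse, t_death, t_cens])
    event = np.select([t_abuse == time, t_death == time], [1, 2], default=0)
    return pd.DataFrame(
        {
            "child_id": np.arange(n),
            "family_id": np.arange(n),
            "stratum": stratum,
            "exposed": exposed.astype(int),
            "time": time,
            "event": event,
        }
    )
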