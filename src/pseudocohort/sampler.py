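"""Incidence-density matched cohort construction (1 exposed : ``ratio`` controls).

For every child newly exposed in a disease category, the index date is the
later of the family's first qualifying month and the child's birth date.
Controls are drawn at the index date from children who are at risk,
unexposed in that category, abuse-free, and have complete covariates,
matching on calendar time (+/- 3 months, trivially satisfied because
controls share the case's index date), reconstituted-family level, birth
year (+/- 1), number-of-children level, and mean parental age (+/- 5 y).
Cases with fewer than ``ratio`` eligible controls are dropped.  Within one
category's cohort a child appears at most once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._time import DAYS_PER_YEAR, add_months, as_date
from .exposure import ExposureTimeline
from .registry import RegistrySnapshot

logger = logging.getLogger(__name__)

MATCH_COVARIATES = ["reconstituted_family", "n_children_category", "mean_parental_age"]
MODEL_COVARIATES = [
    "income",
    "neighborhood_resources",
    "education",
    "psychiatric_disease",
    "interparental_violence",
    "substance_abuse",
    "parental_maltreatment",
    "immigration_background",
    "refugee_status",
    "calendar_period",
]
ALL_COVARIATES = MATCH_COVARIATES + MODEL_COVARIATES

AGE_WINDOW_YEARS = 5.0
BIRTH_YEAR_WINDOW = 1
CALENDAR_WINDOW_DAYS = 92  # +/- 3 months


@dataclass
class SamplingLog:
    """Bookkeeping counters mirroring cohort-construction footnotes."""

    n_exposed_found: int = 0
    n_excluded_prior_outcome: int = 0
    n_incomplete_covariates: int = 0
    n_dropped_short_of_controls: int = 0
    n_sets: int = 0
    notes: list = field(default_factory=list)


def _child_frame(snapshot: RegistrySnapshot) -> pd.DataFrame:
    kids = snapshot.children.copy()
    kids["birth_date"] = kids["birth_date"].values.astype("datetime64[D]")
    out = snapshot.outcomes
    abuse = out[out["type"] == "abuse"].set_index("child_id")["date"]
    kids["abuse_date"] = kids["person_id"].map(abuse)
    term = out.set_index("child_id")["date"]
    kids["terminal_date"] = kids["person_id"].map(term)
    return kids


def find_exposed(
    timeline: ExposureTimeline,
    snapshot: RegistrySnapshot,
    category: str,
    log: SamplingLog | None = None,
) -> pd.DataFrame:
    """Index records: one row per child newly exposed in ``category``.

    Children whose first documented abuse precedes the index date are
    excluded, as are children not at risk (dead, emigrated, 18 or older,
    or unborn) at the index date.
    """
    log = log or SamplingLog()
    first = timeline.first_exposed_month(category)
    if not first:
        return pd.DataFrame(
            columns=["child_id", "family_id", "category", "index_date", "birth_date"]
        )
    kids = _child_frame(snapshot)
    kids = kids[kids["family_id"].isin(first)]
    rows = []
    study_end = timeline.months[-1]
    for row in kids.itertuples(index=False):
        qual = first[row.family_id]
        index_date = max(as_date(qual), as_date(row.birth_date))
        if index_date > study_end:
            continue
        age18 = as_date(row.birth_date) + np.timedelta64(int(round(18 * DAYS_PER_YEAR)), "D")
        if index_date >= age18:
            continue
        if pd.notna(row.abuse_date) and as_date(row.abuse_date) < index_date:
            log.n_excluded_prior_outcome += 1
            continue
        if pd.notna(row.terminal_date) and as_date(row.terminal_date) <= index_date and (
            pd.isna(row.abuse_date) or as_date(row.abuse_date) != as_date(row.terminal_date)
        ):
            continue  # dead/censored before becoming exposed
        rows.append((row.person_id, row.family_id, category, index_date, as_date(row.birth_date)))
    log.n_exposed_found = len(rows)
    return pd.DataFrame(rows, columns=["child_id", "family_id", "category", "index_date", "birth_date"])


def _covariates_for_year(snapshot: RegistrySnapshot, year: int) -> pd.DataFrame:
    cov = snapshot.covariates
    return cov[cov["year"] == year].set_index("family_id")


def draw_matched_controls(
    index_records: pd.DataFrame,
    snapshot: RegistrySnapshot,
    timeline: ExposureTimeline,
    category: str,
    ratio: int = 5,
    seed: int | np.random.Generator = 0,
    log: SamplingLog | None = None,
) -> pd.DataFrame:
    """Matched sets: each case plus ``ratio`` controls sampled uniformly
    without replacement from the eligible risk set at the index date.

    Returns a long table (set_id, child_id, family_id, role, index_date,
    birth_date, + covariates at index).  Cases with incomplete covariates
    or fewer than ``ratio`` eligible controls are dropped and counted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log = log or SamplingLog()
    out_cols = ["set_id", "child_id", "family_id", "role", "index_date", "birth_date"] + ALL_COVARIATES
    if not len(index_records):
        logger.warning("no index records for %r; empty cohort", category)
        return pd.DataFrame(columns=out_cols)

    kids = _child_frame(snapshot)
    birth = kids["birth_date"].values.astype("datetime64[D]")
    age18 = birth + np.timedelta64(int(round(18 * DAYS_PER_YEAR)), "D")
    kids = kids.assign(age18=age18, birth_year=pd.DatetimeIndex(birth).year)

    mat = timeline.exposed_matrix(category)
    fam_row = timeline._fam_row
    kid_fam_rows = np.array([fam_row.get(f, -1) for f in kids["family_id"]])
    birth_arr = kids["birth_date"].values.astype("datetime64[D]")
    age18_arr = kids["age18"].values.astype("datetime64[D]")
    term_arr = pd.to_datetime(pd.Series(kids["terminal_date"].values)).values.astype("datetime64[D]")
    abuse_arr = pd.to_datetime(pd.Series(kids["abuse_date"].values)).values.astype("datetime64[D]")

    used: set = set(index_records["child_id"])  # cases never double as controls
    records = index_records.sort_values(["index_date", "child_id"]).reset_index(drop=True)
    records["birth_year"] = pd.DatetimeIndex(records["birth_date"].values.astype("datetime64[D]")).year

    rows = []
    set_id = 0
    for year, grp in records.groupby(records["index_date"].map(lambda d: pd.Timestamp(d).year), sort=True):
        cov_year = _covariates_for_year(snapshot, year)
        complete = cov_year.dropna(subset=[c for c in ALL_COVARIATES if c in cov_year.columns])
        for rec in grp.itertuples(index=False):
            if rec.family_id not in complete.index:
                log.n_incomplete_covariates += 1
                continue
            case_cov = complete.loc[rec.family_id]
            idx_date = as_date(rec.index_date)
            m = int(np.searchsorted(timeline.months, idx_date, side="right") - 1)
            unexposed = np.ones(len(kids), dtype=bool)
            has_row = kid_fam_rows >= 0
            unexposed[has_row] = ~mat[kid_fam_rows[has_row], m]
            at_risk = (birth_arr <= idx_date) & (age18_arr > idx_date)
            alive = np.isnat(term_arr) | (term_arr > idx_date)
            abuse_free = np.isnat(abuse_arr) | (abuse_arr > idx_date)
            eligible = unexposed & at_risk & alive & abuse_free
            cand = kids.loc[eligible, ["person_id", "family_id", "birth_year", "birth_date"]]
            cand = cand[~cand["person_id"].isin(used)]
            cand = cand.join(complete, on="family_id", how="inner")
            cand = cand[
                (cand["reconstituted_family"] == case_cov["reconstituted_family"])
                & (cand["n_children_category"] == case_cov["n_children_category"])
                & ((cand["birth_year"] - rec.birth_year).abs() <= BIRTH_YEAR_WINDOW)
                & ((cand["mean_parental_age"] - case_cov["mean_parental_age"]).abs() <= AGE_WINDOW_YEARS)
            ]
            if len(cand) < ratio:
                log.n_dropped_short_of_controls += 1
                continue
            pick = cand.iloc[rng.choice(len(cand), size=ratio, replace=False)]
            rows.append(
                (set_id, rec.child_id, rec.family_id, "exposed", idx_date, as_date(rec.birth_date))
                + tuple(case_cov[c] for c in ALL_COVARIATES)
            )
            for c in pick.itertuples(index=False):
                rows.append(
                    (set_id, c.person_id, c.family_id, "control", idx_date, as_date(c.birth_date))
                    + tuple(getattr(c, col) for col in ALL_COVARIATES)
                )
                used.add(c.person_id)
            set_id += 1
    log.n_sets = set_id
    if not rows:
        logger.warning("no matched sets could be formed for %r", category)
    return pd.DataFrame(rows, columns=out_cols)


def cap_exposed(matched: pd.DataFrame, max_n: int = 100_000, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Uniform subsample of matched sets when the number of cases exceeds the cap."""
    if not len(matched):
        return matched
    sets = matched["set_id"].unique()
    if len(sets) <= max_n:
        return matched
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = set(rng.choice(sets, size=max_n, replace=False))
    return matched[matched["set_id"].isin(keep)].reset_index(drop=True)


def build_followup(
    matched: pd.DataFrame,
    outcomes: pd.DataFrame,
    study_end,
    log: SamplingLog | None = None,
) -> pd.DataFrame:
    """Follow-up records: entry one month after index, exit at the first of
    abuse, death, censoring, the 18th birthday or study end.

    Children whose terminal event does not come strictly after entry are
    dropped (the rest of the set is kept).  ``event`` is coded 0 censored,
    1 abuse, 2 death; ``time`` is years from entry to exit.
    """
    log = log or SamplingLog()
    cols = list(matched.columns) + ["entry_date", "exit_date", "event", "time", "exposed"]
    if not len(matched):
        return pd.DataFrame(columns=cols)
    study_end = as_date(study_end)
    term = outcomes.set_index("child_id")
    missing = set(matched["child_id"]) - set(term.index)
    if missing:
        raise ValueError(f"children without a terminal outcome record: {sorted(missing)[:5]} ...")

    out = matched.copy()
    out["entry_date"] = [add_months(d, 1) for d in out["index_date"]]
    t_date = term.loc[out["child_id"], "date"].values.astype("datetime64[D]")
    t_type = term.loc[out["child_id"], "type"].values
    birth = out["birth_date"].values.astype("datetime64[D]")
    age18 = birth + np.timedelta64(int(round(18 * DAYS_PER_YEAR)), "D")
    limit = np.minimum(age18, study_end)

    exit_date = np.minimum(t_date, limit)
    event = np.where(
        (t_date <= limit) & (t_type == "abuse"), 1, np.where((t_date <= limit) & (t_type == "death"), 2, 0)
    )
    entry = out["entry_date"].values.astype("datetime64[D]")
    keep = exit_date > entry
    dropped = int((~keep).sum())
    if dropped:
        log.notes.append(f"{dropped} record(s) with terminal event inside the first month dropped")
    out["exit_date"] = exit_date
    out["event"] = event
    out["time"] = (exit_date - entry) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    out["exposed"] = (out["role"] == "exposed").astype(int)
    return out.loc[keep].reset_index(drop=True)
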