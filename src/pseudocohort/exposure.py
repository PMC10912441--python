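"""Rule-based disease-category classification and monthly exposure timelines.

Codes are classified by longest-prefix match against a taxonomy of rules
(named disease categories, unspecific-symptom codes, excluded chapters and
psychiatric codes).  Family-level exposure is evaluated on a monthly grid:
a family is exposed in a category during month *m* if any currently linked
parent has a qualifying diagnosis inside the category's look-back window
ending at the first day of *m*, or redeemed at least the category's minimum
number of qualifying prescriptions in the 365 days ending there.  The
prescription criterion defines qualification dates to which the category
window is then applied, so "ever" categories stay monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._time import as_date, month_starts

logger = logging.getLogger(__name__)

# classification sentinels (named categories are returned by name)
UNSPECIFIC = "UNSPECIFIC"
OTHER = "OTHER"
EXCLUDED = "EXCLUDED"
PSYCH = "PSYCH"

WINDOWS = {"ever": None, "last_1y": 365, "last_2y": 730, "last_3y": 1095, "last_5y": 1825}
_PRECEDENCE = {EXCLUDED: 0, PSYCH: 1, UNSPECIFIC: 3}  # named categories rank 2

# Window variants synthesised from the sentinel pattern groups.
UNSPECIFIC_2Y = "Unspecific symptoms, two years back"
UNSPECIFIC_EVER = "Unspecific symptoms, ever"
OTHER_CATEGORY = "Other"


class TaxonomyError(ValueError):
    """Invalid taxonomy file contents."""


def normalize_code(code: str) -> str:
    """Strip dots/whitespace and uppercase (ICD-10 'I20.0' -> 'I200')."""
    return str(code).replace(".", "").replace(" ", "").upper()


@dataclass(frozen=True)
class CategoryRule:
    category_name: str
    cluster_name: str = ""
    icd_patterns: tuple = ()
    atc_patterns: tuple = ()
    diagnosis_window: str = "ever"
    min_prescriptions_per_year: int = 0

    def __post_init__(self):
        if self.diagnosis_window not in WINDOWS:
            raise TaxonomyError(f"unknown window {self.diagnosis_window!r} for {self.category_name!r}")
        if self.min_prescriptions_per_year not in (0, 2, 4):
            raise TaxonomyError(f"min_prescriptions_per_year must be 0, 2 or 4 ({self.category_name!r})")


@dataclass
class Taxonomy:
    rules: list = field(default_factory=list)
    exclusion_patterns: tuple = ()
    unspecific_patterns: tuple = ()
    psychiatric_prefix: tuple = ("F",)

    def __post_init__(self):
        names = [r.category_name for r in self.rules]
        if len(names) != len(set(names)):
            raise TaxonomyError("duplicate category names")
        self._build_index()

    def _build_index(self) -> None:
        # pattern -> (target, precedence); one entry per (kind, pattern)
        icd: dict[str, str] = {}
        atc: dict[str, str] = {}
        for rule in self.rules:
            for p in rule.icd_patterns:
                _put(icd, normalize_code(p), rule.category_name)
            for p in rule.atc_patterns:
                _put(atc, normalize_code(p), rule.category_name)
        for p in self.unspecific_patterns:
            _put(icd, normalize_code(p), UNSPECIFIC)
        for p in self.exclusion_patterns:
            _put(icd, normalize_code(p), EXCLUDED)
        for p in self.psychiatric_prefix:
            _put(icd, normalize_code(p), PSYCH)
        self._icd_index = icd
        self._atc_index = atc
        self._icd_lengths = sorted({len(p) for p in icd}, reverse=True)
        self._atc_lengths = sorted({len(p) for p in atc}, reverse=True)

    @property
    def category_names(self) -> list:
        """All testable disease categories, window variants included."""
        names = [r.category_name for r in self.rules]
        if self.unspecific_patterns:
            names += [UNSPECIFIC_2Y, UNSPECIFIC_EVER]
        names.append(OTHER_CATEGORY)
        return names

    def rule_for(self, category: str) -> CategoryRule:
        if category == UNSPECIFIC_2Y:
            return CategoryRule(UNSPECIFIC_2Y, "Unspecific symptoms", diagnosis_window="last_2y")
        if category == UNSPECIFIC_EVER:
            return CategoryRule(UNSPECIFIC_EVER, "Unspecific symptoms", diagnosis_window="ever")
        if category == OTHER_CATEGORY:
            return CategoryRule(OTHER_CATEGORY, "Other diagnoses", diagnosis_window="last_3y")
        for r in self.rules:
            if r.category_name == category:
                return r
        raise KeyError(category)


def _put(index: dict, pattern: str, target: str) -> None:
    if not pattern:
        raise TaxonomyError("empty pattern")
    if pattern in index and index[pattern] != target:
        raise TaxonomyError(f"pattern {pattern!r} mapped to both {index[pattern]!r} and {target!r}")
    index[pattern] = target


def load_taxonomy(path) -> Taxonomy:
    """Read a taxonomy TSV (pattern, kind, target, window, min_rx[, cluster]).

    Sentinel targets UNSPECIFIC / EXCLUDE / PSYCH collect pattern groups;
    every other target is a named disease category whose window and
    prescription threshold must agree across its rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("-")
    required = {"pattern", "kind", "target"}
    if not required <= set(df.columns):
        raise TaxonomyError(f"taxonomy file must have columns {sorted(required)}")
    if "window" not in df.columns:
        df["window"] = "-"
    if "min_rx" not in df.columns:
        df["min_rx"] = "-"
    if "cluster" not in df.columns:
        df["cluster"] = "-"

    exclusion, unspecific, psych = [], [], []
    cat_rows: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        kind = row.kind.strip().lower()
        if kind not in ("icd", "atc"):
            raise TaxonomyError(f"unknown kind {row.kind!r}")
        target = row.target.strip()
        if target == "EXCLUDE":
            exclusion.append(row.pattern)
            continue
        if target == "UNSPECIFIC":
            unspecific.append(row.pattern)
            continue
        if target == "PSYCH":
            psych.append(row.pattern)
            continue
        window = row.window.strip()
        if window not in WINDOWS:
            raise TaxonomyError(f"unknown window token {window!r} (pattern {row.pattern!r})")
        min_rx = int(row.min_rx)
        entry = cat_rows.setdefault(
            target, {"icd": [], "atc": [], "window": window, "min_rx": min_rx, "cluster": row.cluster}
        )
        if entry["window"] != window or entry["min_rx"] != min_rx:
            raise TaxonomyError(f"conflicting window/min_rx for category {target!r}")
        entry[kind].append(row.pattern)

    rules = [
        CategoryRule(
            category_name=name,
            cluster_name="" if e["cluster"] == "-" else e["cluster"],
            icd_patterns=tuple(e["icd"]),
            atc_patterns=tuple(e["atc"]),
            diagnosis_window=e["window"],
            min_prescriptions_per_year=e["min_rx"],
        )
        for name, e in cat_rows.items()
    ]
    return Taxonomy(
        rules=rules,
        exclusion_patterns=tuple(exclusion),
        unspecific_patterns=tuple(unspecific),
        psychiatric_prefix=tuple(psych) if psych else ("F",),
    )


def default_taxonomy() -> Taxonomy:
    """The shipped taxonomy implementing the 33 default disease categories."""
    from importlib.resources import files

    return load_taxonomy(files("pseudocohort.data") / "taxonomy_default.tsv")


def classify_code(taxonomy: Taxonomy, code: str, kind: str = "icd") -> str:
    """Classify one code; longest prefix wins, equal-length ties by
    precedence EXCLUDED > PSYCH > named category > UNSPECIFIC.

    Unmatched ICD codes fall through to OTHER; unmatched ATC codes are
    ignored (OTHER is diagnosis-defined only).
    """
    if not code or not str(code).strip():
        raise ValueError("empty code")
    code = normalize_code(code)
    if kind == "icd":
        index, lengths = taxonomy._icd_index, taxonomy._icd_lengths
    elif kind == "atc":
        index, lengths = taxonomy._atc_index, taxonomy._atc_lengths
    else:
        raise ValueError(f"kind must be 'icd' or 'atc', got {kind!r}")
    for ln in lengths:
        if ln > len(code):
            continue
        hits = [index[code[:ln]]] if code[:ln] in index else []
        if hits:
            return min(hits, key=lambda t: _PRECEDENCE.get(t, 2))
    return OTHER if kind == "icd" else ""


@dataclass
class ExposureTimeline:
    """Boolean exposure state per family x category x month."""

    months: np.ndarray  # month-start grid, datetime64[D]
    family_ids: np.ndarray
    categories: list
    data: dict  # category -> bool array (n_families, n_months)

    def __post_init__(self):
        self._fam_row = {f: i for i, f in enumerate(self.family_ids)}

    def exposed_matrix(self, category: str) -> np.ndarray:
        if category not in self.data:
            raise KeyError(f"unknown category {category!r}")
        return self.data[category]

    def exposure_at(self, family_id, category: str, date) -> bool:
        if family_id not in self._fam_row:
            raise KeyError(f"unknown family {family_id!r}")
        mat = self.exposed_matrix(category)
        d = as_date(date)
        if d < self.months[0]:
            return False
        m = int(np.searchsorted(self.months, d, side="right") - 1)
        if m >= len(self.months):
            raise KeyError(f"date {date} outside the study window")
        return bool(mat[self._fam_row[family_id], m])

    def first_exposed_month(self, category: str) -> dict:
        """family_id -> month-start date of first exposed month."""
        mat = self.exposed_matrix(category)
        any_exp = mat.any(axis=1)
        first = mat.argmax(axis=1)
        return {
            self.family_ids[i]: self.months[first[i]]
            for i in np.nonzero(any_exp)[0]
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (family_id, category, month, exposed)."""
        frames = []
        for cat in self.categories:
            mat = self.data[cat]
            fam_idx, m_idx = np.nonzero(mat)
            frames.append(
                pd.DataFrame(
                    {
                        "family_id": self.family_ids[fam_idx],
                        "category": cat,
                        "month": self.months[m_idx],
                        "exposed": True,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["family_id", "category", "month", "exposed"]
        )


def exposure_at(timeline: ExposureTimeline, family_id, category: str, date) -> bool:
    return timeline.exposure_at(family_id, category, date)


def _mark_window(flag_row: np.ndarray, months: np.ndarray, dates: np.ndarray, window_days) -> None:
    """OR into ``flag_row`` the months whose start lies within ``window_days``
    after each qualifying date (or all later months when window is None)."""
    if len(dates) == 0:
        return
    lo = np.searchsorted(months, dates, side="left")
    if window_days is None:
        m = lo.min()
        if m < len(flag_row):
            flag_row[m:] = True
        return
    hi = np.searchsorted(months, dates + np.timedelta64(int(window_days), "D"), side="right")
    delta = np.zeros(len(flag_row) + 1, dtype=np.int32)
    np.add.at(delta, np.minimum(lo, len(flag_row)), 1)
    np.add.at(delta, np.minimum(hi, len(flag_row)), -1)
    flag_row |= np.cumsum(delta[:-1]) > 0


def _rx_qualify_months(months: np.ndarray, dates: np.ndarray, min_rx: int) -> np.ndarray:
    """Month-start dates where the rolling 365-day prescription count >= min_rx."""
    dates = np.sort(dates)
    hi = np.searchsorted(dates, months, side="right")
    lo = np.searchsorted(dates, months - np.timedelta64(365, "D"), side="left")
    return months[(hi - lo) >= min_rx]


def build_exposure_timeline(
    taxonomy: Taxonomy,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    links: pd.DataFrame,
    study_start,
    study_end,
    burn_in_years: int = 3,
) -> ExposureTimeline:
    """Monthly family-level exposure states for every category in the taxonomy.

    Events earlier than ``study_start - burn_in_years`` are ignored (with a
    warning); a family is exposed through a parent only while that parent is
    linked to one of its children.
    """
    months = month_starts(study_start, study_end)
    read_in = as_date(study_start) - np.timedelta64(int(round(burn_in_years * 365.25)), "D")

    families = np.array(sorted(links["family_id"].unique(), key=str), dtype=object)
    fam_row = {f: i for i, f in enumerate(families)}

    # parent -> list of (family row, active-month mask)
    parent_fams: dict = {}
    plinks = links.drop_duplicates(subset=["parent_id", "family_id", "start_date", "end_date"])
    for row in plinks.itertuples(index=False):
        # a link active during any part of a month counts for that month
        start = as_date(row.start_date) if pd.notna(row.start_date) else months[0]
        start = np.datetime64(pd.Timestamp(start).to_period("M").to_timestamp().date(), "D")
        end = as_date(row.end_date) if pd.notna(row.end_date) else months[-1]
        mask = (months >= start) & (months <= end)
        parent_fams.setdefault(row.parent_id, []).append((fam_row[row.family_id], mask))

    categories = taxonomy.category_names
    data = {c: np.zeros((len(families), len(months)), dtype=bool) for c in categories}

    def _drop_early(df: pd.DataFrame, name: str) -> pd.DataFrame:
        if not len(df):
            return df
        dates = df["date"].values.astype("datetime64[D]")
        early = dates < read_in
        if early.any():
            logger.warning("ignoring %d %s dated before read-in start %s", early.sum(), name, read_in)
            return df.loc[~early]
        return df

    diagnoses = _drop_early(diagnoses, "diagnoses")
    prescriptions = _drop_early(prescriptions, "prescriptions")

    # classify each distinct code once
    def _targets(codes: pd.Series, kind: str) -> pd.Series:
        uniq = codes.dropna().unique()
        mapping = {c: classify_code(taxonomy, c, kind) for c in uniq}
        return codes.map(mapping)

    per_parent_dx: dict = {}
    if len(diagnoses):
        dx = diagnoses.copy()
        dx["target"] = _targets(dx["code"], "icd")
        dx["target"] = dx["target"].replace({UNSPECIFIC: "__UNSPECIFIC__", OTHER: "__OTHER__"})
        dx = dx[~dx["target"].isin([EXCLUDED, PSYCH])]
        for (pid, target), grp in dx.groupby(["person_id", "target"], sort=False):
            per_parent_dx[(pid, target)] = np.sort(grp["date"].values.astype("datetime64[D]"))

    per_parent_rx: dict = {}
    if len(prescriptions):
        rx = prescriptions.copy()
        rx["target"] = _targets(rx["atc_code"], "atc")
        rx = rx[rx["target"] != ""]
        for (pid, target), grp in rx.groupby(["person_id", "target"], sort=False):
            per_parent_rx[(pid, target)] = np.sort(grp["date"].values.astype("datetime64[D]"))

    def _apply(parent_id, category, qual_dates, window_days):
        for row_i, active in parent_fams.get(parent_id, []):
            flags = np.zeros(len(months), dtype=bool)
            _mark_window(flags, months, qual_dates, window_days)
            data[category][row_i] |= flags & active

    for (pid, target), dates in per_parent_dx.items():
        if target == "__UNSPECIFIC__":
            _apply(pid, UNSPECIFIC_2Y, dates, WINDOWS["last_2y"])
            _apply(pid, UNSPECIFIC_EVER, dates, None)
        elif target == "__OTHER__":
            _apply(pid, OTHER_CATEGORY, dates, WINDOWS["last_3y"])
        else:
            _apply(pid, target, dates, WINDOWS[taxonomy.rule_for(target).diagnosis_window])

    for (pid, target), dates in per_parent_rx.items():
        rule = taxonomy.rule_for(target)
        if rule.min_prescriptions_per_year <= 0:
            continue
        qual = _rx_qualify_months(months, dates, rule.min_prescriptions_per_year)
        _apply(pid, target, qual, WINDOWS[rule.diagnosis_window])

    return ExposureTimeline(months=months, family_ids=families, categories=categories, data=data)
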