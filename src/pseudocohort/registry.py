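"""Registry-style tabular data: container and delimited-text I/O.

A :class:`RegistrySnapshot` bundles the person table, parent-child links,
dated diagnosis/prescription streams, first-event outcome records and the
family-year covariate table.  All tables are plain pandas DataFrames and
round-trip through TSV with ISO-8601 dates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

PERSON_COLS = ["person_id", "family_id", "role", "sex", "birth_date", "death_date", "emigration_date"]
LINK_COLS = ["child_id", "parent_id", "family_id", "start_date", "end_date"]
DIAGNOSIS_COLS = ["person_id", "date", "code"]
PRESCRIPTION_COLS = ["person_id", "date", "atc_code"]
OUTCOME_COLS = ["child_id", "date", "type"]
OUTCOME_TYPES = ("abuse", "death", "emigration", "age18", "study_end", "no_parents")

COVARIATE_NUMERIC = ["income", "neighborhood_resources", "mean_parental_age"]
COVARIATE_BINARY = [
    "education",
    "psychiatric_disease",
    "interparental_violence",
    "substance_abuse",
    "parental_maltreatment",
    "immigration_background",
    "refugee_status",
]
COVARIATE_CATEGORICAL = ["reconstituted_family", "n_children_category", "calendar_period"]
COVARIATE_COLS = ["family_id", "year"] + COVARIATE_NUMERIC + COVARIATE_BINARY + COVARIATE_CATEGORICAL

_DATE_COLS = {"birth_date", "death_date", "emigration_date", "date", "start_date", "end_date", "index_date"}

_TABLES = {
    "persons": PERSON_COLS,
    "links": LINK_COLS,
    "diagnoses": DIAGNOSIS_COLS,
    "prescriptions": PRESCRIPTION_COLS,
    "outcomes": OUTCOME_COLS,
    "covariates": COVARIATE_COLS,
}


@dataclass
class RegistrySnapshot:
    persons: pd.DataFrame = field(default_factory=lambda: _empty("persons"))
    links: pd.DataFrame = field(default_factory=lambda: _empty("links"))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty("diagnoses"))
    prescriptions: pd.DataFrame = field(default_factory=lambda: _empty("prescriptions"))
    outcomes: pd.DataFrame = field(default_factory=lambda: _empty("outcomes"))
    covariates: pd.DataFrame = field(default_factory=lambda: _empty("covariates"))

    @property
    def children(self) -> pd.DataFrame:
        return self.persons[self.persons["role"] == "child"]

    @property
    def parents(self) -> pd.DataFrame:
        return self.persons[self.persons["role"] == "parent"]

    def validate(self) -> None:
        for name, cols in _TABLES.items():
            df = getattr(self, name)
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"{name} table missing columns {sorted(missing)}")
        bad = set(self.outcomes["type"]) - set(OUTCOME_TYPES)
        if bad:
            raise ValueError(f"unknown outcome types {sorted(bad)}")
        if self.outcomes["child_id"].duplicated().any():
            raise ValueError("outcomes must hold exactly one first-event record per child")
        kids = self.children
        if len(kids):
            n_par = self.links.groupby("child_id")["parent_id"].nunique()
            n_par = n_par.reindex(kids["person_id"], fill_value=0)
            if (n_par < 1).any() or (n_par > 2).any():
                raise ValueError("every child must have 1-2 linked parents")

    def write(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        for name in _TABLES:
            df = getattr(self, name).copy()
            for col in df.columns:
                if col in _DATE_COLS:
                    df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
            df.to_csv(os.path.join(directory, f"{name}.tsv"), sep="\t", index=False)

    @classmethod
    def read(cls, directory) -> "RegistrySnapshot":
        tables = {}
        for name, cols in _TABLES.items():
            path = os.path.join(directory, f"{name}.tsv")
            if os.path.exists(path):
                df = pd.read_csv(path, sep="\t", dtype={"code": str, "atc_code": str})
                for col in df.columns:
                    if col in _DATE_COLS:
                        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d").values.astype("datetime64[D]")
            else:
                df = _empty(name)
            tables[name] = df
        snap = cls(**tables)
        snap.validate()
        return snap


def _empty(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in _TABLES[name]})
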