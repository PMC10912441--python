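import numpy as np
import pandas as pd
import pytest

from pseudocohort import SimConfig, default_taxonomy
from pseudocohort.registry import RegistrySnapshot


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_snapshot(families, outcomes=None, covariates=None):
    """Hand-build a RegistrySnapshot.

    ``families``: list of dicts with keys family_id, parents: [(pid, birth)],
    children: [(cid, birth)].  Dates are ISO strings.
    """
    persons, links = [], []
    for fam in families:
        fid = fam["family_id"]
        for pid, b in fam["parents"]:
            persons.append((pid, fid, "parent", "F", np.datetime64(b), pd.NaT, pd.NaT))
        for cid, b in fam["children"]:
            persons.append((cid, fid, "child", "M", np.datetime64(b), pd.NaT, pd.NaT))
            for pid, _ in fam["parents"]:
                links.append((cid, pid, fid, np.datetime64(b), pd.NaT))
    snap = RegistrySnapshot(
        persons=pd.DataFrame(
            persons,
            columns=["person_id", "family_id", "role", "sex", "birth_date", "death_date", "emigration_date"],
        ),
        links=pd.DataFrame(links, columns=["child_id", "parent_id", "family_id", "start_date", "end_date"]),
    )
    if outcomes is not None:
        snap.outcomes = pd.DataFrame(outcomes, columns=["child_id", "date", "type"])
        snap.outcomes["date"] = pd.to_datetime(snap.outcomes["date"])
    if covariates is not None:
        snap.covariates = pd.DataFrame(covariates)
    return snap


def default_covariate_row(family_id, year, **overrides):
    row = {
        "family_id": family_id,
        "year": year,
        "income": 100.0,
        "neighborhood_resources": 100.0,
        "mean_parental_age": 30.0,
        "education": 1,
        "psychiatric_disease": 0,
        "interparental_violence": 0,
        "substance_abuse": 0,
        "parental_maltreatment": 0,
        "immigration_background": 0,
        "refugee_status": 0,
        "reconstituted_family": 0,
        "n_children_category": 0,
        "calendar_period": 0,
    }
    row.update(overrides)
    return row


def events_df(rows, code_col="code"):
    df = pd.DataFrame(rows, columns=["person_id", "date", code_col])
    df["date"] = pd.to_datetime(df["date"])
    return df


@pytest.fixture(scope="session")
def small_sim_config():
    return SimConfig(
        n_families=300,
        study_start="1997-01-01",
        study_end="2004-12-31",
        category_diagnosis_rates={"Hypertension": 0.02, "UNSPECIFIC": 0.05, "OTHER": 0.05},
        prescription_rates={"N02BE": 0.5},
        true_log_rr={"Hypertension": 0.5},
        baseline_abuse_hazard=0.01,
        death_hazard=0.001,
        censoring_hazards_by_period=[0.005, 0.01, 0.02],
        seed=42,
    )
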