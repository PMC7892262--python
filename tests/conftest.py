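import numpy as np
import pandas as pd
import pytest

from raretag import AssociationPriors
from raretag.cohort import CLINICAL_COLUMNS


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a clinical table from sparse row dicts, filling sane defaults."""
    defaults = {
        "domain": "PAH",
        "diagnosis": "IPAH",
        "family_history": False,
        "sex": "F",
        "age_at_diagnosis": 50.0,
        "kco_pct_pred": 70.0,
        "fev1_pct_pred": 85.0,
        "fvc_pct_pred": 90.0,
        "tlc_pct_pred": 92.0,
        "smoking_pack_years": 0.0,
        "unrelated_index": True,
        "explained_gene": None,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"subject_id": f"S{i:03d}", **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out)[CLINICAL_COLUMNS]


@pytest.fixture
def uniform_priors():
    """All Beta hyperparameters 1 — the hand-enumeration setting."""
    return AssociationPriors(a0=1, b0=1, a1=1, b1=1, w_a=1, w_b=1)


@pytest.fixture
def default_priors():
    return AssociationPriors()


@pytest.fixture
def assembly_records():
    """10 PAH-domain records: 2 unaffected relatives, 1 unknown phenotype."""
    rows = [{} for _ in range(7)]
    rows += [{"diagnosis": "unaffected_relative"}] * 2
    rows += [{"diagnosis": "unknown"}]
    rows += [{"domain": "non-PAH", "diagnosis": "unknown", "kco_pct_pred": None,
              "age_at_diagnosis": None}] * 3
    return make_records(rows)


def random_instance(rng, k_max=10, n=25):
    """A random small (y, G, moi, priors) inference problem."""
    k = int(rng.integers(1, k_max + 1))
    # sparse counts so both MOI rules are exercised
    G = rng.choice([0, 1, 2], size=(n, k), p=[0.8, 0.15, 0.05])
    y = rng.random(n) < 0.4
    moi = "dominant" if rng.random() < 0.5 else "recessive"
    priors = AssociationPriors(
        a0=float(rng.uniform(0.5, 3)),
        b0=float(rng.uniform(0.5, 9)),
        a1=float(rng.uniform(0.5, 3)),
        b1=float(rng.uniform(0.5, 3)),
        w_a=float(rng.uniform(0.5, 2)),
        w_b=float(rng.uniform(0.5, 2)),
    )
    return y, G, moi, priors
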