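"""Cohort assembly and phenotype-tag assignment.

A deeply phenotyped pulmonary arterial hypertension (PAH) case domain is
tagged with binary phenotype labels — diagnostic categories (I/HPAH, FPAH,
PVOD/PCH) and strata of continuous variables (KCO and age-at-diagnosis
tertiles, KCO below 50% predicted).  For each tag, PAH-domain subjects
matching the rule are cases, PAH-domain subjects failing the rule or
missing the underlying variable are excluded, and every non-PAH-domain
subject serves as a control.  The resulting case/control/excluded partition
feeds one association test per (gene, tag) pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_DIAGNOSES",
    "DEFAULT_TAGS",
    "TagDefinition",
    "read_clinical_table",
    "assemble_cohort",
    "relabel_diagnoses",
    "tertile_bounds",
    "assign_tag",
    "assign_all_tags",
    "lung_disease_excluded",
    "explained_filter",
    "restrict_unrelated",
    "load_tag_registry",
    "save_tag_registry",
]

PAH_DOMAIN = "PAH"
NON_PAH_DOMAIN = "non-PAH"

#: diagnoses eligible for the diagnostic tags; anything else is relabelled
CANONICAL_DIAGNOSES = frozenset({"IPAH", "HPAH", "PVOD_PCH"})
_REMOVED_DIAGNOSES = frozenset({"unaffected_relative", "unknown"})

CLINICAL_COLUMNS = [
    "subject_id",
    "domain",
    "diagnosis",
    "family_history",
    "sex",
    "age_at_diagnosis",
    "kco_pct_pred",
    "fev1_pct_pred",
    "fvc_pct_pred",
    "tlc_pct_pred",
    "smoking_pack_years",
    "unrelated_index",
    "explained_gene",
]

STATUS_CASE = "case"
STATUS_CONTROL = "control"
STATUS_EXCLUDED = "excluded"


@dataclass(frozen=True)
class TagDefinition:
    """One binary phenotype label.

    ``kind`` determines the case rule for PAH-domain subjects:

    - ``diagnostic``: diagnosis in ``diagnoses`` (and, if
      ``require_family_history``, a recorded positive family history);
    - ``tertile_lower`` / ``tertile_upper``: ``source_variable`` at or below
      / at or above the 1/3 / 2/3 quantile of its non-missing PAH-domain
      values;
    - ``threshold_below``: ``source_variable`` strictly below ``threshold``.
    """

    name: str
    kind: str
    source_variable: str | None = None
    threshold: float | None = None
    diagnoses: frozenset[str] | None = None
    require_family_history: bool = False

    def __post_init__(self) -> None:
        numeric = {"tertile_lower", "tertile_upper", "threshold_below"}
        if self.kind in numeric and not self.source_variable:
            raise ValueError(f"tag {self.name!r}: {self.kind} needs source_variable")
        if self.kind == "diagnostic" and self.source_variable:
            raise ValueError(f"tag {self.name!r}: diagnostic tags take no source_variable")
        if self.kind == "threshold_below" and self.threshold is None:
            raise ValueError(f"tag {self.name!r}: threshold_below needs a threshold")
        if self.kind not in numeric | {"diagnostic"}:
            raise ValueError(f"tag {self.name!r}: unknown kind {self.kind!r}")


DEFAULT_TAGS: tuple[TagDefinition, ...] = (
    TagDefinition("I/HPAH", "diagnostic", diagnoses=frozenset({"IPAH", "HPAH"})),
    TagDefinition(
        "FPAH",
        "diagnostic",
        diagnoses=frozenset({"IPAH", "HPAH"}),
        require_family_history=True,
    ),
    TagDefinition("PVOD/PCH", "diagnostic", diagnoses=frozenset({"PVOD_PCH"})),
    TagDefinition("KCO lower tertile", "tertile_lower", "kco_pct_pred"),
    TagDefinition("KCO higher tertile", "tertile_upper", "kco_pct_pred"),
    TagDefinition("KCO<50%", "threshold_below", "kco_pct_pred", threshold=50.0),
    TagDefinition("young age", "tertile_lower", "age_at_diagnosis"),
    TagDefinition("old age", "tertile_upper", "age_at_diagnosis"),
)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-subject clinical table (CSV or TSV; blank / "NA" = missing)."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype={"subject_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    for col in ("family_history", "unrelated_index"):
        df[col] = df[col].map(
            {True: True, False: False, "True": True, "False": False,
             "true": True, "false": False, 1: True, 0: False, 1.0: True, 0.0: False},
            na_action="ignore",
        )
    _validate_clinical(df)
    return df


def _validate_clinical(df: pd.DataFrame) -> None:
    for col in ("age_at_diagnosis", "kco_pct_pred", "fev1_pct_pred",
                "fvc_pct_pred", "tlc_pct_pred"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise ValueError(f"{col} contains negative values")
    bad = df.loc[
        df["explained_gene"].notna() & (df["domain"] != PAH_DOMAIN), "subject_id"
    ]
    if len(bad):
        raise ValueError(
            f"explained_gene set for non-PAH-domain subjects: {list(bad)}"
        )


def assemble_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Drop PAH-domain unaffected relatives and unknown-phenotype subjects.

    Non-PAH-domain records pass through unchanged.  Duplicate subject ids
    are an error.
    """
    if records.empty:
        raise ValueError("records must be nonempty")
    dup = records["subject_id"][records["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id: {sorted(set(dup))}")
    drop = (records["domain"] == PAH_DOMAIN) & records["diagnosis"].isin(
        _REMOVED_DIAGNOSES
    )
    return records.loc[~drop].reset_index(drop=True)


def relabel_diagnoses(records: pd.DataFrame) -> pd.DataFrame:
    """Relabel verified diagnoses outside the canonical PAH categories.

    Subjects in the PAH domain whose diagnosis is not IPAH, HPAH or
    PVOD/PCH (e.g. CTEPH found on verification) become ``other``: they stay
    in the cohort for phenotype-stratum tags but never match a diagnostic
    tag such as I/HPAH.
    """
    out = records.copy()
    mask = (out["domain"] == PAH_DOMAIN) & ~out["diagnosis"].isin(
        CANONICAL_DIAGNOSES | _REMOVED_DIAGNOSES
    )
    out.loc[mask, "diagnosis"] = "other"
    return out


def tertile_bounds(values) -> tuple[float, float]:
    """Tertile cut points (1/3 and 2/3 quantiles, linear interpolation)."""
    vals = pd.Series(values).dropna().to_numpy(dtype=float)
    if vals.size < 3:
        raise ValueError("tertile_bounds needs at least 3 non-missing values")
    q_low, q_high = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0])
    return float(q_low), float(q_high)


def _diagnostic_case(tag: TagDefinition, records: pd.DataFrame) -> pd.Series:
    ok = records["diagnosis"].isin(tag.diagnoses or frozenset())
    if tag.require_family_history:
        ok &= records["family_history"].fillna(False).astype(bool)
    return ok


def assign_tag(tag: TagDefinition, records: pd.DataFrame) -> pd.DataFrame:
    """Assign case/control/excluded status for one tag.

    Returns a frame with columns ``subject_id``, ``tag_name``, ``status``.
    Tertile bounds are computed over the non-missing PAH-domain values of
    the tag's source variable; membership is inclusive at the boundary
    (value <= q_low for the lower tertile, >= q_high for the upper).
    """
    pah = records["domain"] == PAH_DOMAIN
    status = pd.Series(STATUS_EXCLUDED, index=records.index)
    status[~pah] = STATUS_CONTROL

    if tag.kind == "diagnostic":
        is_case = _diagnostic_case(tag, records)
    else:
        vals = pd.to_numeric(records[tag.source_variable], errors="coerce")
        if tag.kind in ("tertile_lower", "tertile_upper"):
            if vals[pah].notna().sum() < 3:
                # tertiles undefined: no PAH subject can be tagged
                is_case = pd.Series(False, index=records.index)
            else:
                q_low, q_high = tertile_bounds(vals[pah])
                cut = q_low if tag.kind == "tertile_lower" else q_high
                is_case = vals <= cut if tag.kind == "tertile_lower" else vals >= cut
        elif tag.kind == "threshold_below":
            is_case = vals < tag.threshold
        else:  # pragma: no cover - guarded by TagDefinition validation
            raise ValueError(f"unknown tag kind: {tag.kind!r}")
        is_case &= vals.notna()

    status[pah & is_case.fillna(False)] = STATUS_CASE
    return pd.DataFrame(
        {
            "subject_id": records["subject_id"].to_numpy(),
            "tag_name": tag.name,
            "status": status.to_numpy(),
        }
    )


def assign_all_tags(tags, records: pd.DataFrame) -> pd.DataFrame:
    """Stack :func:`assign_tag` over a tag registry."""
    return pd.concat([assign_tag(t, records) for t in tags], ignore_index=True)


def lung_disease_excluded(record) -> bool | None:
    """Whether lung-function criteria rule out significant lung disease.

    True when TLC >= 70, FVC >= 70 and FEV1 >= 60 (% predicted); False when
    a recorded value fails; None when the decision would rest on a missing
    value (not evaluable).
    """
    tlc = record.get("tlc_pct_pred")
    fvc = record.get("fvc_pct_pred")
    fev1 = record.get("fev1_pct_pred")
    checks = [(tlc, 70.0), (fvc, 70.0), (fev1, 60.0)]
    any_missing = False
    for val, cut in checks:
        if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
            any_missing = True
        elif float(val) < cut:
            return False
    return None if any_missing else True


def explained_filter(
    assignments: pd.DataFrame, gene_under_test: str, records: pd.DataFrame
) -> pd.DataFrame:
    """Restrict explained cases to the test of their explaining gene.

    A case already explained by a deleterious variant in an established
    gene G contributes only to G's own association test; for every other
    gene it is excluded.
    """
    explained = records.set_index("subject_id")["explained_gene"]
    out = assignments.copy()
    genes = out["subject_id"].map(explained)
    drop = (
        (out["status"] == STATUS_CASE)
        & genes.notna()
        & (genes != gene_under_test)
    )
    out.loc[drop, "status"] = STATUS_EXCLUDED
    return out


def restrict_unrelated(
    assignments: pd.DataFrame, records: pd.DataFrame
) -> pd.DataFrame:
    """Exclude subjects not flagged as unrelated index cases/controls."""
    unrelated = records.set_index("subject_id")["unrelated_index"]
    out = assignments.copy()
    keep = out["subject_id"].map(unrelated).fillna(False).astype(bool)
    out.loc[~keep, "status"] = STATUS_EXCLUDED
    return out


def _tag_to_dict(tag: TagDefinition) -> dict:
    return {
        "name": tag.name,
        "kind": tag.kind,
        "source_variable": tag.source_variable,
        "threshold": tag.threshold,
        "diagnoses": sorted(tag.diagnoses) if tag.diagnoses else None,
        "require_family_history": tag.require_family_history,
    }


def _tag_from_dict(d: dict) -> TagDefinition:
    return TagDefinition(
        name=d["name"],
        kind=d["kind"],
        source_variable=d.get("source_variable"),
        threshold=d.get("threshold"),
        diagnoses=frozenset(d["diagnoses"]) if d.get("diagnoses") else None,
        require_family_history=bool(d.get("require_family_history", False)),
    )


def save_tag_registry(tags, path: str | Path) -> None:
    path = Path(path)
    payload = [_tag_to_dict(t) for t in tags]
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_tag_registry(path: str | Path) -> list[TagDefinition]:
    """Load tag definitions from a JSON or YAML registry file."""
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    return [_tag_from_dict(d) for d in payload]
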