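"""End-to-end gene-tag association pipeline.

For every (gene, tag) pair: assemble the tagged case/control sets (explained
cases restricted to their own gene's test, related subjects excluded), build
the filtered genotype matrix, run the Bayesian model comparison, and report
per-model Bayes factors with the overall posterior probability of
association.  Associations with PP above the significance threshold
(default 0.75) are reported as significant.  Genotype-stratified phenotype
comparisons (KCO, age at diagnosis) use two-sided rank tests between strata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as ct
from .model import AssociationPriors, RareVariantAssociation
from .variants import (
    IMPACT_EXCLUDED,
    build_genotype_matrix,
    classify_impact,
    filter_ultrarare_deleterious,
)

__all__ = [
    "ESTABLISHED_GENES",
    "RunConfig",
    "run_associations",
    "significant",
    "genotype_strata_compare",
    "summarize_cohort",
    "results_to_tsv",
    "results_to_json",
]

ESTABLISHED_GENES = (
    "BMPR2", "ACVRL1", "ENG", "SMAD1", "SMAD4", "SMAD9", "KCNK3",
    "TBX4", "EIF2AK4", "AQP1", "ATP13A3", "GDF2", "SOX17",
)


@dataclass
class RunConfig:
    """Configuration of one association run."""

    genes: Sequence[str]
    tags: Sequence[ct.TagDefinition] = ct.DEFAULT_TAGS
    priors: AssociationPriors = field(default_factory=AssociationPriors)
    pp_min: float = 0.75
    established_genes: Sequence[str] = ESTABLISHED_GENES
    seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must be nonempty")
        if not 0.0 < self.pp_min < 1.0:
            raise ValueError("pp_min must lie in (0, 1)")


def _prepare_cohort(records: pd.DataFrame) -> pd.DataFrame:
    records = ct.assemble_cohort(records)
    return ct.relabel_diagnoses(records)


def _prepare_variants(annotations: pd.DataFrame) -> pd.DataFrame:
    filtered = filter_ultrarare_deleterious(annotations)
    filtered = filtered.copy()
    filtered["impact_class"] = classify_impact(filtered)
    return filtered.loc[filtered["impact_class"] != IMPACT_EXCLUDED].reset_index(
        drop=True
    )


def run_associations(
    records: pd.DataFrame,
    annotations: pd.DataFrame,
    genotype_source: tuple[Sequence[str], Mapping[tuple, np.ndarray]],
    config: RunConfig,
) -> pd.DataFrame:
    """Run the full (gene x tag) association grid.

    Returns one row per pair with per-model natural-log Bayes factors, the
    overall log BF and posterior probability of association, the MOI
    posterior and stratum sizes.  Pairs with an empty case or control set
    are emitted flagged, without inference.  Deterministic for a fixed
    config (the seed enters only through the large-k sampler).
    """
    records = _prepare_cohort(records)
    filtered = _prepare_variants(annotations)
    rows = []
    ss = np.random.SeedSequence(config.seed)
    for tag in config.tags:
        assignments = ct.assign_tag(tag, records)
        assignments = ct.restrict_unrelated(assignments, records)
        for gene in config.genes:
            a = ct.explained_filter(assignments, gene, records)
            cases = a.loc[a["status"] == ct.STATUS_CASE, "subject_id"].tolist()
            controls = a.loc[a["status"] == ct.STATUS_CONTROL, "subject_id"].tolist()
            overlap = set(cases) & set(controls)
            if overlap:
                raise RuntimeError(
                    f"case/control overlap for ({gene}, {tag.name}): {sorted(overlap)}"
                )
            base = {
                "gene": gene,
                "tag": tag.name,
                "n_case": len(cases),
                "n_control": len(controls),
            }
            if not cases or not controls:
                rows.append({**base, "flag": "empty_stratum", "log_bf": np.nan,
                             "pp": np.nan})
                continue
            subjects = cases + controls
            matrix = build_genotype_matrix(gene, filtered, subjects, genotype_source)
            y = np.zeros(len(subjects), dtype=bool)
            y[: len(cases)] = True
            seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            est = RareVariantAssociation(
                a0=config.priors.a0,
                b0=config.priors.b0,
                a1=config.priors.a1,
                b1=config.priors.b1,
                w_a=config.priors.w_a,
                w_b=config.priors.w_b,
                pi=config.priors.pi,
                model_weights=config.priors.model_weights,
                k_max_exact=config.priors.k_max_exact,
                random_state=seed,
            )
            if matrix.k == 0:
                est.fit(np.zeros((len(subjects), 0)), y)
            else:
                est.fit(matrix.counts, y, impact_class=matrix.impact_class)
            res = est.result(gene=gene, tag=tag.name)
            rows.append(
                {
                    **base,
                    "flag": ";".join(res.flags) if res.flags else "",
                    "log_bf": res.log_bf,
                    "pp": res.pp,
                    "best_model": res.best_model,
                    "moi_posterior_dominant": res.moi_posterior.get("dominant", np.nan),
                    "log_bf_per_model": json.dumps(
                        {k: round(v, 6) for k, v in res.log_bf_per_model.items()}
                    ),
                    "variant_posteriors": json.dumps(
                        [None if np.isnan(v) else round(float(v), 6)
                         for v in res.variant_posteriors]
                    ),
                }
            )
    return pd.DataFrame(rows)


def significant(results: pd.DataFrame, pp_min: float = 0.75) -> pd.DataFrame:
    """Associations with PP strictly above the threshold, strongest first."""
    if results.empty:
        return results
    keep = results.loc[results["pp"] > pp_min]
    return keep.sort_values(
        ["pp", "log_bf"], ascending=[False, False]
    ).reset_index(drop=True)


def genotype_strata_compare(
    records: pd.DataFrame,
    strata_labels: Mapping[str, str],
    variables: Sequence[str] = ("kco_pct_pred", "age_at_diagnosis"),
    paired: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sided rank tests of phenotype distributions between strata.

    ``strata_labels`` maps subject_id to a genotype stratum (e.g. KDR
    high-impact / KDR missense / BMPR2 / no mutation).  The default test is
    the unpaired two-sample rank-sum (Mann-Whitney) test; ``paired=True``
    switches to the signed-rank test for equally sized, paired strata.
    Strata with fewer than 2 non-missing values are skipped with a flag.
    """
    labels = records["subject_id"].map(strata_labels)
    strata = [s for s in dict.fromkeys(strata_labels.values())]
    if len(strata) < 2:
        raise ValueError("need at least 2 strata")
    rows = []
    for var in variables:
        vals = pd.to_numeric(records[var], errors="coerce")
        per = {
            s: vals[(labels == s) & vals.notna()].to_numpy() for s in strata
        }
        for i, sa in enumerate(strata):
            for sb in strata[i + 1:]:
                a, b = per[sa], per[sb]
                row = {
                    "variable": var,
                    "stratum_a": sa,
                    "stratum_b": sb,
                    "n_a": a.size,
                    "n_b": b.size,
                    "median_a": float(np.median(a)) if a.size else np.nan,
                    "q1_a": float(np.quantile(a, 0.25)) if a.size else np.nan,
                    "q3_a": float(np.quantile(a, 0.75)) if a.size else np.nan,
                    "median_b": float(np.median(b)) if b.size else np.nan,
                    "q1_b": float(np.quantile(b, 0.25)) if b.size else np.nan,
                    "q3_b": float(np.quantile(b, 0.75)) if b.size else np.nan,
                }
                if a.size < 2 or b.size < 2:
                    row.update(p_value=np.nan, flag="insufficient_data")
                else:
                    if paired:
                        if a.size != b.size:
                            row.update(p_value=np.nan, flag="unpaired_sizes")
                            rows.append(row)
                            continue
                        res = stats.wilcoxon(a, b, alternative="two-sided")
                    else:
                        tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
                        method = "exact" if tie_free and max(a.size, b.size) <= 25 else "auto"
                        res = stats.mannwhitneyu(
                            a, b, alternative="two-sided", method=method
                        )
                    row.update(p_value=float(res.pvalue), flag="")
                rows.append(row)
    return pd.DataFrame(rows)


_NUMERIC_SUMMARY_FIELDS = (
    "age_at_diagnosis", "kco_pct_pred", "fev1_pct_pred", "fvc_pct_pred",
    "tlc_pct_pred", "smoking_pack_years",
)
_CATEGORICAL_SUMMARY_FIELDS = ("sex", "diagnosis", "domain")


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Median [Q1;Q3] for numeric fields, proportions for categoricals."""
    rows = []
    for var in _NUMERIC_SUMMARY_FIELDS:
        if var not in records:
            continue
        vals = pd.to_numeric(records[var], errors="coerce").dropna()
        if vals.empty:
            rows.append({"variable": var, "kind": "numeric", "n": 0,
                         "median": np.nan, "q1": np.nan, "q3": np.nan})
        else:
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append({"variable": var, "kind": "numeric", "n": int(vals.size),
                         "median": float(med), "q1": float(q1), "q3": float(q3)})
    for var in _CATEGORICAL_SUMMARY_FIELDS:
        if var not in records:
            continue
        counts = records[var].value_counts(dropna=True)
        total = int(counts.sum())
        for level, n in counts.items():
            rows.append({"variable": var, "kind": "categorical", "level": level,
                         "n": int(n), "proportion": float(n) / total if total else np.nan})
    return pd.DataFrame(rows)


def results_to_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def results_to_json(results: pd.DataFrame, path: str | Path) -> None:
    payload = results.replace({np.nan: None}).to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
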