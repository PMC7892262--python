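"""Variant filtering, impact classification and genotype matrices.

Candidate variants are ultrarare (population minor allele frequency below
1/10 000, with absent frequencies treated as novel and hence ultrarare) and
predicted deleterious (CADD phred score >= 10, missing CADD fails).
Surviving variants fall into two impact classes:

- ``high``: frameshift, stop-gained and essential splice-site variants
  (likely loss of function);
- ``moderate_deleterious``: missense variants called deleterious by SIFT
  *and* damaging by PolyPhen-2.

Everything else is dropped.  Per gene, an N x k matrix of alternate-allele
counts over the analysis subjects carries the surviving variants into the
association model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import pathogenic_configuration  # noqa: F401  (re-exported here)

logger = logging.getLogger(__name__)

__all__ = [
    "MAF_MAX",
    "CADD_MIN",
    "HIGH_IMPACT_CONSEQUENCES",
    "IMPACT_HIGH",
    "IMPACT_MODERATE",
    "IMPACT_EXCLUDED",
    "GenotypeMatrix",
    "read_annotations",
    "filter_ultrarare_deleterious",
    "classify_impact",
    "read_genotypes_vcf",
    "build_genotype_matrix",
    "pathogenic_configuration",
]

MAF_MAX = 1e-4      # strict: maf < 1/10 000
CADD_MIN = 10.0     # inclusive: cadd >= 10

HIGH_IMPACT_CONSEQUENCES = frozenset(
    {"frameshift", "stop_gained", "splice_acceptor", "splice_donor"}
)

IMPACT_HIGH = "high"
IMPACT_MODERATE = "moderate_deleterious"
IMPACT_EXCLUDED = "excluded"

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene",
    "consequence", "maf", "cadd", "sift", "polyphen",
]


@dataclass
class GenotypeMatrix:
    """Per-gene allele-count matrix with its variant annotations.

    counts[i, j] is the number of alternate alleles subject i carries at
    variant j (diploid: 0, 1 or 2); ``impact_class[j]`` partitions the
    columns into the high / moderate-deleterious classes.
    """

    gene: str
    subjects: list[str]
    variants: pd.DataFrame
    counts: np.ndarray
    impact_class: np.ndarray

    def __post_init__(self) -> None:
        n, k = self.counts.shape if self.counts.size else (len(self.subjects), 0)
        if self.counts.size and n != len(self.subjects):
            raise ValueError("counts rows must match subjects")
        if self.counts.size and k != len(self.variants):
            raise ValueError("counts columns must match variants")
        if self.counts.size and not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("allele counts must be in {0, 1, 2}")

    @property
    def k(self) -> int:
        return len(self.variants)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the sidecar annotation TSV keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    maf = df["maf"].dropna()
    if ((maf < 0) | (maf > 1)).any():
        raise ValueError("maf must lie in [0, 1]")
    return df


def filter_ultrarare_deleterious(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep ultrarare (MAF < 1e-4 or novel) variants with CADD >= 10."""
    maf_ok = variants["maf"].isna() | (variants["maf"] < MAF_MAX)
    cadd_ok = variants["cadd"].notna() & (variants["cadd"] >= CADD_MIN)
    return variants.loc[maf_ok & cadd_ok].reset_index(drop=True)


def classify_impact(variants: pd.DataFrame | pd.Series) -> pd.Series | str:
    """Impact class per variant: high, moderate_deleterious or excluded."""
    if isinstance(variants, pd.Series):
        return _classify_row(variants)
    return variants.apply(_classify_row, axis=1)


def _classify_row(row: pd.Series) -> str:
    if row["consequence"] in HIGH_IMPACT_CONSEQUENCES:
        return IMPACT_HIGH
    if (
        row["consequence"] == "missense"
        and row.get("sift") == "deleterious"
        and row.get("polyphen") == "damaging"
    ):
        return IMPACT_MODERATE
    return IMPACT_EXCLUDED


def _variant_key(row) -> tuple:
    return (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))


def read_genotypes_vcf(path: str | Path) -> tuple[list[str], dict[tuple, np.ndarray]]:
    """Read diploid alternate-allele counts from a VCF.

    Returns the sample list and a mapping (chrom, pos, ref, alt) -> count
    vector aligned to it.  Multiallelic records contribute one key per alt
    allele.  Non-diploid calls are an error; missing calls count as 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: dict[tuple, np.ndarray] = {}
    for rec in vcf:
        gts = np.array(rec.genotypes, dtype=object)
        ploidies = {len(g) - 1 for g in rec.genotypes}  # last entry = phased flag
        if ploidies - {2}:
            raise ValueError(
                f"non-diploid genotype at {rec.CHROM}:{rec.POS} (ploidy {ploidies})"
            )
        alleles = np.array([g[:2] for g in rec.genotypes], dtype=np.int64)
        for ai, alt in enumerate(rec.ALT, start=1):
            counts = (alleles == ai).sum(axis=1)
            out[(str(rec.CHROM), int(rec.POS), rec.REF, alt)] = counts
    return samples, out


def build_genotype_matrix(
    gene: str,
    variants: pd.DataFrame,
    subjects: Sequence[str],
    genotype_source: tuple[Sequence[str], Mapping[tuple, np.ndarray]],
) -> GenotypeMatrix:
    """Assemble the N x k allele-count matrix for one gene.

    ``variants`` must already carry the filtered annotation rows for the
    gene (with an ``impact_class`` column or classifiable consequences);
    ``genotype_source`` is the (samples, counts-by-key) pair from
    :func:`read_genotypes_vcf` or an equivalent in-memory source.  Subjects
    absent from the source get a zero row, with a logged warning.
    """
    source_samples, count_map = genotype_source
    sample_index = {s: i for i, s in enumerate(source_samples)}
    subjects = list(subjects)

    gene_variants = variants.loc[variants["gene"] == gene].reset_index(drop=True)
    if "impact_class" in gene_variants.columns:
        impact = gene_variants["impact_class"].to_numpy()
    else:
        impact = classify_impact(gene_variants).to_numpy()
    keep = impact != IMPACT_EXCLUDED
    gene_variants = gene_variants.loc[keep].reset_index(drop=True)
    impact = impact[keep]

    missing_subjects = [s for s in subjects if s not in sample_index]
    if missing_subjects:
        logger.warning(
            "%d subject(s) absent from genotype source for %s; counts set to 0",
            len(missing_subjects), gene,
        )

    idx = np.array([sample_index.get(s, -1) for s in subjects], dtype=np.int64)
    present = idx >= 0
    counts = np.zeros((len(subjects), len(gene_variants)), dtype=np.int64)
    for j, (_, row) in enumerate(gene_variants.iterrows()):
        vec = count_map.get(_variant_key(row))
        if vec is None:
            continue
        counts[present, j] = np.asarray(vec)[idx[present]]
    return GenotypeMatrix(
        gene=gene,
        subjects=subjects,
        variants=gene_variants,
        counts=counts,
        impact_class=np.asarray(impact, dtype=object),
    )
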