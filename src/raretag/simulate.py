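"""Synthetic cohort generation.

Emulates the statistical structure the association analysis assumes: a
deeply phenotyped PAH case domain alongside a much larger non-PAH control
domain, ultrarare diploid genotypes (per-variant allele frequency below
1/10 000), an optional risk gene whose carriers develop a distinctive
phenotype (reduced KCO, late onset) with a configurable penetrance, and
per-field phenotype missingness.  Background phenotype distributions are
anchored to the cohort the analysis was designed for: KCO centred at 71%
predicted and age at diagnosis at 49 years, with spreads matching the
reported interquartile ranges; risk-gene carriers default to a KCO around
40% predicted and onset in the mid-sixties.

Outputs are exactly the formats the pipeline ingests — clinical CSV, VCF,
annotation TSV — plus a manifest recording the configuration and seed, and
are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CLINICAL_COLUMNS

__all__ = [
    "GeneSimSpec",
    "RiskGeneSpec",
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "inject_annotations",
    "make_worked_fixture",
]

_HIGH_CONSEQUENCES = ("stop_gained", "frameshift", "splice_acceptor", "splice_donor")

# truncation bounds for phenotype draws (% predicted / years)
_KCO_BOUNDS = (10.0, 150.0)
_AGE_BOUNDS = (1.0, 90.0)

ESTABLISHED_GENES = (
    "BMPR2", "ACVRL1", "ENG", "SMAD1", "SMAD4", "SMAD9", "KCNK3",
    "TBX4", "EIF2AK4", "AQP1", "ATP13A3", "GDF2", "SOX17",
)


@dataclass(frozen=True)
class GeneSimSpec:
    """Variant content simulated for one gene."""

    name: str
    k_high: int = 5
    k_missense: int = 10
    af_range: tuple[float, float] = (1e-6, 1e-4)
    missense_deleterious_frac: float = 0.7

    def __post_init__(self) -> None:
        lo, hi = self.af_range
        if not (0 < lo <= hi <= 1e-4):
            raise ValueError("allele frequencies must lie in (0, 1e-4]")


@dataclass(frozen=True)
class RiskGeneSpec:
    """A gene whose carriers develop the tagged phenotype.

    ``case_carrier_freq`` is the total pathogenic-configuration frequency
    among PAH cases (dominant: any risk-class allele; recessive: biallelic).
    ``penetrance`` is the probability a carrier expresses the carrier
    phenotype distributions rather than the background ones.
    """

    gene: str
    moi: str = "dominant"
    impact_class: str = "high"
    penetrance: float = 0.9
    case_carrier_freq: float = 0.01
    kco_carrier: tuple[float, float] = (40.0, 10.0)
    age_carrier: tuple[float, float] = (65.0, 12.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters (defaults mirror the study scale)."""

    n_pah_cases: int = 1000
    n_nonpah_controls: int = 10000
    genes: tuple[GeneSimSpec, ...] = (GeneSimSpec("GENE1"),)
    risk: RiskGeneSpec | None = None
    kco_background: tuple[float, float] = (71.0, 25.0)
    age_background: tuple[float, float] = (49.0, 21.0)
    missingness: dict = field(
        default_factory=lambda: {"kco_pct_pred": 0.05, "age_at_diagnosis": 0.02}
    )
    frac_explained: float = 0.2
    n_unaffected_relatives: int = 0
    n_unknown_phenotype: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for f, rate in self.missingness.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missingness rate for {f} must lie in [0, 1)")
        if self.risk is not None and self.risk.gene not in {g.name for g in self.genes}:
            raise ValueError("risk gene must appear in the simulated gene list")


@dataclass
class SimulatedCohort:
    """In-memory simulation output, writable to the pipeline's file formats."""

    clinical: pd.DataFrame
    annotations: pd.DataFrame
    genotypes: dict[str, np.ndarray]  # gene -> (N x k) counts, clinical row order
    config: SimConfig

    @property
    def subjects(self) -> list[str]:
        return self.clinical["subject_id"].tolist()

    def genotype_source(self) -> tuple[list[str], dict[tuple, np.ndarray]]:
        """(samples, counts-by-variant-key) view matching read_genotypes_vcf."""
        count_map: dict[tuple, np.ndarray] = {}
        for gene, counts in self.genotypes.items():
            ann = self.annotations[self.annotations["gene"] == gene].reset_index(drop=True)
            for j, row in ann.iterrows():
                key = (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
                count_map[key] = counts[:, j]
        return self.subjects, count_map

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write clinical.csv, variants.vcf, annotations.tsv and manifest.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "clinical": outdir / "clinical.csv",
            "vcf": outdir / "variants.vcf",
            "annotations": outdir / "annotations.tsv",
            "manifest": outdir / "manifest.json",
        }
        clin = self.clinical.copy()
        for col in ("age_at_diagnosis", "kco_pct_pred", "fev1_pct_pred",
                    "fvc_pct_pred", "tlc_pct_pred", "smoking_pack_years"):
            clin[col] = clin[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        clin.to_csv(paths["clinical"], index=False, na_rep="")
        ann = self.annotations.copy()
        ann["maf"] = ann["maf"].map(lambda v: f"{v:.3e}")
        ann["cadd"] = ann["cadd"].map(lambda v: f"{v:.2f}")
        ann.to_csv(paths["annotations"], sep="\t", index=False, na_rep="NA")
        paths["vcf"].write_text(self._vcf_text())
        cfg = dataclasses.asdict(self.config)
        paths["manifest"].write_text(json.dumps(cfg, indent=2, default=list) + "\n")
        return paths

    def _vcf_text(self) -> str:
        subjects = self.subjects
        lines = [
            "##fileformat=VCFv4.2",
            "##source=raretag-simulate",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ]
        for chrom in dict.fromkeys(self.annotations["chrom"]):
            lines.append(f"##contig=<ID={chrom}>")
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects)
        )
        gt_text = {0: "0/0", 1: "0/1", 2: "1/1"}
        for gene, counts in self.genotypes.items():
            ann = self.annotations[self.annotations["gene"] == gene].reset_index(drop=True)
            for j, row in ann.iterrows():
                gts = "\t".join(gt_text[int(c)] for c in counts[:, j])
                lines.append(
                    f"{row['chrom']}\t{row['pos']}\t{gene}_{j}\t{row['ref']}\t"
                    f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}"
                )
        return "\n".join(lines) + "\n"


def _truncated_normal(rng, mean, sd, bounds, size):
    lo, hi = bounds
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # redraw; bounds are far in the tails
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def inject_annotations(variants: pd.DataFrame, cfg: SimConfig, rng) -> pd.DataFrame:
    """Attach consequences, CADD, SIFT/PolyPhen and MAF to simulated variants.

    High-impact variants draw a loss-of-function consequence and CADD >= 10;
    a configurable fraction of missense variants is deleterious by both
    SIFT and PolyPhen (the rest fail the conjunction).  MAF equals the
    generating allele frequency.
    """
    out = variants.copy()
    n = len(out)
    conseq = np.empty(n, dtype=object)
    cadd = np.empty(n)
    sift = np.full(n, None, dtype=object)
    polyphen = np.full(n, None, dtype=object)
    spec_by_gene = {g.name: g for g in cfg.genes}
    for i, row in out.iterrows():
        if row["sim_class"] == "high":
            conseq[i] = _HIGH_CONSEQUENCES[rng.integers(len(_HIGH_CONSEQUENCES))]
            cadd[i] = rng.uniform(20.0, 45.0)
        else:
            conseq[i] = "missense"
            frac = spec_by_gene[row["gene"]].missense_deleterious_frac
            if rng.random() < frac:
                sift[i], polyphen[i] = "deleterious", "damaging"
                cadd[i] = rng.uniform(15.0, 35.0)
            else:
                # fails the SIFT∧PolyPhen conjunction in one of three ways
                mode = rng.integers(3)
                sift[i] = "tolerated" if mode in (0, 2) else "deleterious"
                polyphen[i] = "benign" if mode in (1, 2) else "damaging"
                cadd[i] = rng.uniform(5.0, 25.0)
    out["consequence"] = conseq
    out["maf"] = out["af"]
    out["cadd"] = np.round(cadd, 2)
    out["sift"] = sift
    out["polyphen"] = polyphen
    return out[["chrom", "pos", "ref", "alt", "gene",
                "consequence", "maf", "cadd", "sift", "polyphen", "sim_class", "af"]]


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort: clinical table, genotypes, annotations."""
    rng = np.random.default_rng(cfg.seed)
    n_cases = cfg.n_pah_cases
    n_ctrl = cfg.n_nonpah_controls
    n_extra = cfg.n_unaffected_relatives + cfg.n_unknown_phenotype
    case_ids = [f"P{i:05d}" for i in range(n_cases + n_extra)]
    ctrl_ids = [f"C{i:05d}" for i in range(n_ctrl)]
    subjects = case_ids + ctrl_ids
    n_total = len(subjects)

    # ---- variants and genotypes ------------------------------------------
    var_rows = []
    genotypes: dict[str, np.ndarray] = {}
    for g_idx, gene_spec in enumerate(cfg.genes):
        k = gene_spec.k_high + gene_spec.k_missense
        afs = rng.uniform(*gene_spec.af_range, size=k)
        counts = rng.binomial(2, afs[None, :], size=(n_total, k)).astype(np.int64)
        genotypes[gene_spec.name] = counts
        for j in range(k):
            var_rows.append(
                {
                    "chrom": str(g_idx + 1),
                    "pos": 1000 + 10 * j,
                    "ref": "A",
                    "alt": "T",
                    "gene": gene_spec.name,
                    "sim_class": "high" if j < gene_spec.k_high else "missense",
                    "af": afs[j],
                }
            )
    variants = pd.DataFrame(var_rows)
    annotations = inject_annotations(variants, cfg, rng)

    # ---- risk-gene overlay among PAH cases -------------------------------
    carrier = np.zeros(n_total, dtype=bool)
    if cfg.risk is not None:
        risk = cfg.risk
        gene_spec = next(g for g in cfg.genes if g.name == risk.gene)
        counts = genotypes[risk.gene]
        ann_g = annotations.loc[annotations["gene"] == risk.gene].reset_index(drop=True)
        if risk.impact_class == "high":
            keep = ann_g["sim_class"] == "high"
        elif risk.impact_class == "moderate_deleterious":
            # only missense that survive the SIFT∧PolyPhen gate downstream
            keep = (
                (ann_g["sim_class"] == "missense")
                & (ann_g["sift"] == "deleterious")
                & (ann_g["polyphen"] == "damaging")
            )
        else:
            keep = pd.Series(True, index=ann_g.index)
        risk_cols = np.flatnonzero(keep.to_numpy())
        if risk_cols.size == 0:
            raise ValueError(
                f"risk gene {risk.gene} has no variants of class {risk.impact_class}"
            )
        if risk.moi == "recessive":
            expected = risk.case_carrier_freq * n_cases
            if expected < 1:
                import warnings

                warnings.warn(
                    f"recessive risk config expects {expected:.2f} (<1) biallelic "
                    "carriers among cases", stacklevel=2,
                )
        chosen = np.flatnonzero(rng.random(n_cases) < risk.case_carrier_freq)
        # a carrier's variant follows the variant frequency spectrum, so
        # recurrent (higher-AF) variants are seen in several carriers
        afs_risk = annotations.loc[annotations["gene"] == risk.gene, "af"].to_numpy()
        p_var = afs_risk[risk_cols] / afs_risk[risk_cols].sum()
        for i in chosen:
            if risk.moi == "dominant":
                j = rng.choice(risk_cols, p=p_var)
                counts[i, j] = max(counts[i, j], 1)
            else:  # biallelic: hom at one variant or phase-unaware compound het
                if rng.random() < 0.5 or risk_cols.size < 2:
                    j = rng.choice(risk_cols, p=p_var)
                    counts[i, j] = 2
                else:
                    j1, j2 = rng.choice(risk_cols, size=2, replace=False, p=p_var)
                    counts[i, j1] = max(counts[i, j1], 1)
                    counts[i, j2] = max(counts[i, j2], 1)
        carrier[chosen] = True

    # ---- phenotypes -------------------------------------------------------
    affected = carrier.copy()
    if cfg.risk is not None:
        affected[:n_cases] &= rng.random(n_cases) < cfg.risk.penetrance

    kco = _truncated_normal(rng, *cfg.kco_background, _KCO_BOUNDS, n_total)
    age = _truncated_normal(rng, *cfg.age_background, _AGE_BOUNDS, n_total)
    if cfg.risk is not None and affected.any():
        n_aff = int(affected.sum())
        kco[affected] = _truncated_normal(
            rng, *cfg.risk.kco_carrier, _KCO_BOUNDS, n_aff
        )
        age[affected] = _truncated_normal(
            rng, *cfg.risk.age_carrier, _AGE_BOUNDS, n_aff
        )

    # diagnosis mix for the case domain (idiopathic-dominated, as observed)
    diag = rng.choice(
        ["IPAH", "HPAH", "PVOD_PCH", "other"],
        size=n_cases + n_extra,
        p=[0.866, 0.065, 0.018, 0.051],
    ).astype(object)
    # removable records appended after the affected cases
    removable = (["unaffected_relative"] * cfg.n_unaffected_relatives
                 + ["unknown"] * cfg.n_unknown_phenotype)
    if removable:
        diag[n_cases:] = removable

    family_history = diag == "HPAH"
    sex = rng.choice(["F", "M"], size=n_total, p=[0.68, 0.32])

    explained = np.full(n_total, None, dtype=object)
    eligible = np.flatnonzero(~carrier[:n_cases])
    n_expl = int(round(cfg.frac_explained * n_cases))
    if n_expl and eligible.size:
        chosen = rng.choice(eligible, size=min(n_expl, eligible.size), replace=False)
        explained[chosen] = rng.choice(ESTABLISHED_GENES, size=chosen.size)

    clinical = pd.DataFrame(
        {
            "subject_id": subjects,
            "domain": ["PAH"] * (n_cases + n_extra) + ["non-PAH"] * n_ctrl,
            "diagnosis": list(diag) + ["unknown"] * n_ctrl,
            "family_history": list(family_history) + [False] * n_ctrl,
            "sex": sex,
            "age_at_diagnosis": np.round(age, 2),
            "kco_pct_pred": np.round(kco, 2),
            "fev1_pct_pred": np.round(
                _truncated_normal(rng, 85.0, 15.0, (20.0, 150.0), n_total), 2
            ),
            "fvc_pct_pred": np.round(
                _truncated_normal(rng, 90.0, 15.0, (20.0, 150.0), n_total), 2
            ),
            "tlc_pct_pred": np.round(
                _truncated_normal(rng, 92.0, 14.0, (20.0, 150.0), n_total), 2
            ),
            "smoking_pack_years": np.round(
                np.maximum(rng.normal(5.0, 10.0, n_total), 0.0), 1
            ),
            "unrelated_index": [True] * n_total,
            "explained_gene": explained,
        }
    )[CLINICAL_COLUMNS]

    # controls are not phenotyped on the PAH axes
    ctrl_rows = clinical.index[clinical["domain"] == "non-PAH"]
    clinical.loc[ctrl_rows, ["age_at_diagnosis", "kco_pct_pred"]] = np.nan

    case_rows = clinical.index[clinical["domain"] == "PAH"]
    for col, rate in cfg.missingness.items():
        if rate > 0:
            drop = rng.random(case_rows.size) < rate
            clinical.loc[case_rows[drop], col] = np.nan

    return SimulatedCohort(
        clinical=clinical,
        annotations=annotations,
        genotypes=genotypes,
        config=cfg,
    )


def make_worked_fixture() -> dict:
    """Tiny hand-checkable fixtures for the inference and VCF plumbing.

    Returns a dict with:

    - ``y``, ``G``: the 4-subject, 2-variant dominant enumeration fixture
      (subject 1 het at variant 1, subject 2 het at variant 2, subjects 3-4
      non-carriers; first two subjects are cases);
    - ``subjects``, ``vcf_text``, ``annotations``, ``expected_counts``: a
      6-subject x 3-variant genotype transcription fixture.
    """
    y = np.array([1, 1, 0, 0], dtype=bool)
    G = np.array([[1, 0], [0, 1], [0, 0], [0, 0]], dtype=np.int64)

    subjects = [f"S{i}" for i in range(1, 7)]
    counts = np.array(
        [
            [0, 1, 0],
            [1, 0, 0],
            [2, 0, 1],
            [0, 0, 0],
            [0, 1, 1],
            [0, 0, 2],
        ],
        dtype=np.int64,
    )
    annotations = pd.DataFrame(
        {
            "chrom": ["7"] * 3,
            "pos": [100, 200, 300],
            "ref": ["A", "C", "G"],
            "alt": ["T", "G", "A"],
            "gene": ["GENEX"] * 3,
            "consequence": ["stop_gained", "missense", "frameshift"],
            "maf": [5e-5, 2e-5, np.nan],
            "cadd": [35.0, 22.0, 28.0],
            "sift": [None, "deleterious", None],
            "polyphen": [None, "damaging", None],
        }
    )
    gt_text = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=7>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects),
    ]
    for j, (_, row) in enumerate(annotations.iterrows()):
        gts = "\t".join(gt_text[int(c)] for c in counts[:, j])
        lines.append(
            f"{row['chrom']}\t{row['pos']}\tv{j}\t{row['ref']}\t{row['alt']}"
            f"\t.\tPASS\t.\tGT\t{gts}"
        )
    return {
        "y": y,
        "G": G,
        "subjects": subjects,
        "vcf_text": "\n".join(lines) + "\n",
        "annotations": annotations,
        "expected_counts": counts,
    }
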