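"""Seeded synthetic cohort generator.

Emulates the statistical structure of a methylmalonic aciduria fibroblast
cohort so the full analysis pipeline can be exercised and validated without
restricted patient data:

* a latent disease-severity axis driving correlated mixed-type phenotypes,
  including the propionate-incorporation assays (PI, PI+) which decrease with
  severity and the five binary clinical-severity-score components which
  increase with it,
* paired RNA/protein expression with genotype-group effects (MMUT down, OGDH
  protein down, GLUD1/ALDH2 up in the MMUT-deficient group) and tunable
  per-gene transcript-protein coupling,
* variant tables with planted biallelic genotypes (consequence classes drawn
  with the frequencies of a large MMUT cohort allele census) plus decoy
  alleles that each violate at least one triage filter,
* [U-13C]glutamine isotopologue peak tables generated from the forward TCA
  labeling model under condition-specific parameters,
* IP-MS identification and quantification tables with bait-specific prey
  enrichment over a shared background.

Every random draw flows from one seed through named substreams, so the full
bundle is byte-reproducible and layers can be regenerated independently.
The ``truth`` mapping records every generating parameter for downstream
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .tracing import TRACED_METABOLITES, TracingParams, simulate_labeling

__all__ = [
    "PhenotypeSpec",
    "CohortConfig",
    "CohortBundle",
    "default_phenotype_specs",
    "default_effect_table",
    "simulate_phenotypes",
    "simulate_paired_omics",
    "simulate_variants",
    "simulate_tracing",
    "simulate_ipms",
    "simulate_cohort",
]

GROUP_DEFICIENT = "MMUT-deficient"
GROUP_OTHER = "other-MMA"
GROUP_UNAFFECTED = "unaffected"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeSpec:
    """One simulated phenotype variable.

    ``loading`` scales the latent severity contribution; ``noise_sd`` the
    independent Gaussian noise (continuous variables only); ``log_scale``
    exponentiates the linear predictor so the variable is strictly positive
    (typical of concentrations and activities).
    """

    name: str
    kind: str = "continuous"  # continuous | binary
    loading: float = 0.0
    noise_sd: float = 1.0
    log_scale: bool = False
    category: str = "clinical-chemistry"

    def __post_init__(self):
        if self.kind not in {"continuous", "binary"}:
            raise ConfigError(f"{self.name}: unknown kind {self.kind!r}")
        if self.noise_sd <= 0:
            raise ConfigError(f"{self.name}: noise_sd must be positive")


def default_phenotype_specs() -> list[PhenotypeSpec]:
    """The default phenome: five severity-score flags, the PI assays, classic
    clinical-chemistry markers and treatments loading on severity, plus a
    block of null variables carrying no severity signal."""
    P = PhenotypeSpec
    specs = [
        # clinical severity score components (binary, severity-increasing)
        P("early_onset", "binary", 1.5, category="presentation"),
        P("neurological_abnormalities", "binary", 1.2, category="course"),
        P("kidney_impairment", "binary", 1.0, category="course"),
        P("hematological_abnormalities", "binary", 0.8, category="course"),
        P("failure_to_thrive", "binary", 1.0, category="presentation"),
        # in-vitro biochemistry: activities fall with severity
        P("PI", "continuous", -1.0, 0.5, log_scale=True, category="in-vitro"),
        P("PI_plus", "continuous", -1.2, 0.4, log_scale=True, category="in-vitro"),
        P("MMUT_activity", "continuous", -1.1, 0.5, log_scale=True, category="in-vitro"),
        # clinical chemistry
        P("methylmalonic_acid_plasma", "continuous", 1.0, 0.5, log_scale=True),
        P("methylmalonic_acid_urine", "continuous", 0.9, 0.6, log_scale=True),
        P("ammonia", "continuous", 0.8, 0.6, log_scale=True),
        P("blood_pH", "continuous", -0.6, 0.5),
        P("bicarbonate", "continuous", -0.5, 0.7),
        P("propionylcarnitine", "continuous", 0.7, 0.6, log_scale=True),
        P("glycine_plasma", "continuous", 0.4, 0.8, log_scale=True),
        P("creatinine", "continuous", 0.5, 0.8, log_scale=True),
        P("hemoglobin", "continuous", -0.4, 0.8),
        P("age_at_onset_days", "continuous", -0.8, 0.6, log_scale=True,
          category="presentation"),
        # presentation / course (binary)
        P("metabolic_acidosis", "binary", 1.0, category="presentation"),
        P("hyperammonemia", "binary", 0.9, category="presentation"),
        P("muscular_hypotonia", "binary", 0.8, category="course"),
        P("movement_disorder", "binary", 0.6, category="course"),
        P("intellectual_impairment", "binary", 0.7, category="course"),
        P("metabolic_stroke", "binary", 0.5, category="course"),
        # treatments
        P("protein_restriction", "binary", 0.9, category="treatment"),
        P("carnitine_supplementation", "binary", 0.7, category="treatment"),
        P("cobalamin_treatment", "binary", 0.4, category="treatment"),
        P("tube_feeding", "binary", 0.6, category="treatment"),
    ]
    # null block: independent of severity
    for i in range(1, 16):
        specs.append(P(f"null_marker_{i:02d}", "continuous", 0.0, 1.0))
    for i in range(1, 8):
        specs.append(P(f"null_flag_{i:02d}", "binary", 0.0))
    return specs


def default_effect_table() -> dict[str, tuple[float, float]]:
    """Genotype-group log2 fold changes (rna, protein) for the MMUT-deficient
    group: MMUT down at both layers, OGDH protein down, GLUD1/ALDH2 up, PDK4
    transcript up."""
    return {
        "MMUT": (-1.0, -1.0),
        "OGDH": (-0.2, -0.8),
        "GLUD1": (0.2, 0.8),
        "ALDH2": (0.5, 0.5),
        "PDK4": (0.8, 0.1),
    }


#: named genes always present in the expression matrices (TCA cycle and
#: anaplerotic enzymes plus non-mitochondrial isoform controls)
NAMED_GENES = [
    "MMUT", "OGDH", "GLUD1", "ALDH2", "PDK4", "CS", "ACO2", "MDH2",
    "SUCLA2", "GLS", "GOT2", "DLST", "IDH2", "FH", "SDHA",
    "ACO1", "MDH1", "IDH1", "GOT1", "PC",
]

MITO_GENES = set(NAMED_GENES) - {"ACO1", "MDH1", "IDH1", "GOT1"}


@dataclass
class CohortConfig:
    n_case: int = 150
    n_other: int = 60
    n_control: int = 20
    n_genes: int = 4318
    seed: int = 0
    severity_sd: float = 1.0
    case_severity_shift: float = 1.0
    other_severity_shift: float = 0.5
    rna_protein_coupling: float | dict[str, float] = 0.15
    effect_table: dict[str, tuple[float, float]] = field(default_factory=default_effect_table)
    phenotype_specs: list[PhenotypeSpec] = field(default_factory=default_phenotype_specs)
    gene_sd: float = 0.5
    shared_mean_sd: float = 0.8
    protein_offset_sd: float = 1.2
    base_log2_abundance: float = 7.0

    def __post_init__(self):
        for name in ("n_case", "n_other", "n_control", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.severity_sd <= 0:
            raise ConfigError("severity_sd must be positive")
        couplings = (
            self.rna_protein_coupling.values()
            if isinstance(self.rna_protein_coupling, dict)
            else [self.rna_protein_coupling]
        )
        if any(not -1.0 <= c <= 1.0 for c in couplings):
            raise ConfigError("rna_protein_coupling must lie in [-1, 1]")
        if not isinstance(self.effect_table, dict) or any(
            len(v) != 2 for v in self.effect_table.values()
        ):
            raise ConfigError("effect_table must map gene -> (rna_log2fc, protein_log2fc)")
        names = [s.name for s in self.phenotype_specs]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate phenotype variable names")


@dataclass
class CohortBundle:
    phenotypes: pd.DataFrame
    phenotype_meta: pd.DataFrame
    rna: pd.DataFrame
    protein: pd.DataFrame
    variants: pd.DataFrame
    tracing_peaks: pd.DataFrame
    tracing_standards: pd.DataFrame
    ipms_ids: pd.DataFrame
    ipms_quant: pd.DataFrame
    group_labels: pd.Series
    truth: dict

    def to_dir(self, path: str | Path) -> dict[str, Path]:
        """Write every table as TSV plus truth.json; returns the file map."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        files = {}
        tables = {
            "phenotypes.tsv": self.phenotypes.reset_index(names="individual_id"),
            "phenotype_meta.tsv": self.phenotype_meta,
            "rna.tsv": self.rna.reset_index(names="gene"),
            "protein.tsv": self.protein.reset_index(names="gene"),
            "variants.tsv": self.variants,
            "tracing.tsv": self.tracing_peaks,
            "tracing_standards.tsv": self.tracing_standards,
            "ipms_ids.tsv": self.ipms_ids,
            "ipms_quant.tsv": self.ipms_quant.reset_index(names="protein"),
            "groups.tsv": self.group_labels.rename("group").rename_axis("sample").reset_index(),
        }
        for name, df in tables.items():
            f = path / name
            df.to_csv(f, sep="\t", index=False)
            files[name] = f
        f = path / "truth.json"
        f.write_text(json.dumps(self.truth, indent=1, sort_keys=True, default=str))
        files["truth.json"] = f
        return files


# ---------------------------------------------------------------------------
# layer generators


def simulate_phenotypes(
    latent_severity: pd.Series, specs: list[PhenotypeSpec], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype table from a latent severity axis.

    Continuous: loading*severity + noise (exponentiated when log-scale).
    Binary: Bernoulli with a logistic link on loading*severity.
    Returns (table indexed by individual, per-variable metadata).
    """
    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        raise ConfigError("duplicate phenotype variable names")
    sev = latent_severity.to_numpy(dtype=float)
    n = sev.size
    data = {}
    meta = []
    for s in specs:
        if s.kind == "continuous":
            lin = s.loading * sev + s.noise_sd * rng.standard_normal(n)
            data[s.name] = np.exp(lin) if s.log_scale else lin
        else:
            data[s.name] = (rng.random(n) < expit(s.loading * sev)).astype(int)
        meta.append((s.name, s.kind, s.category, s.loading, s.noise_sd, s.log_scale))
    table = pd.DataFrame(data, index=latent_severity.index)
    meta_df = pd.DataFrame(
        meta, columns=["variable", "type", "category", "loading", "noise_sd", "log_scale"]
    )
    return table, meta_df


def _gene_names(n_genes: int, effect_table: dict) -> list[str]:
    genes = list(NAMED_GENES)
    for g in effect_table:
        if g not in genes:
            genes.append(g)
    if n_genes < len(genes):
        genes = genes[:n_genes]
    genes += [f"GENE{i:05d}" for i in range(1, n_genes - len(genes) + 1)]
    return genes


def simulate_paired_omics(
    group_labels: pd.Series,
    effect_table: dict[str, tuple[float, float]],
    coupling: float | dict[str, float],
    n_genes: int,
    rng: np.random.Generator,
    gene_sd: float = 0.5,
    shared_mean_sd: float = 0.8,
    protein_offset_sd: float = 1.2,
    base_log2_abundance: float = 7.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired RNA/protein abundance matrices (genes x samples).

    On the log2 scale, per gene g and sample s:

        rna     = mu_g + fc_rna * 1[deficient] + sd * z1
        protein = mu_g + off_g + fc_prot * 1[deficient] + sd * (c*z1 + sqrt(1-c^2)*z2)

    so genes with coupling c have Pearson correlation c between log-layers
    (Spearman ~ (6/pi) arcsin(c/2) under Gaussianity).  The shared gene mean
    mu_g induces the modest sample-level concordance typical of
    proteogenomic data.  Returned matrices hold raw abundances (2**log2).
    """
    if group_labels.empty:
        raise ConfigError("group labels must be non-empty")
    genes = _gene_names(n_genes, effect_table)
    known = set(genes)
    unknown = [g for g in effect_table if g not in known]
    if unknown:
        raise ConfigError(f"effect_table genes not in matrix: {unknown}")
    samples = list(group_labels.index)
    n, p = len(samples), len(genes)
    deficient = (group_labels == GROUP_DEFICIENT).to_numpy(dtype=float)

    mu = base_log2_abundance + shared_mean_sd * rng.standard_normal(p)
    off = protein_offset_sd * rng.standard_normal(p)
    z1 = rng.standard_normal((p, n))
    z2 = rng.standard_normal((p, n))

    if isinstance(coupling, dict):
        c = np.array([coupling.get(g, 0.0) for g in genes])
    else:
        c = np.full(p, float(coupling))
    fc_rna = np.array([effect_table.get(g, (0.0, 0.0))[0] for g in genes])
    fc_prot = np.array([effect_table.get(g, (0.0, 0.0))[1] for g in genes])

    rna_log2 = mu[:, None] + fc_rna[:, None] * deficient[None, :] + gene_sd * z1
    prot_noise = c[:, None] * z1 + np.sqrt(1.0 - c[:, None] ** 2) * z2
    prot_log2 = (
        mu[:, None]
        + off[:, None]
        + fc_prot[:, None] * deficient[None, :]
        + gene_sd * prot_noise
    )
    rna = pd.DataFrame(2.0 ** rna_log2, index=genes, columns=samples)
    protein = pd.DataFrame(2.0 ** prot_log2, index=genes, columns=samples)
    return rna, protein


#: allele census of a large MMUT-deficient cohort, used as consequence-class
#: sampling frequencies for planted causal alleles
ALLELE_CENSUS = {
    "missense": 165,
    "truncating": 105,
    "splicing": 21,
    "inframe_deletion": 2,
    "cnv": 3,
}

_OTHER_MMA_GENES = ["ACSF3"] * 17 + ["TCN2"] * 3 + ["SUCLA2"] + ["MMAB"]


def simulate_variants(
    group_labels: pd.Series, rng: np.random.Generator, decoy_rate: float = 2.0,
    other_mma_diagnosed_frac: float = 22 / 60,
) -> tuple[pd.DataFrame, dict]:
    """Variant table with planted biallelic genotypes and filter-violating decoys.

    MMUT-deficient individuals receive a biallelic MMUT genotype (homozygous
    or compound het, consequence classes drawn per the allele census); a
    fraction of other-MMA individuals receive biallelic genotypes in
    ACSF3/TCN2/SUCLA2/MMAB.  Decoy alleles each violate at least one filter
    (too common, weak read support, or synonymous without annotations) and a
    few passing-but-monoallelic hets exercise the no-single-het rule.
    """
    cons_names = list(ALLELE_CENSUS)
    cons_p = np.array(list(ALLELE_CENSUS.values()), dtype=float)
    cons_p /= cons_p.sum()
    rows: list[dict] = []
    truth: dict[str, dict] = {}
    counter = [0]

    def vid() -> str:
        counter[0] += 1
        return f"v{counter[0]:05d}"

    def causal_allele(ind: str, gene: str, zygosity: str) -> dict:
        cons = rng.choice(cons_names, p=cons_p)
        fwd, rev = int(rng.integers(3, 30)), int(rng.integers(3, 30))
        clin = rng.choice(["P", "LP", "none"], p=[0.5, 0.3, 0.2])
        row = {
            "individual_id": ind,
            "variant_id": vid(),
            "gene": gene,
            "consequence": cons,
            "zygosity": zygosity,
            "population_max_af": float(rng.uniform(0, 0.005)),
            "fwd_reads": fwd,
            "rev_reads": rev,
            "coverage": fwd + rev + int(rng.integers(0, 10)),
            "clinvar_class": clin,
            "intervar_class": rng.choice(["P", "LP", "VUS"], p=[0.3, 0.3, 0.4]),
            "dbscsnv_ada": float(rng.uniform(0.65, 1.0)) if cons == "splicing" else np.nan,
            "dbscsnv_rf": float(rng.uniform(0.65, 1.0)) if cons == "splicing" else np.nan,
        }
        if cons == "cnv":  # depth-based call, no per-read support
            row["fwd_reads"] = row["rev_reads"] = 0
            row["coverage"] = 0
        return row

    def decoy(ind: str) -> dict:
        mode = rng.choice(["common", "reads", "synonymous"])
        fwd, rev = int(rng.integers(3, 30)), int(rng.integers(3, 30))
        row = {
            "individual_id": ind,
            "variant_id": vid(),
            "gene": f"DECOY{int(rng.integers(1, 30)):03d}",
            "consequence": "missense",
            "zygosity": rng.choice(["het", "hom"]),
            "population_max_af": float(rng.uniform(0, 0.005)),
            "fwd_reads": fwd,
            "rev_reads": rev,
            "coverage": fwd + rev,
            "clinvar_class": "none",
            "intervar_class": "VUS",
            "dbscsnv_ada": np.nan,
            "dbscsnv_rf": np.nan,
        }
        if mode == "common":
            row["population_max_af"] = float(rng.uniform(0.02, 0.3))
        elif mode == "reads":
            which = rng.choice(["fwd", "rev", "cov"])
            if which == "fwd":
                row["fwd_reads"] = int(rng.integers(0, 2))
            elif which == "rev":
                row["rev_reads"] = int(rng.integers(0, 2))
            else:
                row["coverage"] = int(rng.integers(0, 8))
                row["fwd_reads"] = row["rev_reads"] = 2
        else:
            row["consequence"] = "synonymous"
        return row

    other_pool = list(_OTHER_MMA_GENES)
    for ind, group in group_labels.items():
        ind = str(ind)
        if group == GROUP_DEFICIENT:
            gene = "MMUT"
        elif group == GROUP_OTHER and rng.random() < other_mma_diagnosed_frac:
            gene = other_pool[int(rng.integers(0, len(other_pool)))]
        else:
            gene = None
        if gene is not None:
            if rng.random() < 0.4:
                rows.append(causal_allele(ind, gene, "hom"))
                truth[ind] = {"gene": gene, "call_type": "homozygous"}
            else:
                rows.append(causal_allele(ind, gene, "het"))
                rows.append(causal_allele(ind, gene, "het"))
                truth[ind] = {"gene": gene, "call_type": "compound_het"}
        for _ in range(rng.poisson(decoy_rate)):
            rows.append(decoy(ind))
        if rng.random() < 0.3:  # passing but monoallelic carrier variant
            row = causal_allele(ind, f"CARRIER{int(rng.integers(1, 40)):03d}", "het")
            rows.append(row)
    df = pd.DataFrame(rows)
    return df, {"diagnosed": truth}


#: condition-specific labeling parameters: the MMUT-deficient condition shows
#: less unlabeled anaplerotic dilution (a) and a higher reductive fraction (r)
DEFAULT_TRACING_CONDITIONS = {
    "control": {"r": 0.05, "a": 0.5, "e": 0.95, "turns": 3},
    "MMUT-deficient": {"r": 0.3, "a": 0.15, "e": 0.95, "turns": 3},
}

_POLARITY = {m: "neg" for m in TRACED_METABOLITES}
_POLARITY["glutamate"] = "pos"  # amino acid, positive-mode internal standard


def simulate_tracing(
    rng: np.random.Generator,
    conditions: dict[str, dict] | None = None,
    n_per_condition: int = 4,
    fraction_noise_sd: float = 0.01,
    pool_reduction_deficient: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Isotopologue peak tables from the forward labeling model.

    Per condition, fractions come from ``simulate_labeling`` perturbed by
    truncated Gaussian noise and renormalized; areas are fractions times a
    condition-scaled pool size times the sample's internal-standard response.
    The deficient condition carries globally reduced TCA pool sizes.
    """
    conditions = conditions or DEFAULT_TRACING_CONDITIONS
    base_pool = {m: float(rng.lognormal(mean=np.log(100.0), sigma=0.2)) for m in TRACED_METABOLITES}
    peak_rows, is_rows = [], []
    truth = {"conditions": {}, "base_pool": base_pool}
    for cond, pdict in conditions.items():
        params = TracingParams(**pdict)
        sim = simulate_labeling(params)
        truth["conditions"][cond] = dict(pdict)
        pool_scale = pool_reduction_deficient if cond != "control" else 1.0
        for i in range(1, n_per_condition + 1):
            sample = f"{cond}_{i}"
            is_area = {
                "pos": float(rng.lognormal(np.log(1000.0), 0.1)),
                "neg": float(rng.lognormal(np.log(1000.0), 0.1)),
            }
            for pol, area in is_area.items():
                is_rows.append({"sample": sample, "polarity": pol, "area": area})
            for met in TRACED_METABOLITES:
                f = sim[met].fractions.copy()
                f = np.clip(f + fraction_noise_sd * rng.standard_normal(f.size), 0, None)
                f = f / f.sum()
                pool = base_pool[met] * pool_scale * float(rng.lognormal(0, 0.15))
                pol = _POLARITY[met]
                for idx, frac in enumerate(f):
                    peak_rows.append(
                        {
                            "sample": sample,
                            "metabolite": met,
                            "isotopologue": idx,
                            "area": frac * pool * is_area[pol],
                            "polarity": pol,
                        }
                    )
    return pd.DataFrame(peak_rows), pd.DataFrame(is_rows), truth


EXPERIMENTAL_BAITS = ["MMUT", "MMAA", "MMAB", "MCEE"]
CONTROL_BAITS = ["EV", "VLCAD"]
BAIT_ROLES = {**{b: "experimental" for b in EXPERIMENTAL_BAITS},
              **{b: "negative_control" for b in CONTROL_BAITS}}


def simulate_ipms(
    rng: np.random.Generator,
    n_core_prey: int = 37,
    n_partial_prey: int = 20,
    n_background: int = 150,
    n_replicates: int = 3,
    background_rate: float = 0.35,
    detect_prob: float = 0.9,
    enrichment_log2: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """IP-MS identification and quantification tables.

    Core preys appear (with high per-replicate detection probability) in all
    four pathway baits and never in a negative control; partial preys in
    three of the four; background proteins appear at random in any bait
    including controls.  Sub-threshold identification records (low protein
    probability or a single passing peptide) are sprinkled in to exercise
    the thresholding rules.  Quantities are log-normal with the preys
    enriched in their baits.
    """
    core = ["MMUT", "OGDH", "DLST", "GOT2"] + [f"PREY{i:03d}" for i in range(1, n_core_prey - 3)]
    partial = ["MMAB", "GLUD1"] + [f"PART{i:03d}" for i in range(1, n_partial_prey - 1)]
    background = [f"BG{i:03d}" for i in range(1, n_background + 1)]
    partial_baits = ["MMUT", "MMAB", "MCEE"]

    id_rows, present = [], {}
    for protein in core + partial + background:
        if protein in core:
            bait_map = {b: detect_prob for b in EXPERIMENTAL_BAITS}
        elif protein in partial:
            bait_map = {b: detect_prob for b in partial_baits}
        else:
            bait_map = {b: background_rate for b in EXPERIMENTAL_BAITS + CONTROL_BAITS}
        for bait in EXPERIMENTAL_BAITS + CONTROL_BAITS:
            prob = bait_map.get(bait, 0.0)
            for rep in range(1, n_replicates + 1):
                detected = rng.random() < prob
                present[(protein, bait, rep)] = detected
                if detected:
                    n_pep = 2 + int(rng.poisson(3))
                    peps = rng.uniform(0.955, 1.0, size=n_pep)
                    id_rows.append(
                        {
                            "protein": protein,
                            "bait": bait,
                            "replicate": rep,
                            "protein_probability": float(rng.uniform(0.992, 1.0)),
                            "peptide_probabilities": ";".join(f"{p:.4f}" for p in peps),
                        }
                    )
                elif rng.random() < 0.08:  # sub-threshold identification
                    weak = rng.random() < 0.5
                    id_rows.append(
                        {
                            "protein": protein,
                            "bait": bait,
                            "replicate": rep,
                            "protein_probability": float(rng.uniform(0.5, 0.99))
                            if weak
                            else float(rng.uniform(0.992, 1.0)),
                            "peptide_probabilities": f"{rng.uniform(0.955, 1.0):.4f}"
                            if not weak
                            else ";".join(
                                f"{p:.4f}" for p in rng.uniform(0.955, 1.0, size=3)
                            ),
                        }
                    )

    samples = [f"{b}_r{r}" for b in EXPERIMENTAL_BAITS + CONTROL_BAITS
               for r in range(1, n_replicates + 1)]
    quant = {}
    for protein in core + partial + background:
        base = rng.normal(20.0, 1.5)
        row = {}
        if protein in core:
            enriched_in = set(EXPERIMENTAL_BAITS)
        elif protein in partial:
            enriched_in = set(partial_baits)
        else:
            enriched_in = set()
        for bait in EXPERIMENTAL_BAITS + CONTROL_BAITS:
            for rep in range(1, n_replicates + 1):
                shift = enrichment_log2 if bait in enriched_in else 0.0
                row[f"{bait}_r{rep}"] = 2.0 ** (base + shift + 0.3 * rng.standard_normal())
        quant[protein] = row
    quant_df = pd.DataFrame.from_dict(quant, orient="index")[samples]
    quant_df.index.name = "protein"
    truth = {
        "core_prey": core,
        "partial_prey": partial,
        "partial_baits": partial_baits,
        "background": background,
        "enrichment_log2": enrichment_log2,
    }
    return pd.DataFrame(id_rows), quant_df, truth


# ---------------------------------------------------------------------------
# full bundle


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the complete synthetic cohort bundle from one seed.

    Deterministic for a fixed config: the seed is split into named substreams
    (severity, phenotypes, omics, variants, tracing, ipms) so each layer can
    be regenerated independently.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = dict(
        zip(
            ["severity", "phenotypes", "omics", "variants", "tracing", "ipms"],
            [np.random.default_rng(s) for s in ss.spawn(6)],
        )
    )
    n_affected = config.n_case + config.n_other
    ids = [f"MMA{i:03d}" for i in range(1, n_affected + 1)] + [
        f"CTRL{i:03d}" for i in range(1, config.n_control + 1)
    ]
    labels = (
        [GROUP_DEFICIENT] * config.n_case
        + [GROUP_OTHER] * config.n_other
        + [GROUP_UNAFFECTED] * config.n_control
    )
    group_labels = pd.Series(labels, index=ids, name="group")

    shift = group_labels.map(
        {
            GROUP_DEFICIENT: config.case_severity_shift,
            GROUP_OTHER: config.other_severity_shift,
            GROUP_UNAFFECTED: 0.0,
        }
    ).to_numpy()
    severity = pd.Series(
        shift + config.severity_sd * streams["severity"].standard_normal(len(ids)),
        index=ids,
        name="severity",
    )

    phenotypes, meta = simulate_phenotypes(severity, config.phenotype_specs, streams["phenotypes"])
    rna, protein = simulate_paired_omics(
        group_labels,
        config.effect_table,
        config.rna_protein_coupling,
        config.n_genes,
        streams["omics"],
        gene_sd=config.gene_sd,
        shared_mean_sd=config.shared_mean_sd,
        protein_offset_sd=config.protein_offset_sd,
        base_log2_abundance=config.base_log2_abundance,
    )
    variants, variant_truth = simulate_variants(group_labels, streams["variants"])
    peaks, standards, tracing_truth = simulate_tracing(streams["tracing"])
    ipms_ids, ipms_quant, ipms_truth = simulate_ipms(streams["ipms"])

    truth = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "phenotype_specs"},
            "phenotype_specs": [asdict(s) for s in config.phenotype_specs],
        },
        "latent_severity": {i: float(v) for i, v in severity.items()},
        "variants": variant_truth,
        "tracing": tracing_truth,
        "ipms": ipms_truth,
    }
    return CohortBundle(
        phenotypes=phenotypes,
        phenotype_meta=meta,
        rna=rna,
        protein=protein,
        variants=variants,
        tracing_peaks=peaks,
        tracing_standards=standards,
        ipms_ids=ipms_ids,
        ipms_quant=ipms_quant,
        group_labels=group_labels,
        truth=truth,
    )
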