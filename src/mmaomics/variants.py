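"""Rule-based triage of annotated variant tables for a recessive-disease cohort.

A variant observation passes the hard filters when it is rare (maximum
population allele frequency < 0.01) and well supported by reads (>= 2 forward
and >= 2 reverse reads, >= 8 coverage; copy-number calls bypass read support),
and it triggers at least one prioritization rule: a non-synonymous coding
consequence, a pathogenic/likely-pathogenic ClinVar or InterVar class, or a
splice-impact ensemble score (dbscSNV ADA/RF) above 0.6.

Diagnoses are biallelic: one passing homozygous allele, or two distinct
passing heterozygous alleles in the same gene (phase unknown; trans assumed).
A mutational-burden ranking lists genes biallelic in two or more individuals,
and a robust-z expression-outlier screen stands in for aberrant-expression
detection on the RNA layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_COLUMNS",
    "CODING_NONSYNONYMOUS",
    "DiagnosisCall",
    "filter_variants",
    "biallelic_calls",
    "allele_type_counts",
    "mutational_burden",
    "expression_outlier",
]

VARIANT_COLUMNS = [
    "individual_id",
    "variant_id",
    "gene",
    "consequence",
    "zygosity",
    "population_max_af",
    "fwd_reads",
    "rev_reads",
    "coverage",
    "clinvar_class",
    "intervar_class",
    "dbscsnv_ada",
    "dbscsnv_rf",
]

CONSEQUENCES = {"missense", "truncating", "splicing", "inframe_deletion", "cnv",
                "synonymous", "other"}
CODING_NONSYNONYMOUS = {"missense", "truncating", "inframe_deletion", "cnv"}
PATHOGENIC_CLASSES = {"P", "LP"}


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    df = records.copy()
    for i, row in df.iterrows():
        if row["consequence"] not in CONSEQUENCES:
            raise ValueError(f"row {i}: unknown consequence {row['consequence']!r}")
        if row["zygosity"] not in {"het", "hom"}:
            raise ValueError(f"row {i}: unknown zygosity {row['zygosity']!r}")
        if not 0 <= row["population_max_af"] <= 1:
            raise ValueError(f"row {i}: allele frequency outside [0, 1]")
    return df


def filter_variants(
    records: pd.DataFrame,
    max_af: float = 0.01,
    min_fwd: int = 2,
    min_rev: int = 2,
    min_coverage: int = 8,
    splice_score: float = 0.6,
) -> pd.DataFrame:
    """Apply the hard filters and prioritization rules with a per-rule audit trail.

    Returns the input with boolean columns ``rule_frequency``, ``rule_reads``,
    ``rule_coding``, ``rule_clinical``, ``rule_splice`` and ``passed``.
    A record passes iff frequency AND reads AND (coding OR clinical OR splice).
    CNV calls bypass the read-support rule (called from depth profiles, not
    individual reads) but not the frequency rule.
    """
    df = _validate(records)
    af = df["population_max_af"].astype(float)
    ada = pd.to_numeric(df["dbscsnv_ada"], errors="coerce")
    rf = pd.to_numeric(df["dbscsnv_rf"], errors="coerce")

    df["rule_frequency"] = af < max_af
    is_cnv = df["consequence"] == "cnv"
    df["rule_reads"] = (
        (df["fwd_reads"] >= min_fwd)
        & (df["rev_reads"] >= min_rev)
        & (df["coverage"] >= min_coverage)
    ) | is_cnv
    df["rule_coding"] = df["consequence"].isin(CODING_NONSYNONYMOUS)
    df["rule_clinical"] = df["clinvar_class"].isin(PATHOGENIC_CLASSES) | df[
        "intervar_class"
    ].isin(PATHOGENIC_CLASSES)
    df["rule_splice"] = (ada > splice_score).fillna(False) | (rf > splice_score).fillna(False)
    df["passed"] = (
        df["rule_frequency"]
        & df["rule_reads"]
        & (df["rule_coding"] | df["rule_clinical"] | df["rule_splice"])
    )
    return df


@dataclass
class DiagnosisCall:
    individual_id: str
    gene: str
    allele_ids: tuple[str, ...]
    call_type: str  # homozygous | compound_het


def biallelic_calls(filtered: pd.DataFrame) -> list[DiagnosisCall]:
    """Biallelic diagnosis calls from passing records.

    One call per (individual, gene): a passing homozygous allele, or at least
    two distinct passing heterozygous alleles in the same gene (compound
    heterozygosity, trans assumed).  Homozygous calls take precedence.
    """
    if "passed" not in filtered.columns:
        raise ValueError("run filter_variants first")
    calls = []
    passing = filtered.loc[filtered["passed"]]
    for (ind, gene), grp in passing.groupby(["individual_id", "gene"], sort=True):
        homs = grp.loc[grp["zygosity"] == "hom", "variant_id"].unique()
        hets = grp.loc[grp["zygosity"] == "het", "variant_id"].unique()
        if len(homs):
            calls.append(DiagnosisCall(str(ind), str(gene), (str(homs[0]),), "homozygous"))
        elif len(hets) >= 2:
            calls.append(
                DiagnosisCall(str(ind), str(gene), tuple(str(v) for v in hets), "compound_het")
            )
    return calls


def allele_type_counts(
    calls: list[DiagnosisCall], filtered: pd.DataFrame
) -> dict[str, int]:
    """Census of pathogenic alleles by consequence class over resolved calls.

    Homozygous calls contribute 2 alleles of their consequence; every allele
    of a compound-het call contributes 1.
    """
    lookup = filtered.drop_duplicates("variant_id").set_index("variant_id")["consequence"]
    counts: dict[str, int] = {}
    for call in calls:
        mult = 2 if call.call_type == "homozygous" else 1
        for vid in call.allele_ids:
            cons = str(lookup.loc[vid])
            counts[cons] = counts.get(cons, 0) + mult
    return counts


def mutational_burden(calls: list[DiagnosisCall], min_individuals: int = 2) -> pd.DataFrame:
    """Genes with biallelic calls in >= ``min_individuals`` distinct individuals,
    ranked by how many individuals carry them."""
    per_gene: dict[str, set[str]] = {}
    for call in calls:
        per_gene.setdefault(call.gene, set()).add(call.individual_id)
    rows = [
        (gene, len(inds))
        for gene, inds in per_gene.items()
        if len(inds) >= min_individuals
    ]
    out = pd.DataFrame(rows, columns=["gene", "n_individuals"])
    return out.sort_values(
        ["n_individuals", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def expression_outlier(
    expr: pd.DataFrame, z_threshold: float = -3.0
) -> pd.DataFrame:
    """Robust-z under-expression outliers, a simple stand-in for model-based
    aberrant-expression detection.

    Per gene (row), z = (value - median) / (1.4826 * MAD) across samples;
    entries with z below ``z_threshold`` are flagged.  Genes with zero MAD are
    skipped with a warning.  Requires >= 20 samples.
    """
    if expr.shape[1] < 20:
        raise ValueError("need at least 20 samples for outlier detection")
    X = expr.to_numpy(dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    if zero_mad.any():
        warnings.warn(
            f"{int(zero_mad.sum())} gene(s) with zero MAD skipped", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (X - med) / (1.4826 * mad)
    rows = []
    for gi, gene in enumerate(expr.index):
        if zero_mad[gi]:
            continue
        for sj, sample in enumerate(expr.columns):
            if z[gi, sj] < z_threshold:
                rows.append((sample, gene, float(z[gi, sj])))
    return pd.DataFrame(rows, columns=["sample", "gene", "z"])
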