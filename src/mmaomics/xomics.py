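"""Cross-omics correlation analyses.

Transcript-protein and protein-protein Spearman correlations, split by
genotype group (MMUT-deficient versus control), with the signed diagonal
distance d = (rho_deficient - rho_control)/sqrt(2) that measures how far a
gene sits from the equal-correlation diagonal, and a Fisher-z test for
between-group correlation differences.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_with_p",
    "paired_spearman",
    "cross_level_summary",
    "diagonal_distance",
    "correlation_difference_test",
    "protein_pair_correlation",
    "paired_correlation_table",
]

log = logging.getLogger(__name__)

#: at or below this sample size (and absent ties) Spearman p is computed by
#: full permutation enumeration rather than the t approximation
EXACT_PERMUTATION_N = 9


@lru_cache(maxsize=8)
def _exact_rho_distribution(n: int) -> np.ndarray:
    """Null distribution of Spearman rho over all n! rank permutations."""
    base = np.arange(1, n + 1, dtype=float)
    vals = []
    denom = n * (n * n - 1)
    for perm in permutations(base):
        d2 = np.sum((base - np.asarray(perm)) ** 2)
        vals.append(1.0 - 6.0 * d2 / denom)
    return np.asarray(vals)


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation p for n <= 9 without ties; otherwise the usual
    t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    rho = float(stats.spearmanr(x, y).statistic)
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= EXACT_PERMUTATION_N and no_ties:
        dist = _exact_rho_distribution(n)
        p = float(np.mean(np.abs(dist) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def paired_spearman(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    groups: pd.Series,
    min_group_n: int = 4,
) -> pd.DataFrame:
    """Per-gene, per-group Spearman correlation of transcript vs protein.

    ``rna`` and ``protein`` are genes x samples matrices; ``groups`` maps
    sample identifier to group label.  Genes absent from either layer are
    skipped (logged).
    """
    shared_genes = rna.index.intersection(protein.index)
    skipped = rna.index.symmetric_difference(protein.index)
    if len(skipped):
        log.info("paired_spearman: %d genes absent from one layer", len(skipped))
    shared_samples = rna.columns.intersection(protein.columns).intersection(groups.index)
    rows = []
    for grp, members in groups.loc[shared_samples].groupby(groups.loc[shared_samples]):
        cols = members.index
        if len(cols) < min_group_n:
            raise ValueError(f"group {grp!r} has fewer than {min_group_n} samples")
        R = rna.loc[shared_genes, cols].to_numpy(dtype=float)
        P = protein.loc[shared_genes, cols].to_numpy(dtype=float)
        for gi, gene in enumerate(shared_genes):
            rho, p = spearman_with_p(R[gi], P[gi])
            rows.append((gene, grp, rho, p, len(cols)))
    return pd.DataFrame(rows, columns=["gene", "group", "rho", "p", "n"])


def cross_level_summary(rna: pd.DataFrame, protein: pd.DataFrame) -> dict:
    """Gene-level and sample-level transcript-protein Spearman correlations.

    Gene-level: per-gene rho across all shared samples.  Sample-level:
    per-sample rho across all shared genes.  Medians summarize both.
    """
    genes = rna.index.intersection(protein.index)
    samples = rna.columns.intersection(protein.columns)
    if len(genes) < 10:
        raise ValueError("fewer than 10 shared genes between layers")
    R = rna.loc[genes, samples].to_numpy(dtype=float)
    P = protein.loc[genes, samples].to_numpy(dtype=float)
    gene_rho = pd.Series(
        [stats.spearmanr(R[i], P[i]).statistic for i in range(len(genes))],
        index=genes,
        name="rho",
    )
    sample_rho = pd.Series(
        [stats.spearmanr(R[:, j], P[:, j]).statistic for j in range(len(samples))],
        index=samples,
        name="rho",
    )
    return {
        "gene_level": gene_rho,
        "sample_level": sample_rho,
        "median_gene_level": float(gene_rho.median()),
        "median_sample_level": float(sample_rho.median()),
        "n_pairs": int(len(genes)),
        "n_samples": int(len(samples)),
    }


def diagonal_distance(rho_def, rho_ctrl):
    """Signed distance from the equal-correlation diagonal:
    (deficient correlation - control correlation) / sqrt(2).
    """
    a = np.asarray(rho_def, dtype=float)
    b = np.asarray(rho_ctrl, dtype=float)
    if np.any(np.abs(a) > 1) or np.any(np.abs(b) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    d = (a - b) / np.sqrt(2.0)
    return float(d) if d.ndim == 0 else d


def correlation_difference_test(rho1: float, n1: int, rho2: float, n2: int) -> float:
    """Two-sided Fisher-z test for a difference between two correlations."""
    if n1 < 4 or n2 < 4:
        raise ValueError("need at least 4 samples per group")
    if abs(rho1) >= 1 or abs(rho2) >= 1:
        raise ValueError("|rho| = 1 gives an infinite Fisher z")
    z1, z2 = np.arctanh(rho1), np.arctanh(rho2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def protein_pair_correlation(
    protein: pd.DataFrame,
    anchor: str,
    partners: list[str],
    groups: pd.Series,
    min_group_n: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of the anchor protein against each partner per group."""
    if anchor not in protein.index:
        raise ValueError(f"anchor protein {anchor!r} absent from matrix")
    samples = protein.columns.intersection(groups.index)
    rows = []
    for grp, members in groups.loc[samples].groupby(groups.loc[samples]):
        cols = members.index
        if len(cols) < min_group_n:
            raise ValueError(f"group {grp!r} has fewer than {min_group_n} samples")
        a = protein.loc[anchor, cols].to_numpy(dtype=float)
        for partner in partners:
            if partner not in protein.index:
                log.info("protein_pair_correlation: partner %s missing; skipped", partner)
                continue
            rho, p = spearman_with_p(a, protein.loc[partner, cols].to_numpy(dtype=float))
            rows.append((anchor, partner, grp, rho, p, len(cols)))
    return pd.DataFrame(rows, columns=["anchor", "partner", "group", "rho", "p", "n"])


def paired_correlation_table(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    groups: pd.Series,
    deficient_label: str = "MMUT-deficient",
) -> pd.DataFrame:
    """Per-gene deficient/control correlations with diagonal distance and
    difference p-values.

    Samples not labeled ``deficient_label`` form the control group, mirroring
    the deficient-versus-everyone-else contrast.  Genes are retained only when
    present in both layers with at least 4 samples per group.
    """
    two_group = groups.map(lambda g: deficient_label if g == deficient_label else "control")
    per = paired_spearman(rna, protein, two_group)
    piv_rho = per.pivot(index="gene", columns="group", values="rho")
    piv_p = per.pivot(index="gene", columns="group", values="p")
    piv_n = per.pivot(index="gene", columns="group", values="n")
    out = pd.DataFrame(
        {
            "gene": piv_rho.index,
            "rho_def": piv_rho[deficient_label].to_numpy(),
            "rho_ctrl": piv_rho["control"].to_numpy(),
            "p_def": piv_p[deficient_label].to_numpy(),
            "p_ctrl": piv_p["control"].to_numpy(),
            "n_def": piv_n[deficient_label].to_numpy(dtype=int),
            "n_ctrl": piv_n["control"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    out["d"] = diagonal_distance(out["rho_def"].to_numpy(), out["rho_ctrl"].to_numpy())
    out["p_diff"] = [
        correlation_difference_test(r1, n1, r2, n2)
        if abs(r1) < 1 and abs(r2) < 1
        else np.nan
        for r1, n1, r2, n2 in zip(out["rho_def"], out["n_def"], out["rho_ctrl"], out["n_ctrl"])
    ]
    return out
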