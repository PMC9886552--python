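"""Affinity-purification MS downstream logic.

Identification thresholding (protein probability > 0.99 with at least two
peptides above 0.95), bait-prey presence matrices, specificity/Venn set
logic ("pulled down by the pathway baits but never by a negative control"),
per-protein one-way ANOVA enrichment across bait groups, and the weighted
bait-prey interaction network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PresenceMatrix",
    "apply_id_thresholds",
    "specific_prey",
    "venn_partition",
    "anova_enrichment",
    "build_network",
]

log = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Protein x (bait, replicate) detection booleans with bait roles."""

    detected: pd.DataFrame  # index: protein; columns: MultiIndex (bait, replicate)
    bait_roles: dict[str, str] = field(default_factory=dict)  # bait -> experimental|negative_control

    def __post_init__(self):
        baits = self.detected.columns.get_level_values(0).unique()
        missing = [b for b in baits if b not in self.bait_roles]
        if missing:
            raise ValueError(f"baits without a role: {missing}")

    @property
    def baits(self) -> list[str]:
        return list(self.detected.columns.get_level_values(0).unique())

    def detected_in_bait(self, bait: str, min_replicates: int = 1) -> set[str]:
        """Proteins detected in at least ``min_replicates`` replicates of a bait."""
        if bait not in self.baits:
            raise ValueError(f"unknown bait {bait!r}")
        sub = self.detected.loc[:, bait]
        return set(sub.index[sub.sum(axis=1) >= min_replicates])


def apply_id_thresholds(
    records: pd.DataFrame,
    protein_prob: float = 0.99,
    min_peptides: int = 2,
    peptide_prob: float = 0.95,
    bait_roles: dict[str, str] | None = None,
) -> PresenceMatrix:
    """Convert identification records into a presence matrix.

    A protein counts as detected in (bait, replicate) iff its protein
    probability strictly exceeds ``protein_prob`` and at least
    ``min_peptides`` of its peptides have probability strictly above
    ``peptide_prob``.  ``records`` columns: protein, bait, replicate,
    protein_probability, peptide_probabilities (list or ';'-joined string).
    """
    def _peptides(v) -> list[float]:
        if isinstance(v, str):
            return [float(t) for t in v.split(";") if t]
        return [float(t) for t in v]

    passing = []
    for _, row in records.iterrows():
        peps = _peptides(row["peptide_probabilities"])
        ok = (
            float(row["protein_probability"]) > protein_prob
            and sum(p > peptide_prob for p in peps) >= min_peptides
        )
        passing.append(ok)
    rec = records.assign(_pass=passing)
    grid = rec.pivot_table(
        index="protein", columns=["bait", "replicate"], values="_pass",
        aggfunc="any", fill_value=False,
    ).astype(bool)
    roles = bait_roles or {b: "experimental" for b in grid.columns.get_level_values(0).unique()}
    return PresenceMatrix(detected=grid, bait_roles=roles)


def specific_prey(
    matrix: PresenceMatrix,
    required_baits: set[str],
    min_required: int,
    forbidden_baits: set[str],
    min_replicates: int = 1,
) -> set[str]:
    """Preys detected in >= ``min_replicates`` replicate(s) of at least
    ``min_required`` required baits and in zero replicates of every
    forbidden bait."""
    required_baits, forbidden_baits = set(required_baits), set(forbidden_baits)
    if required_baits & forbidden_baits:
        raise ValueError("required and forbidden bait sets overlap")
    for b in required_baits | forbidden_baits:
        if b not in matrix.baits:
            raise ValueError(f"unknown bait {b!r}")
    in_required = {b: matrix.detected_in_bait(b, min_replicates) for b in required_baits}
    in_forbidden = set()
    for b in forbidden_baits:
        in_forbidden |= matrix.detected_in_bait(b, min_replicates=1)
    out = set()
    for protein in matrix.detected.index:
        if protein in in_forbidden:
            continue
        if sum(protein in in_required[b] for b in required_baits) >= min_required:
            out.add(protein)
    return out


def venn_partition(
    matrix: PresenceMatrix, baits: list[str] | None = None
) -> dict[frozenset, set[str]]:
    """Assign every detected protein to its exact bait-membership region.

    Membership means detection in >= 1 replicate of that bait; the regions
    (non-empty subsets of the bait list) partition the detected proteins.
    """
    baits = list(baits) if baits is not None else matrix.baits
    if len(baits) > 6:
        raise ValueError("Venn partition limited to 6 baits")
    membership = {b: matrix.detected_in_bait(b) for b in baits}
    regions: dict[frozenset, set[str]] = {}
    for k in range(1, len(baits) + 1):
        for combo in combinations(baits, k):
            regions[frozenset(combo)] = set()
    for protein in matrix.detected.index:
        members = frozenset(b for b in baits if protein in membership[b])
        if members:
            regions[members].add(protein)
    return regions


def anova_enrichment(
    quant: pd.DataFrame, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per protein across bait groups.

    ``quant`` is protein x sample abundances; ``groups`` maps group name to
    its sample columns (each group needs >= 2 replicates).  Degenerate
    proteins with zero variance everywhere and equal means get F = 0, p = 1.
    """
    for g, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        missing = [c for c in cols if c not in quant.columns]
        if missing:
            raise ValueError(f"group {g!r}: unknown sample columns {missing}")
    rows = []
    for protein, row in quant.iterrows():
        arrays = [row[cols].to_numpy(dtype=float) for cols in groups.values()]
        flat = np.concatenate(arrays)
        if np.all(flat == flat[0]):
            log.info("anova_enrichment: %s constant across all groups; p = 1", protein)
            F, p = 0.0, 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.f_oneway(*arrays)
            F, p = float(res.statistic), float(res.pvalue)
            if not np.isfinite(p):  # zero within-group variance, unequal means
                F, p = np.inf, 0.0
        means = {f"mean_{g}": float(np.mean(a)) for g, a in zip(groups, arrays)}
        rows.append({"protein": protein, "F": F, "p_anova": p, **means})
    return pd.DataFrame(rows)


def build_network(
    preys: set[str],
    enrichment: pd.DataFrame,
    matrix: PresenceMatrix,
    alpha: float = 0.05,
    min_replicates: int = 1,
) -> nx.Graph:
    """Weighted bait-prey network of significantly enriched preys.

    One edge per (experimental bait, significant prey) pair where the prey is
    detected in the bait; edge weight is -log10 of the ANOVA p-value (thicker
    = more significant).  Node classes: ``bait``, ``exclusive_prey`` (member
    of ``preys``, the control-free specific set) or ``shared_prey``.
    """
    sig = enrichment.loc[enrichment["p_anova"] < alpha].set_index("protein")["p_anova"]
    experimental = [b for b, role in matrix.bait_roles.items() if role == "experimental"]
    G = nx.Graph()
    for b in experimental:
        G.add_node(b, kind="bait")
    for prey, p in sig.items():
        kind = "exclusive_prey" if prey in preys else "shared_prey"
        for b in experimental:
            if prey in matrix.detected_in_bait(b, min_replicates):
                if prey not in G:
                    G.add_node(prey, kind=kind, p_anova=float(p))
                G.add_edge(b, prey, weight=float(-np.log10(max(p, 1e-300))))
    return G
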