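"""Phenomics: clinical severity score, mixed-type correlation matrix, and the
phenome-wide linear-model screen for surrogate severity markers.

The clinical severity score (CSS) sums five binary clinical indicators of
methylmalonic aciduria (early disease onset, neurological abnormalities,
kidney impairment, hematological abnormalities, failure to thrive) into a
0-5 scale.  The screen regresses every phenotype variable on a chosen target
(e.g. CSS or PI+ activity) after log transformation of strictly positive
continuous variables and z-standardization of both sides, then applies
Benjamini-Hochberg adjustment across the screened set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CSS_COMPONENTS",
    "CssResult",
    "compute_css",
    "css_scores",
    "correlation_matrix",
    "association_screen",
    "bh_adjust",
    "count_significant",
]

log = logging.getLogger(__name__)

CSS_COMPONENTS = (
    "early_onset",
    "neurological_abnormalities",
    "kidney_impairment",
    "hematological_abnormalities",
    "failure_to_thrive",
)

#: onset at or below this many days counts as "early onset" when binarizing age
EARLY_ONSET_DAYS = 28


@dataclass
class CssResult:
    score: int
    n_missing: int

    @property
    def complete(self) -> bool:
        return self.n_missing == 0


def compute_css(components: dict[str, float | None] | pd.Series) -> CssResult:
    """Sum the five binary severity flags; missing flags contribute 0.

    Raises ValueError when every component is missing.
    """
    if isinstance(components, pd.Series):
        components = components.to_dict()
    unknown = set(components) - set(CSS_COMPONENTS)
    if unknown:
        raise ValueError(f"unknown CSS components: {sorted(unknown)}")
    score = 0
    n_missing = 0
    for name in CSS_COMPONENTS:
        v = components.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            n_missing += 1
            continue
        if v not in (0, 1, 0.0, 1.0):
            raise ValueError(f"CSS component {name} must be 0/1/missing, got {v!r}")
        score += int(v)
    if n_missing == len(CSS_COMPONENTS):
        raise ValueError("all CSS components missing; score undefined")
    return CssResult(score=score, n_missing=n_missing)


def css_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-individual CSS over a phenotype table containing the five flag columns."""
    missing_cols = [c for c in CSS_COMPONENTS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks CSS components: {missing_cols}")
    rows = []
    for ind, row in table[list(CSS_COMPONENTS)].iterrows():
        res = compute_css(row)
        rows.append((ind, res.score, res.n_missing))
    return pd.DataFrame(rows, columns=["individual_id", "css", "n_missing"]).set_index(
        "individual_id"
    )


def correlation_matrix(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Spearman correlation matrix on pairwise-complete observations.

    A single rank-based estimator is used for every variable-type pair
    (continuous-continuous, continuous-binary, binary-binary; the latter equals
    a rank phi coefficient).  Cells with fewer than ``min_pairs`` complete
    pairs, or involving a constant variable, are left missing.
    """
    df = table.apply(pd.to_numeric, errors="coerce")
    constant = [c for c in df.columns if df[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant variables yield missing correlations: {constant}", stacklevel=2)
    corr = df.corr(method="spearman", min_periods=min_pairs)
    for c in df.columns:
        if c not in constant:
            corr.loc[c, c] = 1.0
    return corr


@dataclass
class AssociationResult:
    variable: str
    effect_size: float
    p: float
    p_adj: float
    n_used: int


def _log_if_positive(x: np.ndarray, name: str) -> np.ndarray:
    """Natural log when strictly positive, else log1p with a warning."""
    if np.nanmin(x) > 0:
        return np.log(x)
    warnings.warn(f"variable {name} not strictly positive; using log(x+1)", stacklevel=3)
    return np.log1p(np.clip(x, 0, None))


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def association_screen(
    table: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
    variable_types: dict[str, str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Regress every other phenotype variable on ``target``.

    For each variable: strictly positive continuous variables are natural-log
    transformed, both sides z-standardized on their pairwise-complete subset,
    and an ordinary least-squares slope with two-sided p-value computed.
    Benjamini-Hochberg adjustment runs across the screened set; results come
    back sorted by adjusted p.  Variables with fewer than 3 complete pairs
    against the target are skipped (logged).
    """
    if target not in table.columns:
        raise ValueError(f"target {target!r} not in phenotype table")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = table.apply(pd.to_numeric, errors="coerce")
    tgt_all = df[target]
    if tgt_all.dropna().nunique() <= 1:
        raise ValueError("target variable is constant")
    types = variable_types or {}

    def _is_binary(name: str, values: pd.Series) -> bool:
        if name in types:
            return types[name] == "binary"
        return set(values.dropna().unique()) <= {0, 1}

    records = []
    for var in df.columns:
        if var == target:
            continue
        pair = df[[target, var]].dropna()
        if len(pair) < 3 or pair[var].nunique() <= 1:
            log.info("screen: skipping %s (insufficient complete pairs or constant)", var)
            continue
        t = pair[target].to_numpy(dtype=float)
        v = pair[var].to_numpy(dtype=float)
        if log_transform and not _is_binary(target, pair[target]):
            t = _log_if_positive(t, target)
        if log_transform and not _is_binary(var, pair[var]):
            v = _log_if_positive(v, var)
        t, v = _zscore(t), _zscore(v)
        res = stats.linregress(t, v)
        records.append((var, float(res.slope), float(res.pvalue), len(pair)))

    out = pd.DataFrame(records, columns=["variable", "effect_size", "p", "n_used"])
    if out.empty:
        out["p_adj"] = []
        return out
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values("p_adj", kind="mergesort").reset_index(drop=True)
    return out[["variable", "effect_size", "p", "p_adj", "n_used"]]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def count_significant(results: pd.DataFrame, alpha: float = 0.05) -> int:
    """Number of screened variables with adjusted p below alpha."""
    if results.empty:
        return 0
    return int((results["p_adj"] < alpha).sum())
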