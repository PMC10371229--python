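"""Protein-trait linear modelling with q-value multiple-testing adjustment.

Each protein is regressed against (log2) Matsuda Index with optional
covariates:

    trait = alpha + beta_protein * protein + covariates + error

fitted by ordinary least squares on complete cases, with a two-sided Wald
t-test on ``beta_protein``.  The sign convention matters downstream: a
negative effect size means more protein, lower insulin sensitivity, which is
the direction the fingerprint selects for.

Multiple testing uses Storey q-values: pi0 (the null proportion) is estimated
on a lambda grid with a cubic smoother and q_i = pi0 * min_{p_j >= p_i}
(m * p_j / rank_j).  With pi0 fixed at 1 this reduces exactly to
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationModelSpec",
    "AssociationResult",
    "fit_protein_trait_model",
    "run_association_scan",
    "qvalues",
    "consensus_overlap",
]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass(frozen=True)
class AssociationModelSpec:
    """How the protein-trait model is fitted.

    trait_transform: "log2" (default; insulin-sensitivity indices are
    right-skewed) or "identity".  covariates: phenotype-table column names
    entered additively (e.g. adiposity).
    """

    trait_transform: str = "log2"
    covariates: tuple[str, ...] = ()
    q_threshold: float = 0.05

    def transform(self, trait: pd.Series) -> pd.Series:
        if self.trait_transform == "log2":
            return np.log2(trait)
        if self.trait_transform == "identity":
            return trait
        raise ValueError(f"unknown trait_transform {self.trait_transform!r}")


@dataclass(frozen=True)
class AssociationResult:
    protein_id: str
    effect_size: float
    p_value: float
    q_value: float = np.nan
    n_used: int = 0
    flagged: bool = False


def fit_protein_trait_model(
    protein: pd.Series,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    spec: AssociationModelSpec | None = None,
) -> AssociationResult:
    """OLS fit of trait on one protein (plus covariates), complete cases only.

    Rank-deficient designs (e.g. a constant protein) yield a flagged result
    with undefined p, which the scan excludes from q-value input.
    """
    spec = spec or AssociationModelSpec()
    y = spec.transform(trait)
    df = pd.DataFrame({"trait": y, "protein": protein})
    if covariates is not None and len(spec.covariates):
        for c in spec.covariates:
            if c not in covariates.columns:
                raise KeyError(f"covariate {c!r} not found in phenotype table")
            df[c] = covariates[c]
    df = df.dropna()
    k = 1 + (len(spec.covariates) if covariates is not None else 0)
    n_min = k + 2 + 1
    name = str(protein.name)
    if len(df) < n_min:
        return AssociationResult(name, np.nan, np.nan, n_used=len(df), flagged=True)
    X = sm.add_constant(df.drop(columns="trait"), has_constant="add")
    if np.isclose(df["protein"].std(ddof=1), 0.0):
        return AssociationResult(name, np.nan, np.nan, n_used=len(df), flagged=True)
    fit = sm.OLS(df["trait"], X).fit()
    return AssociationResult(
        protein_id=name,
        effect_size=float(fit.params["protein"]),
        p_value=float(fit.pvalues["protein"]),
        n_used=int(fit.nobs),
    )


def qvalues(
    p: np.ndarray | list[float],
    pi0: float | None = None,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> np.ndarray:
    """Storey q-values for a vector of p-values.

    pi0 is estimated by the cubic-smoother-on-lambda-grid method (a degree-3
    polynomial fit to pi0(lambda) evaluated at the largest lambda), clipped to
    (0, 1].  Pass ``pi0=1.0`` to reduce to Benjamini-Hochberg exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    m = len(p)
    if m == 0:
        return p.copy()
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    if not (0 < pi0 <= 1):
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    order = np.argsort(p, kind="mergesort")  # stable: ties keep input order
    # p / (rank/m) rather than p*m/rank: matches the reference BH operation
    # order bit-for-bit when pi0 == 1
    ecdf = np.arange(1, m + 1) / m
    raw = pi0 * (p[order] / ecdf)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def estimate_pi0(p: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Null-proportion estimate via the lambda-grid cubic smoother."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < 20:
        # too few tests to estimate the tail; be conservative
        return 1.0
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambda_grid])
    coeffs = np.polynomial.polynomial.polyfit(lambda_grid, pi0_l, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(lambda_grid.max(), coeffs))
    return float(min(1.0, max(pi0, 1.0 / m)))


def run_association_scan(
    pm,
    phenotypes: pd.DataFrame,
    spec: AssociationModelSpec | None = None,
    trait_column: str = "matsuda",
) -> pd.DataFrame:
    """Fit the protein-trait model for every protein of one fraction.

    ``pm`` is a :class:`~musclemap.phenotypes.ProteinMatrix`; ``phenotypes``
    a per-mouse table holding ``trait_column`` and any covariates.  Mouse ids
    must match exactly.  Returns a DataFrame ordered by protein_id with
    columns effect_size, p_value, q_value, n_used, flagged; q-values are
    computed over the non-flagged proteins of this call only (i.e. within
    fraction, unless the caller pools fractions first).
    """
    spec = spec or AssociationModelSpec()
    pm_ids = list(pm.values.index)
    ph_ids = set(phenotypes.index)
    for mid in pm_ids:
        if mid not in ph_ids:
            raise ValueError(f"mouse id mismatch: {mid!r} present in proteome but not phenotypes")
    pheno = phenotypes.loc[pm_ids]
    trait = pheno[trait_column]
    rows = []
    for pid in sorted(pm.values.columns):
        res = fit_protein_trait_model(pm.values[pid], trait, pheno, spec)
        rows.append(res)
    out = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in rows],
            "effect_size": [r.effect_size for r in rows],
            "p_value": [r.p_value for r in rows],
            "n_used": [r.n_used for r in rows],
            "flagged": [r.flagged for r in rows],
        }
    ).set_index("protein_id")
    ok = ~out["flagged"]
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = qvalues(out.loc[ok, "p_value"].to_numpy())
    n_flagged = int(out["flagged"].sum())
    if n_flagged:
        logger.warning("association scan: flagged=%d proteins excluded from q-values", n_flagged)
    return out


def consensus_overlap(
    results_with_cov: pd.DataFrame,
    results_without_cov: pd.DataFrame,
    q_threshold: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Compare significant calls between covariate-adjusted and unadjusted scans.

    Returns DataFrames (effect signs from each model) for proteins significant
    in both models, only with the covariate, and only without it.  Proteins
    significant only without the covariate are confounding suspects.
    """
    if set(results_with_cov.index) != set(results_without_cov.index):
        raise ValueError("the two result sets must share a protein universe")

    def sig(df: pd.DataFrame) -> set[str]:
        return set(df.index[(df["q_value"] < q_threshold) & ~df["flagged"]])

    s_with, s_without = sig(results_with_cov), sig(results_without_cov)
    def table(ids: set[str]) -> pd.DataFrame:
        ids = sorted(ids)
        return pd.DataFrame(
            {
                "effect_with_cov": results_with_cov.loc[ids, "effect_size"],
                "effect_without_cov": results_without_cov.loc[ids, "effect_size"],
            },
            index=pd.Index(ids, name="protein_id"),
        )

    return {
        "both": table(s_with & s_without),
        "only_with": table(s_with - s_without),
        "only_without": table(s_without - s_with),
    }
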