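"""Weighted Kolmogorov-Smirnov enrichment: one core, three callers.

The same running-score statistic serves (i) GSEA on proteins ranked by trait
effect size, (ii) GSEA on proteins ranked by CV, and (iii) connectivity
scoring of compound perturbation signatures against the insulin-resistance
fingerprint.

Walking down a ranked gene list, hitting a set member increments the running
sum by |metric|^w normalised by the total hit weight, and a miss decrements
by 1/(N - n_set).  The enrichment score (ES) is the signed extremum of the
running sum and lies in [-1, 1].  A strongly negative ES against a compound
signature means the compound down-regulates the query set -- a "reversal" in
connectivity-map terms.

Connectivity uses weight 0 (the fingerprint is an unordered gene set carrying
no ranking metric), raw per-cell-line ES values are averaged per compound,
and compounds are ordered ascending so the strongest reversers come first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import qvalues

logger = logging.getLogger(__name__)

__all__ = [
    "RankedSignature",
    "EnrichmentResult",
    "ConnectivityResult",
    "SignatureDB",
    "running_enrichment_score",
    "es_permutation_p",
    "connectivity_score",
]


@dataclass(frozen=True)
class RankedSignature:
    """A fully ordered gene list with its (non-increasing) ranking metric.

    ``from_metric`` sorts descending with ties broken by gene id so that the
    ranking is deterministic.
    """

    source: str
    genes: tuple[str, ...]
    metric: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if any(b > a for a, b in zip(self.metric, self.metric[1:])):
            raise ValueError("metric must be non-increasing")

    @classmethod
    def from_metric(cls, source: str, metric: pd.Series) -> "RankedSignature":
        df = pd.DataFrame({"gene": metric.index.astype(str), "m": metric.to_numpy(dtype=float)})
        df = df.sort_values(["m", "gene"], ascending=[False, True], kind="mergesort")
        return cls(source=source, genes=tuple(df["gene"]), metric=tuple(df["m"]))

    @classmethod
    def from_ranking(cls, source: str, genes: list[str]) -> "RankedSignature":
        """Rank-only signature (metric is the reversed rank; used at w = 0)."""
        n = len(genes)
        return cls(source=source, genes=tuple(genes), metric=tuple(float(n - i) for i in range(n)))


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    running: np.ndarray
    n_hits: int
    p_value: float = np.nan


@dataclass(frozen=True)
class ConnectivityResult:
    compound: str
    per_cell_line: dict[str, float]
    raw_score: float
    coverage: float


@dataclass
class SignatureDB:
    """Compound x cell-line ranked gene lists over a common universe."""

    rankings: dict[tuple[str, str], tuple[str, ...]]
    universe: tuple[str, ...]

    @property
    def compounds(self) -> list[str]:
        return sorted({c for c, _ in self.rankings})

    @property
    def cell_lines(self) -> list[str]:
        return sorted({l for _, l in self.rankings})


def running_enrichment_score(
    sig: RankedSignature,
    gene_set: set[str] | frozenset[str],
    weight_exponent: float = 1.0,
    set_name: str = "query",
) -> EnrichmentResult:
    """Weighted-KS enrichment of ``gene_set`` within a ranked signature.

    Hits step up by |metric|^w / NR (NR = total hit weight); misses step down
    by 1/(N - n_set).  ES is the running-sum value of largest magnitude; its
    sign marks whether the set concentrates at the top (+) or bottom (-) of
    the ranking.
    """
    genes = np.asarray(sig.genes)
    gene_set = frozenset(gene_set)
    hit = np.isin(genes, list(gene_set))
    n_hits = int(hit.sum())
    n = len(genes)
    if n_hits == 0:
        raise ValueError(f"gene set {set_name!r} is disjoint from the signature")
    if n_hits == n:
        raise ValueError("gene set equals the whole universe; miss penalty undefined")
    metric = np.abs(np.asarray(sig.metric, dtype=float))
    w = metric ** weight_exponent if weight_exponent != 0 else np.ones(n)
    nr = float(w[hit].sum())
    if nr <= 0:
        raise ValueError("total hit weight is zero; cannot normalise")
    steps = np.where(hit, w / nr, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return EnrichmentResult(set_name=set_name, es=float(running[i]), running=running, n_hits=n_hits)


def es_permutation_p(
    sig: RankedSignature,
    gene_set: set[str],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> EnrichmentResult:
    """Two-sided gene-permutation p for an enrichment score (+1 corrected).

    Null sets are drawn uniformly from the signature's universe at the
    observed hit count.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(rng)
    obs = running_enrichment_score(sig, gene_set, weight_exponent)
    genes = np.asarray(sig.genes)
    n = len(genes)
    metric = np.abs(np.asarray(sig.metric, dtype=float))
    w = metric ** weight_exponent if weight_exponent != 0 else np.ones(n)
    miss_base = None
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=obs.n_hits, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        nr = float(w[hit].sum())
        if nr <= 0:
            continue
        steps = np.where(hit, w / nr, -1.0 / (n - obs.n_hits))
        running = np.cumsum(steps)
        if np.abs(running).max() >= abs(obs.es):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return EnrichmentResult(obs.set_name, obs.es, obs.running, obs.n_hits, p_value=p)


def fdr_across_sets(results: list[EnrichmentResult]) -> np.ndarray:
    """BH adjustment (pi0 = 1) of permutation p-values across gene sets."""
    return qvalues(np.array([r.p_value for r in results]), pi0=1.0)


def gsea_on_ranking(
    metric: pd.Series,
    gene_sets: dict[str, set[str]],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    source: str = "ranking",
) -> pd.DataFrame:
    """GSEA of several gene sets against one ranked protein list.

    ``metric`` maps gene -> ranking value (e.g. trait effect size, or CV);
    the ranking is metric-descending with ties broken by gene id.  This is
    the same weighted-KS core that connectivity scoring uses — only the
    caller differs.  Returns one row per gene set with ES, permutation p and
    BH-adjusted q; sets disjoint from the ranking are skipped with a warning.
    """
    sig = RankedSignature.from_metric(source, metric)
    rng = np.random.default_rng(rng)
    rows, results = [], []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & set(sig.genes)
        if not members or len(members) == len(sig.genes):
            logger.warning("gsea: skipping set %r (empty or full overlap)", name)
            continue
        res = es_permutation_p(sig, members, weight_exponent, n_perm, rng)
        results.append(res)
        rows.append({"set_name": name, "es": res.es, "n_hits": res.n_hits,
                     "p_value": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = fdr_across_sets(results)
        out = out.set_index("set_name")
    return out


def connectivity_score(
    db: SignatureDB,
    query: set[str],
    weight_exponent: float = 0.0,
    coverage_warn: float = 0.9,
) -> list[ConnectivityResult]:
    """Score every compound's signatures against the query gene set.

    Per compound x cell line, the ES of the query within that ranking; the
    raw connectivity score is the arithmetic mean across cell lines.  Results
    are sorted ascending (strongest reversers first, ties by compound id).
    Signatures covering less than ``coverage_warn`` of the query are scored on
    the intersection with a logged warning.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    out = []
    for compound in db.compounds:
        per_line: dict[str, float] = {}
        coverages = []
        for line in db.cell_lines:
            key = (compound, line)
            if key not in db.rankings:
                continue
            genes = db.rankings[key]
            present = query & set(genes)
            cov = len(present) / len(query)
            coverages.append(cov)
            if cov == 0:
                logger.warning("connectivity: %s/%s covers none of the query", compound, line)
                continue
            if cov < coverage_warn:
                logger.warning(
                    "connectivity coverage=%0.2f compound=%s cell_line=%s (scored on intersection)",
                    cov, compound, line,
                )
            sig = RankedSignature.from_ranking(f"{compound}:{line}", list(genes))
            per_line[line] = running_enrichment_score(sig, present, weight_exponent).es
        if not per_line:
            continue
        out.append(
            ConnectivityResult(
                compound=compound,
                per_cell_line=per_line,
                raw_score=float(np.mean(list(per_line.values()))),
                coverage=float(np.mean(coverages)),
            )
        )
    out.sort(key=lambda r: (r.raw_score, r.compound))
    return out


def connectivity_table(results: list[ConnectivityResult]) -> pd.DataFrame:
    """Long-to-wide convenience: one row per compound with per-line ES columns."""
    lines = sorted({l for r in results for l in r.per_cell_line})
    rows = {
        r.compound: {
            **{f"es_{l}": r.per_cell_line.get(l, np.nan) for l in lines},
            "raw_score": r.raw_score,
            "coverage": r.coverage,
        }
        for r in results
    }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_values(["raw_score"])
    df.index.name = "compound"
    return df
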