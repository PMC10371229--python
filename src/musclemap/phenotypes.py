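"""Per-mouse and per-protein summary phenotypes.

This module computes the phenotypic primitives of the pipeline: the Matsuda
Index (a surrogate for whole-body insulin sensitivity built from glucose
tolerance test curves), adiposity from body composition, and the standard
proteome summaries (presence filtering, median normalisation, coefficient of
variation, fraction enrichment).

The Matsuda Index is

    10,000 / sqrt(G0 * I0 * G_mean * I_mean)

where ``G0``/``I0`` are fasting (t = 0) glucose and insulin and the means run
over all sampled GTT timepoints.  The index is scale-equivariant, not
unit-free: halving all glucose values doubles the index.  Units therefore only
need to be internally consistent across mice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GTTRecord",
    "BodyComposition",
    "ProteinMatrix",
    "matsuda_index",
    "adiposity_percent",
    "presence_filter",
    "normalise_proteome",
    "coefficient_of_variation",
    "fraction_enrichment",
    "phenotype_table",
]


class DomainError(ValueError):
    """Raised when an input violates a biological domain constraint."""


@dataclass(frozen=True)
class GTTRecord:
    """One mouse's glucose tolerance test time course.

    Glucose is sampled at several timepoints after the oral bolus; insulin at
    a subset of those (here typically 0 and 15 min).  All concentrations must
    be positive and time 0 must be present in both series.
    """

    mouse_id: str
    glucose_times: tuple[float, ...]
    glucose_values: tuple[float, ...]
    insulin_times: tuple[float, ...]
    insulin_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, times, values in (
            ("glucose", self.glucose_times, self.glucose_values),
            ("insulin", self.insulin_times, self.insulin_values),
        ):
            if len(times) != len(values):
                raise DomainError(f"{name} times/values length mismatch for {self.mouse_id}")
            if len(times) == 0:
                raise DomainError(f"empty {name} series for {self.mouse_id}")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise DomainError(f"{name} times not strictly increasing for {self.mouse_id}")
            if times[0] != 0:
                raise DomainError(f"{name} series must start at time 0 for {self.mouse_id}")
            if any(v <= 0 for v in values):
                raise DomainError(f"non-positive {name} value for {self.mouse_id}")
        if not set(self.insulin_times) <= set(self.glucose_times):
            raise DomainError(f"insulin times not a subset of glucose times for {self.mouse_id}")


@dataclass(frozen=True)
class BodyComposition:
    """EchoMRI-style body composition for one mouse (grams)."""

    mouse_id: str
    fat_mass: float
    lean_mass: float
    body_mass: float

    def __post_init__(self) -> None:
        if min(self.fat_mass, self.lean_mass, self.body_mass) < 0:
            raise DomainError(f"negative mass for {self.mouse_id}")
        if self.fat_mass + self.lean_mass > self.body_mass * (1 + 1e-9):
            raise DomainError(f"fat + lean exceeds body mass for {self.mouse_id}")


@dataclass
class ProteinMatrix:
    """A mice x proteins log2-abundance matrix for one subcellular fraction.

    ``values`` holds mice as rows (index = mouse_id) and proteins as columns;
    missing observations are NaN.  ``positions`` maps each protein to the
    genomic coordinate of its gene (columns ``chrom`` and ``pos_bp``, 1-based
    physical bp), which the pQTL stage needs for cis/trans classification.
    """

    values: pd.DataFrame
    fraction: str
    positions: pd.DataFrame = field(default_factory=pd.DataFrame)
    annotations: pd.DataFrame | None = None

    @property
    def mouse_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    def presence_fraction(self) -> pd.Series:
        """Fraction of mice in which each protein was observed."""
        return self.values.notna().mean(axis=0)


def matsuda_index(record: GTTRecord, exclude_baseline_from_mean: bool = False) -> float:
    """Surrogate whole-body insulin sensitivity from a GTT record.

    Returns ``10,000 / sqrt(G0 * I0 * G_mean * I_mean)``.  By default the GTT
    means include the t = 0 (fasting) value, the convention of the original
    composite-index derivation; set ``exclude_baseline_from_mean`` to average
    post-bolus timepoints only.
    """
    g = np.asarray(record.glucose_values, dtype=float)
    i = np.asarray(record.insulin_values, dtype=float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise DomainError(f"non-positive concentration for {record.mouse_id}")
    g0 = g[0]
    i0 = i[0]
    gm = g[1:].mean() if exclude_baseline_from_mean and len(g) > 1 else g.mean()
    im = i[1:].mean() if exclude_baseline_from_mean and len(i) > 1 else i.mean()
    return 10_000.0 / float(np.sqrt(g0 * i0 * gm * im))


def adiposity_percent(bc: BodyComposition) -> float:
    """Percentage of body mass which is adipose tissue."""
    if bc.body_mass <= 0:
        raise DomainError(f"zero body mass for {bc.mouse_id}")
    return 100.0 * bc.fat_mass / bc.body_mass


def presence_filter(pm: ProteinMatrix, min_fraction: float = 0.5) -> ProteinMatrix:
    """Retain proteins observed in at least ``min_fraction`` of mice (inclusive).

    Column order is preserved; dropped protein ids are logged.
    """
    if pm.values.shape[1] == 0:
        logger.warning("presence_filter: empty protein matrix (fraction=%s)", pm.fraction)
        return pm
    frac = pm.presence_fraction()
    keep = frac[frac >= min_fraction].index
    dropped = [p for p in pm.protein_ids if p not in set(keep)]
    if dropped:
        logger.info(
            "presence_filter fraction=%s dropped=%d kept=%d ids=%s",
            pm.fraction, len(dropped), len(keep), ",".join(dropped[:20]),
        )
    values = pm.values.loc[:, [p for p in pm.protein_ids if p in set(keep)]]
    positions = pm.positions.loc[[p for p in values.columns if p in pm.positions.index]] \
        if len(pm.positions) else pm.positions
    return replace(pm, values=values, positions=positions)


def normalise_proteome(pm: ProteinMatrix, log_transform: bool = False) -> ProteinMatrix:
    """Median-normalise a proteome to remove per-mouse loading differences.

    With ``log_transform`` the input is raw positive intensities which are
    log2 transformed first; otherwise values are taken as already log2.  Each
    mouse's (row) median is then shifted to the grand median of all row
    medians.  Missing values are untouched.
    """
    values = pm.values
    if log_transform:
        bad = values.stack()
        bad = bad[bad <= 0]
        if len(bad):
            cells = ", ".join(f"({m},{p})" for m, p in bad.index[:10])
            raise DomainError(f"non-positive intensities cannot be log2 transformed: {cells}")
        values = np.log2(values)
    row_medians = values.median(axis=1, skipna=True)
    grand = row_medians.median()
    values = values.sub(row_medians - grand, axis=0)
    return replace(pm, values=values)


def coefficient_of_variation(pm: ProteinMatrix, from_log2: bool = True) -> pd.DataFrame:
    """Per-protein CV on the linear intensity scale, ranked descending.

    The CV of log values is not scale-free, so log2 data are exponentiated
    back to linear intensities first (``from_log2``).  Sample (n-1) SD.
    Proteins with fewer than two observations or non-positive linear mean are
    flagged (``cv`` NaN) and sort to the bottom.
    """
    linear = np.power(2.0, pm.values) if from_log2 else pm.values
    mean = linear.mean(axis=0, skipna=True)
    sd = linear.std(axis=0, ddof=1, skipna=True)
    n_obs = linear.notna().sum(axis=0)
    cv = sd / mean
    undefined = (mean <= 0) | (n_obs < 2)
    if undefined.any():
        logger.warning("coefficient_of_variation: %d proteins with undefined CV", int(undefined.sum()))
    cv[undefined] = np.nan
    out = pd.DataFrame({"mean": mean, "sd": sd, "n_obs": n_obs, "cv": cv})
    out.index.name = "protein_id"
    return out.sort_values("cv", ascending=False, na_position="last", kind="mergesort")


def fraction_enrichment(
    pm_mito: ProteinMatrix, pm_pmf: ProteinMatrix, geneset: Iterable[str],
    from_log2: bool = True,
) -> float:
    """Enrichment of a gene set's abundance share in the mito fraction vs PMF.

    Computes, per fraction, the share of total summed linear abundance carried
    by gene-set proteins, and returns mito share / PMF share.  A value near 2
    means the set is twofold enriched in the mitochondrial fraction.
    """
    geneset = set(geneset)
    shares = []
    for pm in (pm_mito, pm_pmf):
        linear = np.power(2.0, pm.values) if from_log2 else pm.values
        members = [p for p in pm.protein_ids if p in geneset]
        if not members:
            shares.append(np.nan)
            continue
        total = float(np.nansum(linear.to_numpy()))
        part = float(np.nansum(linear[members].to_numpy()))
        shares.append(part / total if total > 0 else np.nan)
    if all(np.isnan(s) for s in shares):
        raise DomainError("gene set absent from both fractions")
    return shares[0] / shares[1]


def phenotype_table(
    records: Sequence[GTTRecord],
    body: Sequence[BodyComposition],
    exclude_baseline_from_mean: bool = False,
) -> pd.DataFrame:
    """Per-mouse phenotype summary: Matsuda Index and adiposity percent."""
    mats = {r.mouse_id: matsuda_index(r, exclude_baseline_from_mean) for r in records}
    adip = {b.mouse_id: adiposity_percent(b) for b in body}
    ids = sorted(mats)
    return pd.DataFrame(
        {
            "matsuda": [mats[m] for m in ids],
            "adiposity": [adip.get(m, np.nan) for m in ids],
        },
        index=pd.Index(ids, name="mouse_id"),
    )
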