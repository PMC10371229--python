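"""GLUT4-translocation screen hit calling and compound-score integration.

Three assay modes probe different routes to improved glucose uptake, each
read out as % of total GLUT4 at the plasma membrane:

* ``basal_agonist`` -- raises surface GLUT4 without insulin,
* ``sensitiser`` -- potentiates a submaximal (1 nM) insulin dose,
* ``reverser`` -- restores the 100 nM insulin response after palmitate-induced
  insulin resistance.

A compound is a hit when its mean response strictly exceeds 50% of the
relevant control window: basal + 0.5*(ins100 - basal) for agonists,
ins1 + 0.5*(ins100 - ins1) for sensitisers, and palm + 0.5*(ins100 - palm)
for reversers.  (The agonist rule is interpreted as 50% of the insulin
*response* above basal, parallel to the two difference rules; the literal
absolute reading "50% of the 100 nM level" is available via
``basal_rule='absolute'``.)

Integration z-scores each assay's responses and the (sign-flipped)
connectivity score over the consensus compound set, then ranks by

    overall = (z_bas + z_sens + z_rev) / 3 + z_cmap.

Raw connectivity scores are negated before z-scoring so that a stronger
reversal (more negative raw score) contributes positively to the overall
score; the raw sign convention is available via ``cmap_sign='raw'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenPlate",
    "HitCalls",
    "call_hits",
    "overlap_summary",
    "zscore_column",
    "overall_score",
    "build_score_matrix",
    "rank_compounds",
    "MODE_CONTROLS",
]

MODE_CONTROLS = {
    "basal_agonist": ("basal", "insulin_100nM"),
    "sensitiser": ("basal", "insulin_1nM", "insulin_100nM"),
    "reverser": ("basal", "insulin_100nM", "insulin_palmitate"),
}


@dataclass
class ScreenPlate:
    """One assay mode's plate set: control and compound wells (replicates)."""

    mode: str
    controls: dict[str, np.ndarray]
    compounds: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.mode not in MODE_CONTROLS:
            raise ValueError(f"unknown screen mode {self.mode!r}")
        missing = [c for c in MODE_CONTROLS[self.mode] if c not in self.controls]
        if missing:
            raise ValueError(f"mode {self.mode!r} missing required controls: {missing}")
        for name, vals in [*self.controls.items(), *self.compounds.items()]:
            if np.any(np.asarray(vals) < 0):
                raise ValueError(f"negative %GLUT4 value in well {name!r}")

    def control_mean(self, name: str) -> float:
        return float(np.mean(self.controls[name]))


@dataclass
class HitCalls:
    mode: str
    threshold: float
    table: pd.DataFrame  # index compound; columns mean_response, is_hit

    @property
    def hits(self) -> set[str]:
        return set(self.table.index[self.table["is_hit"]])


def call_hits(plate: ScreenPlate, basal_rule: str = "response") -> HitCalls:
    """Apply the mode's 50%-of-control rule; strict ``>`` at the threshold."""
    ins100 = plate.control_mean("insulin_100nM")
    if plate.mode == "basal_agonist":
        basal = plate.control_mean("basal")
        if basal_rule == "response":
            threshold = basal + 0.5 * (ins100 - basal)
            ref = basal
        elif basal_rule == "absolute":
            threshold = 0.5 * ins100
            ref = 0.0
        else:
            raise ValueError(f"unknown basal_rule {basal_rule!r}")
    elif plate.mode == "sensitiser":
        ref = plate.control_mean("insulin_1nM")
        threshold = ref + 0.5 * (ins100 - ref)
    else:  # reverser
        ref = plate.control_mean("insulin_palmitate")
        threshold = ref + 0.5 * (ins100 - ref)
    if ins100 <= ref:
        raise ValueError(
            f"no assay window in mode {plate.mode!r}: insulin_100nM ({ins100:.3g}) "
            f"<= reference control ({ref:.3g})"
        )
    means = {c: float(np.mean(v)) for c, v in plate.compounds.items()}
    table = pd.DataFrame(
        {
            "mean_response": pd.Series(means),
            "threshold": threshold,
        }
    ).sort_index()
    table["is_hit"] = table["mean_response"] > threshold
    table.index.name = "compound"
    logger.info("call_hits mode=%s threshold=%.3f hits=%d", plate.mode, threshold, int(table["is_hit"].sum()))
    return HitCalls(mode=plate.mode, threshold=threshold, table=table)


def overlap_summary(calls: dict[str, HitCalls]) -> dict[str, int]:
    """Counts of every intersection region of the three hit sets."""
    b = calls["basal_agonist"].hits
    s = calls["sensitiser"].hits
    r = calls["reverser"].hits
    return {
        "basal_only": len(b - s - r),
        "sensitiser_only": len(s - b - r),
        "reverser_only": len(r - b - s),
        "basal_and_sensitiser": len((b & s) - r),
        "basal_and_reverser": len((b & r) - s),
        "sensitiser_and_reverser": len((s & r) - b),
        "all_three": len(b & s & r),
    }


def zscore_column(values: pd.Series) -> pd.Series:
    """(x - mean) / SD with sample SD; missing values propagate as missing."""
    obs = values.dropna()
    if obs.nunique() < 2:
        raise ValueError("zscore_column needs at least two distinct observed values")
    sd = obs.std(ddof=1)
    return (values - obs.mean()) / sd


def overall_score(z_bas: float, z_sens: float, z_rev: float, z_cmap_reversal: float) -> float:
    """Average of the three assay z-scores plus the connectivity z-score."""
    return (z_bas + z_sens + z_rev) / 3.0 + z_cmap_reversal


def build_score_matrix(
    responses: pd.DataFrame,
    connectivity_raw: pd.Series,
    cmap_sign: str = "reversal-positive",
) -> pd.DataFrame:
    """Integrate screen responses and connectivity into the final score matrix.

    ``responses`` has one row per compound with columns ``basal_agonist``,
    ``sensitiser`` and ``reverser`` (mean %GLUT4-at-PM per assay);
    ``connectivity_raw`` is the raw mean connectivity score per compound.
    Scoring is restricted to the consensus set: compounds present in both
    inputs.  Each column is z-scored over that set; a compound missing one
    assay gets z = 0 there (population-neutral) and is flagged.
    """
    if cmap_sign not in ("reversal-positive", "raw"):
        raise ValueError(f"unknown cmap_sign {cmap_sign!r}")
    consensus = sorted(set(responses.index) & set(connectivity_raw.index))
    if not consensus:
        raise ValueError("empty consensus compound set between screen and signature database")
    resp = responses.loc[consensus]
    raw = connectivity_raw.loc[consensus].astype(float)
    if cmap_sign == "reversal-positive":
        raw = -raw
    out = pd.DataFrame(index=pd.Index(consensus, name="compound"))
    incomplete = pd.Series(False, index=out.index)
    for mode, col in (("basal_agonist", "z_bas"), ("sensitiser", "z_sens"), ("reverser", "z_rev")):
        z = zscore_column(resp[mode])
        incomplete |= z.isna()
        out[col] = z.fillna(0.0)
    out["z_cmap"] = zscore_column(raw).fillna(0.0)
    incomplete |= raw.isna()
    out["overall"] = (out["z_bas"] + out["z_sens"] + out["z_rev"]) / 3.0 + out["z_cmap"]
    out["incomplete"] = incomplete
    return out


def rank_compounds(score_matrix: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Order the score matrix descending by overall score.

    Ties break by z_cmap (descending) then compound id, so the ranking is
    fully deterministic under row permutations of the input.
    """
    if score_matrix.empty:
        raise ValueError("empty score matrix")
    df = score_matrix.copy()
    df["_id"] = df.index
    df = df.sort_values(["overall", "z_cmap", "_id"], ascending=[False, False, True], kind="mergesort")
    df = df.drop(columns="_id")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.head(top_k) if top_k else df
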