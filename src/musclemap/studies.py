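"""Calibration and recovery studies run against the synthetic generator.

These are the package's own validation experiments: each function sets up a
known ground truth, runs the relevant pipeline machinery from scratch, and
returns the measured operating characteristics (false-positive rates, recall,
ranking recovery).  The test suite asserts on these numbers and the
acceptance script reports them; both call the same code so the reported
numbers are always recomputed, never cached.

Problem sizes default to desk scale: a few hundred mice/markers/proteins and
200 permutations, which keeps every study in seconds-to-minutes while leaving
the statistics well resolved.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .association import qvalues
from .enrichment import connectivity_score
from .pipeline import PipelineConfig, run_pipeline
from .qtl import ScanConfig, genome_scan, kinship_matrix, map_pqtl, permutation_threshold
from .screen import build_score_matrix, call_hits, rank_compounds
from .simulate import (SimConfig, SimTruth, simulate_genotypes,
                       simulate_proteome, simulate_screen,
                       simulate_signature_db)

__all__ = [
    "qvalue_null_fdr",
    "permutation_fpr",
    "cis_trans_recovery",
    "connectivity_recovery",
    "integration_recovery",
    "fingerprint_recovery",
    "determinism_check",
]


def qvalue_null_fdr(n_seeds: int = 100, m: int = 10_000, q_cut: float = 0.05,
                    seed: int = 0) -> dict:
    """Empirical FDR of the q-value procedure under a global null.

    Every discovery under the null is false, so per seed the false-discovery
    proportion is 1 if anything passes ``q_cut`` and 0 otherwise.
    """
    rng = np.random.default_rng([seed, 201])
    fdp = []
    for _ in range(n_seeds):
        p = rng.uniform(size=m)
        rej = int((qvalues(p) < q_cut).sum())
        fdp.append(1.0 if rej else 0.0)
    return {"fdr": float(np.mean(fdp)), "n_seeds": n_seeds, "m": m}


def permutation_fpr(
    n_seeds: int = 200,
    n_mice: int = 100,
    n_chromosomes: int = 5,
    markers_per_chromosome: int = 100,
    n_perm: int = 200,
    alpha: float = 0.05,
    heritability: float = 0.3,
    seed: int = 0,
) -> dict:
    """Genome-wide false-positive rate of the permutation threshold.

    Null phenotypes carry kinship-structured (polygenic) variance but no
    marker effect; a well-calibrated genome-wide permutation p rejects at
    ``alpha`` with probability ``alpha``.
    """
    gcfg = SimConfig(n_mice=n_mice, n_chromosomes=n_chromosomes,
                     markers_per_chromosome=markers_per_chromosome, seed=seed)
    geno = simulate_genotypes(gcfg)
    G = geno.dosages
    K = kinship_matrix(G)
    lam, U = np.linalg.eigh(K.to_numpy())
    sqrtK = U * np.sqrt(np.clip(lam, 0, None))
    rng = np.random.default_rng([seed, 202])
    ss = np.random.SeedSequence([seed, 203]).spawn(n_seeds)
    hits = 0
    for child in ss:
        g = sqrtK @ rng.standard_normal(n_mice)
        g = (g - g.mean()) / g.std(ddof=1)
        y = pd.Series(np.sqrt(heritability) * g
                      + np.sqrt(1 - heritability) * rng.standard_normal(n_mice),
                      index=G.index)
        cfg = ScanConfig(n_permutations=n_perm)
        scan = genome_scan(y, G, K, None, cfg)
        perm = permutation_threshold(y, G, K, None, cfg, rng=np.random.default_rng(child))
        hits += perm.p_value(scan.peak_lod) < alpha
    return {"fpr": hits / n_seeds, "n_seeds": n_seeds, "alpha": alpha}


def cis_trans_recovery(seed: int = 0, n_perm: int = 200,
                       n_proteins_per_fraction: int = 100) -> dict:
    """Classification recovery for planted cis and trans architectures.

    Uses the default proteome scale so that the 10-factor residualisation
    step sees the matrix width it was designed for.
    """
    cfg = SimConfig(n_mice=215, cis_h2=0.3, missing_rate=0.1,
                    n_proteins_per_fraction=n_proteins_per_fraction, seed=seed)
    geno = simulate_genotypes(cfg)
    proteome, truth = simulate_proteome(cfg, geno)
    scan_cfg = ScanConfig(n_permutations=n_perm, seed=seed)
    records = pd.concat([
        map_pqtl(proteome[fr], geno.dosages, geno.marker_map, scan_cfg)
        for fr in ("mito", "pmf")
    ])
    cis_true = [p for p in truth.cis_qtl_map if p in records.index]
    trans_true = [p for p in truth.trans_qtl_map if p in records.index]
    cls = records["classification"]
    recall_cis = float((cls.loc[cis_true] == "cis").mean()) if cis_true else np.nan
    trans_as_cis = float((cls.loc[trans_true] == "cis").mean()) if trans_true else 0.0
    return {
        "cis_recall": recall_cis,
        "trans_called_cis": trans_as_cis,
        "n_cis": len(cis_true),
        "n_trans": len(trans_true),
    }


def _signature_setup(seed: int, n_genes: int = 200, n_targets: int = 10) -> tuple:
    cfg = SimConfig(seed=seed)
    universe = [f"g{i:03d}" for i in range(n_genes)]
    targets = universe[:n_targets]
    truth = SimTruth()
    db = simulate_signature_db(cfg, universe, targets, truth)
    return cfg, db, set(targets), truth


def connectivity_recovery(n_seeds: int = 50, seed: int = 0) -> dict:
    """Do planted reversers land in the bottom decile of raw connectivity?"""
    all_bottom, neutral_means = [], []
    for s in range(n_seeds):
        cfg, db, targets, truth = _signature_setup(seed * 1000 + s)
        results = connectivity_score(db, targets)
        raw = pd.Series({r.compound: r.raw_score for r in results})
        cutoff = raw.sort_values().iloc[max(len(raw) // 10 - 1, 0)]
        rev = truth.reverser_compound_ids
        all_bottom.append(all(raw[c] <= cutoff for c in rev))
        neutral_means.append(raw.drop(list(rev)).mean())
    return {
        "bottom_decile_rate": float(np.mean(all_bottom)),
        "neutral_mean_score": float(np.mean(neutral_means)),
        "n_seeds": n_seeds,
    }


def integration_recovery(n_seeds: int = 50, seed: int = 0) -> dict:
    """How often does the planted dual-active reverser top the final ranking?"""
    top = 0
    for s in range(n_seeds):
        cfg, db, targets, truth = _signature_setup(seed * 1000 + s)
        plates = simulate_screen(cfg, db.compounds, truth)
        responses = pd.DataFrame({
            mode: call_hits(plate).table["mean_response"]
            for mode, plate in plates.items()
        })
        raw = pd.Series({r.compound: r.raw_score
                         for r in connectivity_score(db, targets)})
        ranked = rank_compounds(build_score_matrix(responses, raw))
        top += ranked.index[0] == truth.dual_compound
    return {"top_rank_rate": top / n_seeds, "n_seeds": n_seeds}


def fingerprint_recovery(seed: int = 1, n_perm: int = 200,
                         outdir: str | Path | None = None) -> dict:
    """End-to-end fingerprint recovery at the default study design (n=215)."""
    import json
    tmp = None
    if outdir is None:
        tmp = tempfile.TemporaryDirectory()
        outdir = tmp.name
    cfg = PipelineConfig(
        outdir=str(outdir),
        sim=SimConfig(seed=seed),
        scan=ScanConfig(n_permutations=n_perm, seed=seed),
        force=True,
    )
    out = run_pipeline(cfg)
    fp = pd.read_csv(out / "fingerprint.tsv", sep="\t", comment="#", index_col=0)
    truth = set(json.load(open(out / "truth.json"))["causal_effects"])
    recovered = set(fp.index)
    jaccard = len(recovered & truth) / len(recovered | truth) if recovered | truth else np.nan
    pqtl = pd.read_csv(out / "pqtl.tsv", sep="\t", comment="#", index_col=0)
    assoc = pd.concat([
        pd.read_csv(out / f"associations_{fr}.tsv", sep="\t", comment="#", index_col=0)
        for fr in ("mito", "pmf")
    ])
    neg_sig = set(assoc.index[(assoc["effect_size"] < 0) & (assoc["q_value"] < 0.05)])
    cis = set(pqtl.index[pqtl["classification"] == "cis"])
    subset_ok = recovered <= (neg_sig & cis)
    result = {
        "jaccard": float(jaccard),
        "fingerprint_size": len(recovered),
        "n_causal": len(truth),
        "recall": len(recovered & truth) / len(truth) if truth else np.nan,
        "subset_invariant_holds": bool(subset_ok),
        "n_mice": cfg.sim.n_mice,
    }
    if tmp is not None:
        tmp.cleanup()
    return result


def determinism_check(seed: int = 0, n_perm: int = 100) -> dict:
    """Two full runs with one seed must produce byte-identical score matrices."""
    sim = SimConfig(seed=seed)
    with tempfile.TemporaryDirectory() as d1, tempfile.TemporaryDirectory() as d2:
        for d in (d1, d2):
            run_pipeline(PipelineConfig(outdir=d, sim=sim,
                                        scan=ScanConfig(n_permutations=n_perm, seed=seed),
                                        force=True))
        identical = filecmp.cmp(Path(d1) / "score_matrix.tsv",
                                Path(d2) / "score_matrix.tsv", shallow=False)
    return {"byte_identical": bool(identical)}
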