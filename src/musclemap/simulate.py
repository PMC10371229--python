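"""Synthetic Diversity-Outbred-style data with known ground truth.

Every downstream stage of the pipeline is testable against this generator:

* ``simulate_genotypes`` -- founder-mosaic chromosomes (Poisson breakpoints,
  random founder segments) so that kinship and local LD exist, which is what
  the mixed-model scan and the cis window are there to handle.
* ``simulate_proteome`` -- per-protein variance built from a local-marker
  (cis) effect, shared latent factors, a polygenic term and noise, on the
  log2-abundance scale, with MCAR missingness.  A subset of proteins is
  driven by a distal marker (trans) and a subset is confounded with the
  adiposity latent.
* ``simulate_gtt`` -- draws a target log2 Matsuda Index per mouse from the
  causal-protein model and constructs glucose/insulin curves that reproduce
  that target *exactly* through the Matsuda formula (glucose curve shape is
  fixed; the fasting insulin level is solved in closed form).
* ``simulate_signature_db`` -- compound x cell-line rankings of the gene
  universe in which planted "reverser" compounds push target genes toward the
  bottom with tunable strength (strength >= 1 forces an exact bottom block).
* ``simulate_screen`` -- three GLUT4-translocation plate sets with controls
  and planted actives exceeding their mode's 50%-of-control rule in
  expectation.

Determinism contract: identical config + seed give byte-identical outputs;
each generator stage draws from its own seed stream so stages can be re-run
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .phenotypes import GTTRecord, BodyComposition, ProteinMatrix
from .enrichment import SignatureDB
from .screen import ScreenPlate

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "GenotypeData",
    "simulate_genotypes",
    "simulate_proteome",
    "simulate_gtt",
    "simulate_signature_db",
    "simulate_screen",
    "simulate_all",
]

# per-stage stream tags so stages draw independent, reproducible randomness
_STAGE_GENO, _STAGE_PROT, _STAGE_GTT, _STAGE_SIG, _STAGE_SCREEN = range(5)

GTT_GLUCOSE_TIMES = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0)
GTT_INSULIN_TIMES = (0.0, 15.0)
# fixed post-bolus glucose excursion shape (multiples of fasting glucose)
_GLUCOSE_SHAPE = np.array([1.0, 2.2, 1.9, 1.6, 1.3, 1.1])


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic population.

    Defaults emulate the scale of a chow-fed outbred mouse cohort: 215 mice,
    two muscle proteome fractions of 100 proteins each, cis effects explaining
    30% of protein variance, a handful of strong causal drivers of (log2)
    insulin sensitivity, an adiposity confounder, and ~10% missing protein
    observations.  Trait heterogeneity under these defaults spans two to three
    orders of magnitude across mice, matching the heterogeneity such outbred
    populations show.
    """

    n_mice: int = 215
    n_founders: int = 8
    n_chromosomes: int = 5
    markers_per_chromosome: int = 60
    chromosome_length_bp: int = 100_000_000
    # Expected founder-switch points per haplotype per chromosome.  An outbred
    # population at generation ~30 carries the recombination of all previous
    # generations, so mosaics are fine-grained (~6-7 Mb blocks here), not the
    # 1-2 crossovers of a single meiosis.
    mean_crossovers: float = 15.0
    n_proteins_per_fraction: int = 100
    cis_h2: float = 0.30
    cis_fraction: float = 0.50            # share of proteins with a local (cis) driver
    trans_fraction: float = 0.10          # share driven by a distal marker instead
    latent_share: float = 0.15            # variance share of hidden factors
    polygenic_share: float = 0.10
    n_latent_factors: int = 5
    n_causal_proteins: int = 8
    causal_effect_sd: float = 0.50        # central |effect| on log2 Matsuda per SD protein
    adiposity_effect: float = -0.50       # log2 Matsuda per SD adiposity latent
    n_confounded_proteins: int = 8
    confound_strength: float = 0.60
    noise_sd: float = 0.30                # residual SD of log2 Matsuda
    missing_rate: float = 0.10
    baseline_log2_matsuda: float = 3.3
    # compound-signature database
    n_compounds: int = 100
    n_cell_lines: int = 3
    n_reversers: int = 5
    reversal_strength: float = 0.7
    # GLUT4 screen
    screen_replicates: int = 4
    screen_noise_sd: float = 1.5          # %GLUT4 well noise
    active_margin: float = 0.25           # planted actives sit this far beyond threshold (x window)
    n_basal_actives: int = 5
    n_sensitiser_actives: int = 4
    n_reverser_actives: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_mice": self.n_mice, "n_founders": self.n_founders,
            "n_chromosomes": self.n_chromosomes,
            "markers_per_chromosome": self.markers_per_chromosome,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_proteins_per_fraction": self.n_proteins_per_fraction,
        }
        for name, v in counts.items():
            if v <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {v}")
        if self.markers_per_chromosome < 2:
            raise InvalidConfigError("markers_per_chromosome must be >= 2")
        for name, v in (("cis_h2", self.cis_h2), ("missing_rate", self.missing_rate),
                        ("latent_share", self.latent_share), ("polygenic_share", self.polygenic_share)):
            if not (0 <= v < 1):
                raise InvalidConfigError(f"{name} must be in [0, 1), got {v}")
        if self.cis_h2 + self.latent_share + self.polygenic_share > 1:
            raise InvalidConfigError("cis_h2 + latent_share + polygenic_share must be <= 1")
        if self.cis_fraction + self.trans_fraction > 1:
            raise InvalidConfigError("cis_fraction + trans_fraction must be <= 1")


@dataclass
class SimTruth:
    """Planted ground truth used by recovery tests and acceptance checks."""

    causal_effects: dict[str, float] = field(default_factory=dict)
    cis_qtl_map: dict[str, tuple[str, float]] = field(default_factory=dict)
    trans_qtl_map: dict[str, tuple[str, float]] = field(default_factory=dict)
    confounded_proteins: list[str] = field(default_factory=list)
    adiposity_latent: pd.Series | None = None
    complete_values: pd.DataFrame | None = None
    biological_values: pd.DataFrame | None = None
    gtt_targets: pd.Series | None = None
    reverser_compound_ids: set[str] = field(default_factory=set)
    dual_compound: str | None = None
    screen_active_map: dict[str, tuple[str, float]] = field(default_factory=dict)

    @property
    def causal_protein_ids(self) -> set[str]:
        return set(self.causal_effects)

    def to_json_dict(self) -> dict:
        return {
            "causal_effects": self.causal_effects,
            "cis_qtl_map": {k: list(v) for k, v in self.cis_qtl_map.items()},
            "trans_qtl_map": {k: list(v) for k, v in self.trans_qtl_map.items()},
            "confounded_proteins": self.confounded_proteins,
            "reverser_compound_ids": sorted(self.reverser_compound_ids),
            "dual_compound": self.dual_compound,
            "screen_active_map": {k: list(v) for k, v in self.screen_active_map.items()},
        }


@dataclass
class GenotypeData:
    dosages: pd.DataFrame            # mice x markers, values in [0, 2]
    marker_map: pd.DataFrame         # index marker_id; chrom, pos_bp
    founder_haplotypes: np.ndarray   # (n_mice, 2, n_markers) founder labels
    founder_alleles: np.ndarray      # (n_founders, n_markers) 0/1


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


def simulate_genotypes(cfg: SimConfig) -> GenotypeData:
    """Founder-mosaic genotypes for an outbred population.

    Each of a mouse's two haplotypes per chromosome is a mosaic of founder
    segments: breakpoint count ~ Poisson(mean_crossovers), breakpoint
    positions uniform, segment founders drawn uniformly.  Marker dosage is
    the sum of the two founders' allele states.  With a single founder every
    mouse is genetically identical.
    """
    rng = _rng(cfg, _STAGE_GENO)
    n, nf = cfg.n_mice, cfg.n_founders
    mpc, L = cfg.markers_per_chromosome, cfg.chromosome_length_bp
    chroms, positions, marker_ids = [], [], []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = np.round((np.arange(mpc) + 0.5) * L / mpc).astype(int)
        pos = np.maximum.accumulate(pos)  # guard against rounding collisions
        pos += np.arange(mpc)             # strictly increasing
        for j, p in enumerate(pos):
            chroms.append(chrom)
            positions.append(int(p))
            marker_ids.append(f"{chrom}_m{j + 1:04d}")
    marker_map = pd.DataFrame(
        {"chrom": chroms, "pos_bp": positions},
        index=pd.Index(marker_ids, name="marker_id"),
    )
    m_total = len(marker_map)
    founder_alleles = rng.integers(0, 2, size=(nf, m_total)).astype(np.int8)

    hap = np.zeros((n, 2, m_total), dtype=np.int16)
    col0 = 0
    for c in range(cfg.n_chromosomes):
        pos = marker_map["pos_bp"].to_numpy()[col0:col0 + mpc].astype(float)
        for i in range(n):
            for h in range(2):
                nb = rng.poisson(cfg.mean_crossovers)
                cuts = np.sort(rng.uniform(0, L, size=nb))
                founders = rng.integers(0, nf, size=nb + 1)
                seg = np.searchsorted(cuts, pos, side="right")
                hap[i, h, col0:col0 + mpc] = founders[seg]
        col0 += mpc

    dos = founder_alleles[hap[:, 0, :], np.arange(m_total)] + \
        founder_alleles[hap[:, 1, :], np.arange(m_total)]
    mouse_ids = [f"DO{i + 1:04d}" for i in range(n)]
    dosages = pd.DataFrame(dos.astype(float), index=pd.Index(mouse_ids, name="mouse_id"),
                           columns=marker_map.index)
    return GenotypeData(dosages=dosages, marker_map=marker_map,
                        founder_haplotypes=hap, founder_alleles=founder_alleles)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_proteome(cfg: SimConfig, geno: GenotypeData) -> tuple[dict[str, ProteinMatrix], SimTruth]:
    """Two-fraction log2 proteome with cis/trans/null proteins.

    Per protein (unit-variance scale before the log2 abundance offset):

        value = sqrt(h2_qtl) * z(dosage) + sqrt(latent_share) * factor_mix
                + sqrt(polygenic_share) * u + sqrt(residual) * noise

    Confounded proteins additionally mix in the adiposity latent.  Missing
    values are MCAR at ``missing_rate``.  Returns {"mito": ..., "pmf": ...}
    and the ground truth (which also keeps the complete, pre-missingness
    matrix for the GTT stage).
    """
    if cfg.cis_h2 >= 1:
        raise InvalidConfigError("cis_h2 must be < 1")
    rng = _rng(cfg, _STAGE_PROT)
    n = cfg.n_mice
    n_prot = 2 * cfg.n_proteins_per_fraction
    fractions = ["mito"] * cfg.n_proteins_per_fraction + ["pmf"] * cfg.n_proteins_per_fraction
    pids = [f"{fr}P{i + 1:04d}" for i, fr in enumerate(fractions)]

    marker_map = geno.marker_map
    dos = geno.dosages.to_numpy()
    poly_markers = np.where(dos.std(axis=0, ddof=1) > 0)[0]
    if len(poly_markers) == 0:
        raise InvalidConfigError("no polymorphic markers; cannot place QTL effects")

    roles = np.array(["null"] * n_prot, dtype=object)
    order = rng.permutation(n_prot)
    n_cis = int(round(cfg.cis_fraction * n_prot))
    n_trans = int(round(cfg.trans_fraction * n_prot))
    roles[order[:n_cis]] = "cis"
    roles[order[n_cis:n_cis + n_trans]] = "trans"

    # latent factors shared across the proteome (batch / hidden structure)
    k = cfg.n_latent_factors
    F = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    # polygenic background from the realised kinship
    A = _col_standardized(dos[:, poly_markers])
    K = A @ A.T / A.shape[1]
    lamK, UK = np.linalg.eigh((K + K.T) / 2)
    u_all = UK @ (np.sqrt(np.clip(lamK, 0, None))[:, None] * rng.standard_normal((n, n_prot)))

    adiposity_latent = rng.standard_normal(n)

    truth = SimTruth()
    values = np.zeros((n, n_prot))
    latent_part = np.zeros((n, n_prot))   # technical/batch structure, not physiology
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    prot_chrom, prot_pos = [], []
    for j, pid in enumerate(pids):
        h2 = cfg.cis_h2 if roles[j] in ("cis", "trans") else 0.0
        resid = 1.0 - h2 - cfg.latent_share - cfg.polygenic_share
        comp = np.zeros(n)
        if roles[j] == "cis":
            mi = int(rng.choice(poly_markers))
            mrow = marker_map.iloc[mi]
            offset = int(rng.integers(-1_500_000, 1_500_001))
            gene_pos = int(np.clip(mrow["pos_bp"] + offset, 1, cfg.chromosome_length_bp))
            prot_chrom.append(str(mrow["chrom"]))
            prot_pos.append(gene_pos)
            comp += np.sqrt(h2) * _standardize(dos[:, mi])
            truth.cis_qtl_map[pid] = (marker_map.index[mi], float(np.sqrt(h2)))
        elif roles[j] == "trans":
            mi = int(rng.choice(poly_markers))
            mchrom = str(marker_map.iloc[mi]["chrom"])
            other = [c for c in chrom_names if c != mchrom]
            prot_chrom.append(str(rng.choice(other)))
            prot_pos.append(int(rng.integers(1, cfg.chromosome_length_bp)))
            comp += np.sqrt(h2) * _standardize(dos[:, mi])
            truth.trans_qtl_map[pid] = (marker_map.index[mi], float(np.sqrt(h2)))
        else:
            prot_chrom.append(str(rng.choice(chrom_names)))
            prot_pos.append(int(rng.integers(1, cfg.chromosome_length_bp)))
        if k:
            load = rng.standard_normal(k)
            load /= np.linalg.norm(load)
            lat = np.sqrt(cfg.latent_share) * (F @ load)
            latent_part[:, j] = lat
            comp += lat
        if cfg.polygenic_share > 0:
            uz = _standardize(u_all[:, j])
            comp += np.sqrt(cfg.polygenic_share) * uz
        comp += np.sqrt(resid) * rng.standard_normal(n)
        values[:, j] = comp

    # adiposity confounding hits a subset of null proteins
    null_ids = [pids[j] for j in range(n_prot) if roles[j] == "null"]
    n_conf = min(cfg.n_confounded_proteins, len(null_ids))
    conf = list(rng.choice(null_ids, size=n_conf, replace=False)) if n_conf else []
    cs = cfg.confound_strength
    for pid in conf:
        j = pids.index(pid)
        values[:, j] = np.sqrt(1 - cs ** 2) * values[:, j] + cs * adiposity_latent
        latent_part[:, j] = np.sqrt(1 - cs ** 2) * latent_part[:, j]
    truth.confounded_proteins = sorted(conf)

    # causal drivers of insulin sensitivity: a subset of cis proteins,
    # strictly negative effects ("up in insulin resistance")
    cis_ids = [pids[j] for j in range(n_prot) if roles[j] == "cis"]
    n_causal = min(cfg.n_causal_proteins, len(cis_ids))
    causal = list(rng.choice(cis_ids, size=n_causal, replace=False)) if n_causal else []
    for pid in sorted(causal):
        mag = cfg.causal_effect_sd * rng.uniform(0.7, 1.3)
        truth.causal_effects[pid] = -float(mag)

    base = rng.normal(12.0, 1.5, size=n_prot)   # log2 abundance offsets
    full = values + base[None, :]
    mouse_ids = list(geno.dosages.index)
    complete = pd.DataFrame(full, index=pd.Index(mouse_ids, name="mouse_id"),
                            columns=pids)
    observed = complete.mask(rng.random(size=complete.shape) < cfg.missing_rate)
    truth.complete_values = complete
    # physiology sees the animal's true protein levels, not batch structure
    truth.biological_values = complete - pd.DataFrame(latent_part, index=complete.index,
                                                      columns=complete.columns)
    truth.adiposity_latent = pd.Series(adiposity_latent, index=complete.index, name="adiposity_latent")

    positions = pd.DataFrame({"chrom": prot_chrom, "pos_bp": prot_pos},
                             index=pd.Index(pids, name="protein_id"))
    out: dict[str, ProteinMatrix] = {}
    for fr in ("mito", "pmf"):
        cols = [p for p, f in zip(pids, fractions) if f == fr]
        out[fr] = ProteinMatrix(values=observed[cols], fraction=fr,
                                positions=positions.loc[cols])
    return out, truth


def _col_standardized(X: np.ndarray) -> np.ndarray:
    """Column-standardise a mice x markers dosage block."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    return (X - mu) / sd


def simulate_gtt(cfg: SimConfig, truth: SimTruth) -> tuple[list[GTTRecord], list[BodyComposition]]:
    """GTT curves and body composition realising the causal trait model.

    Target log2 Matsuda per mouse:

        m = b0 + sum_j beta_j * (protein_j - mean_j) + gamma * adiposity + eps

    over the planted causal proteins.  The glucose curve uses a fixed
    excursion shape around a noisy fasting level; the fasting insulin level is
    then solved so that the Matsuda formula returns 2**m exactly (insulin at
    15 min is a fixed noisy multiple of fasting insulin).
    """
    rng = _rng(cfg, _STAGE_GTT)
    if truth.complete_values is None:
        raise ValueError("simulate_proteome must run before simulate_gtt")
    # causal drive goes through the biological protein signal; the measured
    # matrix adds technical factor structure on top of it
    vals = truth.biological_values if truth.biological_values is not None else truth.complete_values
    n = len(vals)
    m = np.full(n, cfg.baseline_log2_matsuda)
    for pid, beta in sorted(truth.causal_effects.items()):
        x = vals[pid].to_numpy()
        m = m + beta * (x - x.mean())
    a = truth.adiposity_latent.to_numpy()
    m = m + cfg.adiposity_effect * a
    m = m + cfg.noise_sd * rng.standard_normal(n)
    target = np.power(2.0, m)
    truth.gtt_targets = pd.Series(target, index=vals.index, name="matsuda_target")

    records: list[GTTRecord] = []
    body: list[BodyComposition] = []
    for i, mouse in enumerate(vals.index):
        g0 = max(rng.normal(9.0, 0.8), 4.0)
        shape = _GLUCOSE_SHAPE * (1 + rng.normal(0, 0.03, size=len(_GLUCOSE_SHAPE)))
        shape[0] = 1.0
        glucose = g0 * shape
        ratio = rng.uniform(2.0, 3.0)   # insulin excursion i15 / i0
        gmean = glucose.mean()
        i0 = 10_000.0 / (target[i] * np.sqrt(g0 * gmean * (1 + ratio) / 2.0))
        if i0 <= 0:  # cannot occur with positive targets; kept as a guard
            logger.warning("regenerating insulin for %s (non-positive solve)", mouse)
            i0 = 1e-6
        insulin = np.array([i0, ratio * i0])
        records.append(GTTRecord(
            mouse_id=str(mouse),
            glucose_times=GTT_GLUCOSE_TIMES,
            glucose_values=tuple(float(v) for v in glucose),
            insulin_times=GTT_INSULIN_TIMES,
            insulin_values=tuple(float(v) for v in insulin),
        ))
        body_mass = max(rng.normal(32.0, 3.0), 15.0)
        adip_pct = float(np.clip(18.0 + 6.0 * a[i], 2.0, 50.0))
        fat = adip_pct / 100.0 * body_mass
        lean = 0.75 * (body_mass - fat)
        body.append(BodyComposition(mouse_id=str(mouse), fat_mass=fat, lean_mass=lean, body_mass=body_mass))
    return records, body


def simulate_signature_db(
    cfg: SimConfig,
    universe: list[str],
    target_genes: list[str],
    truth: SimTruth | None = None,
) -> SignatureDB:
    """Compound x cell-line rankings with planted reversers of the target set.

    Every gene gets a uniform score per (compound, cell line); reversers
    subtract ``reversal_strength`` from the target genes' scores, pushing them
    toward the bottom of the ranking (down-regulated).  Strength >= 1 makes
    the target set the exact bottom block.  Neutral compounds rank the
    universe uniformly at random.
    """
    rng = _rng(cfg, _STAGE_SIG)
    missing = [g for g in target_genes if g not in set(universe)]
    if missing:
        raise ValueError(f"target genes missing from universe: {missing[:10]}")
    compounds = [f"cpd{i + 1:03d}" for i in range(cfg.n_compounds)]
    cell_lines = [f"CL{i + 1}" for i in range(cfg.n_cell_lines)]
    n_rev = min(cfg.n_reversers, cfg.n_compounds)
    reversers = sorted(rng.choice(compounds, size=n_rev, replace=False).tolist())
    target = set(target_genes)
    uni = sorted(universe)
    is_target = np.array([g in target for g in uni])
    rankings: dict[tuple[str, str], tuple[str, ...]] = {}
    for compound in compounds:
        for line in cell_lines:
            score = rng.random(len(uni))
            if compound in reversers:
                score = score - cfg.reversal_strength * is_target
            order = np.lexsort((uni, -score))
            rankings[(compound, line)] = tuple(uni[i] for i in order)
    if truth is not None:
        truth.reverser_compound_ids = set(reversers)
        truth.dual_compound = reversers[0] if reversers else None
    return SignatureDB(rankings=rankings, universe=tuple(uni))


# control well means per mode, % of total GLUT4 at the plasma membrane
CONTROL_MEANS = {
    "basal": 5.0,
    "insulin_1nM": 10.0,
    "insulin_100nM": 25.0,
    "insulin_palmitate": 12.0,
}
_MODE_REFERENCE = {"basal_agonist": "basal", "sensitiser": "insulin_1nM", "reverser": "insulin_palmitate"}


def simulate_screen(
    cfg: SimConfig,
    compounds: list[str],
    truth: SimTruth | None = None,
) -> dict[str, ScreenPlate]:
    """Three GLUT4-translocation plate sets with planted actives.

    Neutral compounds respond at their mode's reference-control level.
    Planted actives respond at threshold + active_margin * window, i.e. they
    exceed the 50%-of-control rule in expectation.  If ground truth carries a
    dual compound (a planted signature reverser), it is additionally planted
    as a reverser-mode active.
    """
    rng = _rng(cfg, _STAGE_SCREEN)
    n_rep = cfg.screen_replicates
    sd = cfg.screen_noise_sd
    pool = [c for c in compounds]
    dual = truth.dual_compound if truth is not None else None
    sig_reversers = truth.reverser_compound_ids if truth is not None else set()
    neutral_pool = [c for c in pool if c not in sig_reversers]
    counts = {
        "basal_agonist": cfg.n_basal_actives,
        "sensitiser": cfg.n_sensitiser_actives,
        "reverser": cfg.n_reverser_actives,
    }
    chosen: dict[str, list[str]] = {}
    avail = list(neutral_pool)
    for mode in ("basal_agonist", "sensitiser", "reverser"):
        k = min(counts[mode], len(avail))
        picked = sorted(rng.choice(avail, size=k, replace=False).tolist()) if k else []
        avail = [c for c in avail if c not in picked]
        chosen[mode] = picked
    if dual is not None and dual in pool:
        chosen["reverser"] = sorted(set(chosen["reverser"]) | {dual})

    plates: dict[str, ScreenPlate] = {}
    for mode in ("basal_agonist", "sensitiser", "reverser"):
        ref = CONTROL_MEANS[_MODE_REFERENCE[mode]]
        ins100 = CONTROL_MEANS["insulin_100nM"]
        threshold = ref + 0.5 * (ins100 - ref)
        window = ins100 - ref
        controls = {
            name: np.clip(CONTROL_MEANS[name] + sd * rng.standard_normal(n_rep), 0, None)
            for name in ("basal", "insulin_1nM", "insulin_100nM", "insulin_palmitate")
        }
        wells: dict[str, np.ndarray] = {}
        for c in pool:
            mean = threshold + cfg.active_margin * window if c in chosen[mode] else ref
            wells[c] = np.clip(mean + sd * rng.standard_normal(n_rep), 0, None)
            if truth is not None and c in chosen[mode]:
                truth.screen_active_map[c] = (mode, cfg.active_margin)
        plates[mode] = ScreenPlate(mode=mode, controls=controls, compounds=wells)
    return plates


def simulate_all(cfg: SimConfig):
    """Run every generator stage in order; returns (geno, proteome, truth, gtt, body, db, plates)."""
    geno = simulate_genotypes(cfg)
    proteome, truth = simulate_proteome(cfg, geno)
    records, body = simulate_gtt(cfg, truth)
    universe = list(truth.complete_values.columns)
    targets = sorted(truth.causal_effects)
    db = simulate_signature_db(cfg, universe, targets, truth)
    plates = simulate_screen(cfg, db.compounds, truth)
    return geno, proteome, truth, records, body, db, plates
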