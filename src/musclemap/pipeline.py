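"""Pipeline driver: simulate -> phenotype -> associate -> mapqtl ->
fingerprint -> connect -> screen -> integrate.

Stages communicate through flat TSV artifacts in the output directory, so any
stage can be re-run in isolation or fed real data in the same formats.  A
stage whose outputs already exist is skipped unless ``force`` is set; the
frozen configuration (JSON echo) and a short hash of it are stamped into
every artifact's header comment together with the seed, so a result file is
traceable to the run that made it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssociationModelSpec, run_association_scan
from .enrichment import SignatureDB, connectivity_score, connectivity_table
from .fingerprint import build_fingerprint, export_query_set
from .io import (config_hash, header_comment, read_gmt, read_matrix_tsv,
                 read_table_tsv, write_gmt, write_matrix_tsv, write_table_tsv)
from .phenotypes import (BodyComposition, GTTRecord, ProteinMatrix,
                         normalise_proteome, phenotype_table, presence_filter,
                         coefficient_of_variation)
from .qtl import ScanConfig, map_pqtl
from .screen import (ScreenPlate, build_score_matrix, call_hits,
                     overlap_summary, rank_compounds)
from .simulate import SimConfig, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

FRACTIONS = ("mito", "pmf")
MODES = ("basal_agonist", "sensitiser", "reverser")


@dataclass
class PipelineConfig:
    """Every stage parameter of a pipeline run, in one frozen document."""

    outdir: str = "musclemap_run"
    sim: SimConfig = field(default_factory=SimConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    q_threshold: float = 0.05
    trait_transform: str = "log2"
    covariates: tuple[str, ...] = ("adiposity",)
    min_presence: float = 0.5
    weight_exponent_connectivity: float = 0.0
    cmap_sign: str = "reversal-positive"
    basal_rule: str = "response"
    exclude_baseline_from_mean: bool = False
    top_k: int = 20
    force: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(d["sim"]) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            d["sim"] = SimConfig(**d["sim"])
        if "scan" in d and isinstance(d["scan"], dict):
            scan_known = {f.name for f in dataclasses.fields(ScanConfig)}
            bad = set(d["scan"]) - scan_known
            if bad:
                raise ValueError(f"unknown scan config keys: {sorted(bad)}")
            d["scan"] = ScanConfig(**d["scan"])
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            sim=dataclasses.replace(self.sim, seed=seed),
            scan=dataclasses.replace(self.scan, seed=seed),
        )


class _Run:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        # hash the scientific parameters only: where the artifacts live and
        # whether stages were forced must not change their content stamp
        params = {k: v for k, v in cfg.to_dict().items() if k not in ("outdir", "force")}
        self.hash = config_hash(params)
        self.comment = header_comment(__version__, self.hash, cfg.sim.seed)
        payload = json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n"
        echo = self.out / "config_echo.json"
        if not echo.exists() or echo.read_text(encoding="utf-8") != payload:
            echo.write_text(payload, encoding="utf-8")

    def path(self, name: str) -> Path:
        return self.out / name

    def done(self, *names: str) -> bool:
        return all(self.path(n).exists() for n in names)


# ---------------------------------------------------------------- stages

def stage_simulate(run: _Run) -> None:
    cfg = run.cfg
    geno, proteome, truth, records, body, db, plates = simulate_all(cfg.sim)
    write_matrix_tsv(run.path("genotypes.tsv"), geno.dosages.T, run.comment)
    write_table_tsv(run.path("markers.tsv"), geno.marker_map, run.comment)
    for fr in FRACTIONS:
        write_matrix_tsv(run.path(f"proteome_{fr}.tsv"), proteome[fr].values.T, run.comment)
    positions = pd.concat([proteome[fr].positions.assign(fraction=fr) for fr in FRACTIONS])
    write_table_tsv(run.path("proteins.tsv"), positions, run.comment)

    rows = []
    for r in records:
        ins = dict(zip(r.insulin_times, r.insulin_values))
        for t, g in zip(r.glucose_times, r.glucose_values):
            rows.append({"mouse_id": r.mouse_id, "time_min": t, "glucose": g,
                         "insulin": ins.get(t, np.nan)})
    write_table_tsv(run.path("gtt.tsv"), pd.DataFrame(rows).set_index("mouse_id"), run.comment)
    write_table_tsv(
        run.path("bodycomp.tsv"),
        pd.DataFrame([b.__dict__ for b in body]).set_index("mouse_id"),
        run.comment,
    )

    sig_rows = []
    for (compound, line), genes in sorted(db.rankings.items()):
        for rank, gene in enumerate(genes, start=1):
            sig_rows.append((compound, line, gene, rank))
    write_table_tsv(
        run.path("signatures.tsv"),
        pd.DataFrame(sig_rows, columns=["compound", "cell_line", "gene", "rank"]).set_index("compound"),
        run.comment,
    )

    for mode, plate in plates.items():
        rows = []
        for name, vals in plate.controls.items():
            rows.append({"id": name, "role": "control",
                         **{f"rep{i + 1}": v for i, v in enumerate(vals)}})
        for name, vals in plate.compounds.items():
            rows.append({"id": name, "role": "compound",
                         **{f"rep{i + 1}": v for i, v in enumerate(vals)}})
        write_table_tsv(run.path(f"screen_{mode}.tsv"), pd.DataFrame(rows).set_index("id"), run.comment)

    with open(run.path("truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_gtt(run: _Run) -> list[GTTRecord]:
    df = read_table_tsv(run.path("gtt.tsv")).reset_index()
    records = []
    for mouse, grp in df.groupby("mouse_id", sort=True):
        grp = grp.sort_values("time_min")
        ins = grp.dropna(subset=["insulin"])
        records.append(GTTRecord(
            mouse_id=str(mouse),
            glucose_times=tuple(grp["time_min"]),
            glucose_values=tuple(grp["glucose"]),
            insulin_times=tuple(ins["time_min"]),
            insulin_values=tuple(ins["insulin"]),
        ))
    return records


def _load_proteome(run: _Run, fraction: str) -> ProteinMatrix:
    values = read_matrix_tsv(run.path(f"proteome_{fraction}.tsv"), orientation="columns")
    positions = read_table_tsv(run.path("proteins.tsv"))
    positions = positions[positions["fraction"] == fraction][["chrom", "pos_bp"]]
    return ProteinMatrix(values=values, fraction=fraction, positions=positions)


def stage_phenotype(run: _Run) -> None:
    records = _load_gtt(run)
    body_df = read_table_tsv(run.path("bodycomp.tsv")).reset_index()
    body = [BodyComposition(str(r.mouse_id), r.fat_mass, r.lean_mass, r.body_mass)
            for r in body_df.itertuples()]
    pheno = phenotype_table(records, body, run.cfg.exclude_baseline_from_mean)
    write_table_tsv(run.path("phenotypes.tsv"), pheno, run.comment)

    stats = []
    for fr in FRACTIONS:
        pm = _load_proteome(run, fr)
        cv = coefficient_of_variation(pm)
        cv["presence"] = pm.presence_fraction()
        cv["fraction"] = fr
        stats.append(cv)
    write_table_tsv(run.path("protein_stats.tsv"), pd.concat(stats), run.comment)


def _prepared_proteome(run: _Run, fraction: str) -> ProteinMatrix:
    pm = _load_proteome(run, fraction)
    pm = presence_filter(pm, run.cfg.min_presence)
    return normalise_proteome(pm)  # simulated values are already log2


def stage_associate(run: _Run) -> None:
    pheno = read_table_tsv(run.path("phenotypes.tsv"))
    spec = AssociationModelSpec(trait_transform=run.cfg.trait_transform,
                                covariates=run.cfg.covariates,
                                q_threshold=run.cfg.q_threshold)
    spec_nocov = dataclasses.replace(spec, covariates=())
    for fr in FRACTIONS:
        pm = _prepared_proteome(run, fr)
        res = run_association_scan(pm, pheno, spec)
        res["fraction"] = fr
        write_table_tsv(run.path(f"associations_{fr}.tsv"), res, run.comment)
        res0 = run_association_scan(pm, pheno, spec_nocov)
        res0["fraction"] = fr
        write_table_tsv(run.path(f"associations_{fr}_nocov.tsv"), res0, run.comment)


def stage_mapqtl(run: _Run) -> None:
    G = read_matrix_tsv(run.path("genotypes.tsv"), orientation="columns")
    marker_map = read_table_tsv(run.path("markers.tsv"))
    results = []
    for fr in FRACTIONS:
        pm = _prepared_proteome(run, fr)
        res = map_pqtl(pm, G, marker_map, run.cfg.scan)
        res["fraction"] = fr
        results.append(res)
    write_table_tsv(run.path("pqtl.tsv"), pd.concat(results), run.comment)


def stage_fingerprint(run: _Run) -> None:
    assoc = pd.concat([read_table_tsv(run.path(f"associations_{fr}.tsv")) for fr in FRACTIONS])
    pqtl = read_table_tsv(run.path("pqtl.tsv"))
    fp = build_fingerprint(assoc, pqtl, run.cfg.q_threshold)
    # invariants asserted on every run
    assert all(fp.entries["effect_size"] < 0) and all(fp.entries["q_value"] < run.cfg.q_threshold)
    assert set(fp.entries.index) <= set(pqtl.index[pqtl["classification"] == "cis"])
    write_table_tsv(run.path("fingerprint.tsv"), fp.entries, run.comment)
    if len(fp):
        line = export_query_set(fp)
        name, desc, *genes = line.split("\t")
        write_gmt(run.path("fingerprint.gmt"), [{"name": name, "description": desc, "genes": genes}])
    else:
        write_gmt(run.path("fingerprint.gmt"), [])


def _load_signature_db(run: _Run) -> SignatureDB:
    df = read_table_tsv(run.path("signatures.tsv")).reset_index()
    rankings = {}
    universe: set[str] = set()
    for (compound, line), grp in df.groupby(["compound", "cell_line"], sort=True):
        genes = tuple(grp.sort_values("rank")["gene"])
        rankings[(str(compound), str(line))] = genes
        universe.update(genes)
    return SignatureDB(rankings=rankings, universe=tuple(sorted(universe)))


def stage_connect(run: _Run) -> None:
    sets = read_gmt(run.path("fingerprint.gmt"))
    if not sets:
        raise RuntimeError("fingerprint.gmt is empty; nothing to query")
    query = set(sets[0]["genes"])
    db = _load_signature_db(run)
    results = connectivity_score(db, query, run.cfg.weight_exponent_connectivity)
    write_table_tsv(run.path("connectivity.tsv"), connectivity_table(results), run.comment)


def _load_plate(run: _Run, mode: str) -> ScreenPlate:
    df = read_table_tsv(run.path(f"screen_{mode}.tsv")).reset_index()
    reps = [c for c in df.columns if c.startswith("rep")]
    controls = {str(r.id): np.array([getattr(r, c) for c in reps])
                for r in df[df["role"] == "control"].itertuples()}
    compounds = {str(r.id): np.array([getattr(r, c) for c in reps])
                 for r in df[df["role"] == "compound"].itertuples()}
    return ScreenPlate(mode=mode, controls=controls, compounds=compounds)


def stage_screen(run: _Run) -> None:
    calls = {}
    for mode in MODES:
        plate = _load_plate(run, mode)
        hc = call_hits(plate, run.cfg.basal_rule)
        calls[mode] = hc
        write_table_tsv(run.path(f"hits_{mode}.tsv"), hc.table, run.comment)
    with open(run.path("hit_overlap.json"), "w", encoding="utf-8") as fh:
        json.dump(overlap_summary(calls), fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_integrate(run: _Run) -> None:
    responses = pd.DataFrame({
        mode: read_table_tsv(run.path(f"hits_{mode}.tsv"))["mean_response"]
        for mode in MODES
    })
    conn = read_table_tsv(run.path("connectivity.tsv"))["raw_score"]
    score = build_score_matrix(responses, conn, run.cfg.cmap_sign)
    ranked = rank_compounds(score)
    write_table_tsv(run.path("score_matrix.tsv"), ranked, run.comment)
    write_table_tsv(run.path(f"top{run.cfg.top_k}.tsv"), ranked.head(run.cfg.top_k), run.comment)


STAGES: dict[str, tuple] = {
    # name -> (fn, output artifacts used for skip detection)
    "simulate": (stage_simulate, ("genotypes.tsv", "markers.tsv", "proteome_mito.tsv",
                                  "proteome_pmf.tsv", "gtt.tsv", "bodycomp.tsv",
                                  "signatures.tsv", "truth.json")),
    "phenotype": (stage_phenotype, ("phenotypes.tsv", "protein_stats.tsv")),
    "associate": (stage_associate, ("associations_mito.tsv", "associations_pmf.tsv")),
    "mapqtl": (stage_mapqtl, ("pqtl.tsv",)),
    "fingerprint": (stage_fingerprint, ("fingerprint.tsv", "fingerprint.gmt")),
    "connect": (stage_connect, ("connectivity.tsv",)),
    "screen": (stage_screen, ("hits_basal_agonist.tsv", "hits_sensitiser.tsv",
                              "hits_reverser.tsv")),
    "integrate": (stage_integrate, ("score_matrix.tsv",)),
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all) and return the output directory."""
    run = _Run(cfg)
    root = logging.getLogger("musclemap")
    handler = logging.FileHandler(run.out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root.addHandler(handler)
    try:
        logger.info("run start seed=%d config=%s version=%s", cfg.sim.seed, run.hash, __version__)
        for name in stages or list(STAGES):
            fn, outputs = STAGES[name]
            if not cfg.force and run.done(*outputs):
                logger.info("stage=%s skipped (outputs present)", name)
                continue
            logger.info("stage=%s running", name)
            fn(run)
    finally:
        root.removeHandler(handler)
        handler.close()
    return run.out
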