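"""End-to-end driver: simulate -> qc -> index -> gwas -> wish -> dwire -> annot.

Each stage consumes only prior stage outputs and appends one entry to the
run manifest (counts, thresholds, settings), so a finished manifest is a
complete audit of the run.  All stages are also usable standalone on files
through :mod:`wishnet.cli`.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annot as annot_mod
from . import dwire as dwire_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import wish as wish_mod
from .index import (DEFAULT_WEIGHTS, IndexCoefficients, SelectionIndexSpec,
                    index_coefficients, obesity_index, select_extremes)
from .qc import run_qc
from .simdata import SimConfig, SimOutput, simulate_cross, synthetic_annotation

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


DEFAULTS = {
    "qc": {"enabled": True, "sample_max_missing": 0.05, "ibs_max": 0.95,
           "marker_max_missing": 0.05, "min_maf": 0.05, "hwe_alpha": 1e-5,
           "hwe_test": "exact"},
    "gwas": {},
    "wish": {"p_max": 0.05, "top_n": 2500, "k_norm_min": 0.12,
             "gamma": 5, "fit_gamma": False, "min_module_size": 50,
             "cut_quantile": 0.99, "extremes": {"low": 25, "mid": 25, "high": 25},
             "p_oi_max": 0.001, "mtr_other_min": 0.4},
    "dwire": {"n_extreme": 50, "threshold": 0.6, "snp_set": "full"},
    "annot": {"enabled": True, "flank_bp": 20_000, "bed": None, "gmt": None},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)  # None -> real inputs
    inputs: dict = field(default_factory=dict)  # paths when not simulating
    qc: dict = field(default_factory=dict)
    index: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)
    wish: dict = field(default_factory=dict)
    dwire: dict = field(default_factory=dict)
    annot: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        out = {"seed": self.seed, "simulate": self.simulate, "inputs": self.inputs,
               "index": {"weights": self.index.get("weights", DEFAULT_WEIGHTS)}}
        for stage in ("qc", "gwas", "wish", "dwire", "annot"):
            out[stage] = {**DEFAULTS[stage], **getattr(self, stage)}
        return out


def load_config(path) -> PipelineConfig:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    manifest: dict
    sim: SimOutput | None = None
    genotypes = None
    qc_report = None
    coefficients: IndexCoefficients | None = None
    oi: pd.Series | None = None
    gwas: gwas_mod.GwasResult | None = None
    network_genotypes = None
    scale_free: pd.DataFrame | None = None
    modules: wish_mod.ModuleSet | None = None
    gmat: wish_mod.Gmat | None = None
    selected_modules: list = field(default_factory=list)
    dwire: dwire_mod.DwResult | None = None
    snp_genes: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"].append({"stage": name, **info})


def run_pipeline(config: PipelineConfig | None = None,
                 outdir=None) -> PipelineResult:
    """Run every stage in order; returns all in-memory stage outputs.

    With ``outdir`` set, each stage additionally writes its flat-file
    outputs there, including the manifest.
    """
    config = config or PipelineConfig()
    cfg = config.resolved()
    manifest = {
        "tool": "wishnet",
        "version": _version(),
        "seed": cfg["seed"],
        "config": _jsonable(cfg),
        "started": datetime.datetime.now().isoformat(timespec="seconds"),
        "stages": [],
    }
    res = PipelineResult(manifest=manifest)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        # -- simulate or load ------------------------------------------------
        if cfg["simulate"] is not None:
            sim_cfg = SimConfig(**{**cfg["simulate"], "seed": cfg["seed"]})
            sim = simulate_cross(sim_cfg)
            res.sim = sim
            genotypes, traits = sim.genotypes, sim.traits
            spec_traits = sim_cfg.traits
            _stage(manifest, stage, n_animals=genotypes.n_animals,
                   n_markers=genotypes.n_markers,
                   missing_rate=float(genotypes.missing_mask.mean()))
            if out is not None:
                io_mod.write_dosage_tsv(genotypes, out / "genotypes.tsv")
                io_mod.write_map(genotypes.gmap, out / "markers.map")
                io_mod.write_traits(traits, out / "traits.tsv")
                sim.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
                io_mod.write_covariance(spec_traits.P, spec_traits.names,
                                        out / "P.tsv")
                io_mod.write_covariance(spec_traits.G, spec_traits.names,
                                        out / "G.tsv")
        else:
            inputs = cfg["inputs"]
            genotypes = io_mod.read_genotypes(
                inputs["genotypes"], inputs.get("dialect", "dosage_tsv"),
                inputs.get("map"))
            traits = io_mod.read_traits(inputs["traits"])
            P, namesP = io_mod.read_covariance(inputs["P"])
            G, namesG = io_mod.read_covariance(inputs["G"])
            if namesP != namesG:
                raise ValueError("P and G trait names differ")
            spec_traits = None
            _stage(manifest, stage, n_animals=genotypes.n_animals,
                   n_markers=genotypes.n_markers, source="files")

        # -- qc --------------------------------------------------------------
        stage = "qc"
        qc_cfg = cfg["qc"]
        if qc_cfg["enabled"]:
            genotypes, report = run_qc(
                genotypes, qc_cfg["sample_max_missing"], qc_cfg["ibs_max"],
                qc_cfg["marker_max_missing"], qc_cfg["min_maf"],
                qc_cfg["hwe_alpha"], qc_cfg["hwe_test"])
            res.qc_report = report
            _stage(manifest, stage, n_animals=genotypes.n_animals,
                   n_markers=genotypes.n_markers,
                   removed=report.counts_by_rule().to_dict(),
                   thresholds=report.thresholds)
            if out is not None:
                report.to_tsv(out / "qc_exclusions.tsv")
                io_mod.write_dosage_tsv(genotypes, out / "genotypes_qc.tsv")
        else:
            _stage(manifest, stage, skipped=True)
        res.genotypes = genotypes

        # -- obesity index ---------------------------------------------------
        stage = "index"
        weights = cfg["index"]["weights"]
        trait_names = list(weights)
        if cfg["simulate"] is not None:
            names = list(spec_traits.names)
            sel = [names.index(t) for t in trait_names]
            P = spec_traits.P[np.ix_(sel, sel)]
            G = spec_traits.G[np.ix_(sel, sel)]
        else:
            sel = [namesP.index(t) for t in trait_names]
            P = P[np.ix_(sel, sel)]
            G = G[np.ix_(sel, sel)]
        spec = SelectionIndexSpec(tuple(trait_names), P, G,
                                  np.array([weights[t] for t in trait_names]))
        coef = index_coefficients(spec)
        oi, omitted = obesity_index(coef, traits)
        res.coefficients, res.oi = coef, oi
        _stage(manifest, stage, n_animals=len(oi), omitted=len(omitted),
               oi_mean=float(oi.mean()), oi_sd=float(oi.std(ddof=1)),
               b=dict(zip(trait_names, map(float, coef.b))))
        if out is not None:
            io_mod.write_oi(oi, out / "oi.tsv")
            coef.as_series().to_csv(out / "index_coefficients.tsv", sep="\t")

        # -- gwas ------------------------------------------------------------
        stage = "gwas"
        scan = gwas_mod.scan(oi, genotypes)
        res.gwas = scan
        n_sugg = int((scan.table["p"] < scan.threshold("suggestive")).sum())
        n_high = int((scan.table["p"] < scan.threshold("high")).sum())
        _stage(manifest, stage, n_markers=scan.n_markers,
               thresholds={k: float(v) for k, v in scan.thresholds.items()},
               n_suggestive=n_sugg, n_high=n_high)
        if out is not None:
            scan.manhattan_frame().to_csv(out / "gwas.tsv", sep="\t",
                                          index=False, float_format="%.6e")

        # -- wish network ----------------------------------------------------
        stage = "wish"
        wcfg = cfg["wish"]
        extremes = select_extremes(oi, wcfg["extremes"])
        network_animals = [a for grp in extremes.values() for a in grp]
        net_g, meta = wish_mod.preselect_snps(
            scan, genotypes, network_animals, wcfg["p_max"], wcfg["top_n"],
            wcfg["k_norm_min"])
        res.network_genotypes = net_g
        gamma = wcfg["gamma"]
        sf_table = None
        if wcfg["fit_gamma"] and net_g.n_markers >= 50:
            sf_table, fitted = wish_mod.scale_free_fit(net_g)
            if fitted is not None:
                gamma = fitted
        res.scale_free = sf_table
        adj = wish_mod.adjacency(net_g, gamma)
        t = wish_mod.tom(adj)
        modules = wish_mod.detect_modules(1.0 - t, net_g.marker_ids,
                                          wcfg["min_module_size"],
                                          wcfg["cut_quantile"])
        if modules.module_labels:
            modules = wish_mod.eigensnp(net_g, modules)
            trait_cols = _other_trait_columns(traits, trait_names)
            tdf = traits.set_index("animal_id")[trait_cols] \
                if "animal_id" in traits.columns else traits[trait_cols]
            tdf = tdf.copy()
            tdf.insert(0, "OI", oi)
            gm = wish_mod.gmat(modules.eigensnps, tdf)
            selected = wish_mod.select_modules(gm, wcfg["p_oi_max"],
                                               wcfg["mtr_other_min"])
        else:
            gm, selected = None, []
        res.modules, res.gmat, res.selected_modules = modules, gm, selected
        _stage(manifest, stage, preselect=meta, gamma=gamma,
               n_modules=len(modules.module_labels),
               module_sizes=modules.sizes(),
               var_explained=modules.var_explained,
               selected_modules=selected,
               rules={"p_oi_max": wcfg["p_oi_max"],
                      "mtr_other_min": wcfg["mtr_other_min"]})
        if out is not None:
            modules.assignment_frame().to_csv(out / "modules.tsv", sep="\t",
                                              index=False)
            if modules.eigensnps is not None:
                modules.eigensnps.to_csv(out / "eigensnps.tsv", sep="\t",
                                         float_format="%.6g")
            if gm is not None:
                gm.to_frame().to_csv(out / "gmat.tsv", sep="\t",
                                     float_format="%.6e")
            if sf_table is not None:
                sf_table.to_csv(out / "scale_free_fit.tsv", sep="\t",
                                index=False, float_format="%.6g")

        # -- differential wiring --------------------------------------------
        stage = "dwire"
        dcfg = cfg["dwire"]
        grp = select_extremes(oi, {"lean": dcfg["n_extreme"],
                                   "obese": dcfg["n_extreme"]})
        dw_g = net_g if dcfg["snp_set"] == "wish" else genotypes
        dw = dwire_mod.run_dwire(dw_g, grp["lean"], grp["obese"],
                                 dcfg["threshold"])
        res.dwire = dw
        _stage(manifest, stage, n_snps=len(dw.table), threshold=dw.threshold,
               n_selected=int(dw.table["selected"].sum()),
               snp_set=dcfg["snp_set"], n_lean=dw.n_lean, n_obese=dw.n_obese)
        if out is not None:
            dw.table.to_csv(out / "dwire.tsv", sep="\t", index=False,
                            float_format="%.6g")

        # -- annotation and enrichment --------------------------------------
        stage = "annot"
        acfg = cfg["annot"]
        if acfg["enabled"]:
            res_annot = _run_annot(acfg, cfg, res, genotypes, manifest)
            if out is not None and res.enrichment is not None:
                res.snp_genes.to_csv(out / "snp_genes.tsv", sep="\t", index=False)
                res.enrichment.to_csv(out / "enrichment.tsv", sep="\t",
                                      index=False, float_format="%.6e")
            if not res_annot:
                _stage(manifest, stage, skipped=True,
                       reason="no annotation inputs available")
        else:
            _stage(manifest, stage, skipped=True)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["failed_stage"] = stage
        raise StageError(stage, manifest, exc) from exc

    manifest["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
    if out is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2)
    return res


def _run_annot(acfg, cfg, res: PipelineResult, genotypes, manifest) -> bool:
    if acfg["bed"] is not None:
        annotation = annot_mod.read_bed(acfg["bed"])
        gene_sets = annot_mod.read_gmt(acfg["gmt"]) if acfg["gmt"] else {}
    elif res.sim is not None:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg["seed"], 97]).generate_state(1)[0])
        genes, gene_sets = synthetic_annotation(res.sim.genotypes.gmap,
                                                res.sim.causal, rng)
        annotation = annot_mod.GeneAnnotation(genes)
    else:
        return False
    markers = genotypes.gmap.to_frame()
    mapping = annot_mod.map_snps_to_genes(markers, annotation, acfg["flank_bp"])
    res.snp_genes = mapping
    background = sorted(mapping["gene"].dropna().unique())
    query_markers: set = set()
    if res.modules is not None:
        for lab in res.selected_modules:
            query_markers |= set(res.modules.members(int(lab.lstrip("M"))))
    if res.gwas is not None:
        hits = gwas_mod.significant_markers(res.gwas, "high")
        query_markers |= set(hits["marker"])
    query = sorted(mapping[mapping["marker"].isin(query_markers)]["gene"]
                   .dropna().unique())
    if gene_sets and background:
        res.enrichment = annot_mod.fisher_enrichment(query, gene_sets, background)
        top = res.enrichment.iloc[0] if len(res.enrichment) else None
        _stage(manifest, "annot", n_genes=len(background),
               n_query_genes=len(query), n_sets=len(res.enrichment),
               flank_bp=acfg["flank_bp"],
               top_set=None if top is None else str(top["gene_set"]))
    else:
        _stage(manifest, "annot", n_genes=len(background),
               n_query_genes=len(query), n_sets=0, flank_bp=acfg["flank_bp"])
    return True


def _other_trait_columns(traits: pd.DataFrame, index_traits) -> list:
    """EBV columns of every recorded trait outside the index roster."""
    out = []
    for c in traits.columns:
        if c.endswith("_ebv") and c[:-4] not in index_traits:
            out.append(c)
    return out


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("wishnet")
    except Exception:
        return "unknown"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
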