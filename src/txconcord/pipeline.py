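"""Config-driven orchestration of the full concordance workflow.

Stage order: reference DE -> model-contrast DE -> concordance labelling ->
exclusion/residual subsetting -> ORA and GSEA -> report tables and plots.
Every run writes a JSON manifest carrying the config hash, seed and
stage-by-stage bookkeeping counts; plots are rendered from the serialized
tables, never from in-memory state, so reports can be regenerated without
re-running statistics.
"""
from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import LABELS, ConcordanceAnalysis
from .diffexp import NegativeBinomialDE
from .enrichment import gsea, gsea_from_counts, lollipop_table, ora, rank_genes, zscore_rows
from .exceptions import PipelineError, ValidationError
from .io import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    SampleSheet,
    map_gene_ids,
    read_count_matrix,
    read_gmt,
    read_id_map,
    read_sample_sheet,
    write_count_matrix,
    write_gmt,
)
from .simulate import SimulationConfig, preset, simulate_study

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

_SCHEMA = {
    "seed": None,
    "synthetic": {"preset", "overrides"},
    "inputs": {
        "reference_counts", "reference_sheet", "model_counts", "model_sheet",
        "id_map", "collections",
    },
    "contrasts": {"reference", "model"},
    "thresholds": {"p_adj_max", "abs_log2fc_min"},
    "enrichment": {"min_overlap", "gsea_B", "permutation", "weight_exponent",
                   "min_size", "metric"},
    "plots": None,
}

_DEFAULT_CONTRASTS = {
    "reference": {"a": "CTL", "b": "ASD", "direction_label": "case_vs_control"},
    "model": [
        {"a": "NM", "b": "NTr", "direction_label": "case_vs_control"},
        {"a": "NM", "b": "NUntr", "direction_label": "case_vs_control"},
        {"a": "NUntr", "b": "NTr", "direction_label": "case_vs_control"},
    ],
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    raw: dict
    seed: int
    synthetic: dict | None
    inputs: dict | None
    contrasts: dict
    thresholds: dict
    enrichment: dict
    plots: bool = True

    @classmethod
    def from_dict(cls, cfg: dict, seed: int | None = None) -> "RunConfig":
        unknown = set(cfg) - set(_SCHEMA)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key, allowed in _SCHEMA.items():
            if allowed and key in cfg and isinstance(cfg[key], dict):
                extra = set(cfg[key]) - allowed
                if extra:
                    raise ValidationError(f"unknown keys under {key!r}: {sorted(extra)}")
        if seed is None:
            seed = cfg.get("seed")
        if seed is None:
            raise ValidationError("a seed is required (config key 'seed' or --seed)")
        synthetic = cfg.get("synthetic")
        inputs = cfg.get("inputs")
        if (synthetic is None) == (inputs is None):
            raise ValidationError("config needs exactly one of 'synthetic' or 'inputs'")
        contrasts = cfg.get("contrasts") or (_DEFAULT_CONTRASTS if synthetic else None)
        if contrasts is None or not contrasts.get("reference"):
            raise ValidationError("missing config section: contrasts.reference")
        if not contrasts.get("model"):
            raise ValidationError("missing config section: contrasts.model")
        thresholds = {"p_adj_max": 0.05, "abs_log2fc_min": 0.2}
        thresholds.update(cfg.get("thresholds") or {})
        enrichment = {
            "min_overlap": 1, "gsea_B": 200, "permutation": "gene_set",
            "weight_exponent": 1.0, "min_size": 2, "metric": "signed_stat",
        }
        enrichment.update(cfg.get("enrichment") or {})
        return cls(
            raw=cfg,
            seed=int(seed),
            synthetic=synthetic,
            inputs=inputs,
            contrasts=contrasts,
            thresholds=thresholds,
            enrichment=enrichment,
            plots=bool(cfg.get("plots", True)),
        )

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ValidationError(f"config {path} is not a mapping")
        return cls.from_dict(cfg, seed=seed)

    def config_hash(self) -> str:
        canon = dict(self.raw)
        canon["seed"] = self.seed
        blob = json.dumps(canon, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunResult:
    out_dir: Path
    manifest: dict


def _load_inputs(cfg: RunConfig, out_inputs: Path):
    """Materialise study data either from the synthetic generator or from files.

    Synthetic inputs are also written to ``out_inputs`` so every run is
    traceable to concrete files.
    """
    if cfg.synthetic is not None:
        name = cfg.synthetic.get("preset", "demo")
        overrides = dict(cfg.synthetic.get("overrides") or {})
        sim_cfg = preset(name, seed=cfg.seed, **overrides)
        study = simulate_study(sim_cfg)
        out_inputs.mkdir(parents=True, exist_ok=True)
        write_count_matrix(study.reference_counts, out_inputs / "reference_counts.tsv")
        study.reference_sheet.to_tsv(out_inputs / "reference_sheet.tsv")
        write_count_matrix(study.model_counts, out_inputs / "model_counts.tsv")
        study.model_sheet.to_tsv(out_inputs / "model_sheet.tsv")
        write_gmt(study.genesets, out_inputs / "genesets.gmt")
        study.truth.to_tsv(out_inputs / "truth.tsv")
        study.id_map.to_csv(out_inputs / "id_map.tsv", sep="\t", index=False, header=False)
        collections = {"synthetic": study.genesets}
        id_map = study.id_map if sim_cfg.emit_source_ids else None
        return (study.reference_counts, study.reference_sheet,
                study.model_counts, study.model_sheet, collections, id_map)

    inp = cfg.inputs
    for key in ("reference_counts", "reference_sheet", "model_counts",
                "model_sheet", "collections"):
        if key not in inp:
            raise ValidationError(f"missing config key: inputs.{key}")
        if key != "collections" and not Path(inp[key]).exists():
            raise ValidationError(f"inputs.{key}: no such file {inp[key]}")
    ref_cm = read_count_matrix(inp["reference_counts"])
    ref_sheet = read_sample_sheet(inp["reference_sheet"])
    mod_cm = read_count_matrix(inp["model_counts"])
    mod_sheet = read_sample_sheet(inp["model_sheet"])
    collections = {}
    for name, path in inp["collections"].items():
        if not Path(path).exists():
            raise ValidationError(f"inputs.collections.{name}: no such file {path}")
        collections[name] = read_gmt(path)
    id_map = read_id_map(inp["id_map"]) if inp.get("id_map") else None
    return ref_cm, ref_sheet, mod_cm, mod_sheet, collections, id_map


def run_pipeline(cfg: RunConfig, out_dir) -> RunResult:
    """Execute the full workflow, writing the output bundle under ``out_dir``.

    Any stage error aborts the run with :class:`PipelineError` naming the
    stage; partial outputs created by this run are removed.
    """
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stage = "setup"
    try:
        stage = "inputs"
        (ref_cm, ref_sheet, mod_cm, mod_sheet,
         collections, id_map) = _load_inputs(cfg, out / "inputs")
        manifest["stages"]["inputs"] = {
            "reference_genes_in": ref_cm.shape[0],
            "model_genes_in": mod_cm.shape[0],
            "collections": {k: len(v) for k, v in collections.items()},
        }

        stage = "id_mapping"
        if id_map is not None:
            ref_cm, ref_report = map_gene_ids(ref_cm, id_map)
            mod_cm, mod_report = map_gene_ids(mod_cm, id_map)
            manifest["stages"]["id_mapping"] = {
                "reference_mapped": ref_report.n_mapped,
                "reference_unmapped": ref_report.n_unmapped,
                "model_mapped": mod_report.n_mapped,
                "model_unmapped": mod_report.n_unmapped,
            }

        stage = "reference_de"
        (out / "contrasts").mkdir(exist_ok=True)
        rc = cfg.contrasts["reference"]
        ref_model = NegativeBinomialDE(ref_cm, ref_sheet)
        ref_res = ref_model.fit(rc["a"], rc["b"], direction_label=rc.get("direction_label"))
        ref_res.to_tsv(out / "contrasts" / "reference.tsv")
        ref_degs = ref_res.select_degs(
            p_adj_max=cfg.thresholds["p_adj_max"],
            abs_log2fc_min=cfg.thresholds["abs_log2fc_min"],
        )
        (out / "degs").mkdir(exist_ok=True)
        pd.DataFrame({"sign": ref_degs.signs}).to_csv(
            out / "degs" / "reference_degs.tsv", sep="\t", index_label="gene"
        )
        manifest["stages"]["reference_de"] = {
            "genes_tested": ref_res.genes_tested,
            "n_degs": len(ref_degs),
        }

        stage = "model_de"
        mod_model = NegativeBinomialDE(mod_cm, mod_sheet)
        model_results = {}
        for mc in cfg.contrasts["model"]:
            res = mod_model.fit(mc["a"], mc["b"], direction_label=mc.get("direction_label"))
            model_results[res.name] = res
            res.to_tsv(out / "contrasts" / f"{res.name}.tsv")
        manifest["stages"]["model_de"] = {
            name: {"genes_tested": r.genes_tested} for name, r in model_results.items()
        }

        stage = "concordance"
        analysis = ConcordanceAnalysis(
            ref_degs,
            model_results,
            p_adj_max=cfg.thresholds["p_adj_max"],
            abs_log2fc_min=cfg.thresholds["abs_log2fc_min"],
        )
        conc = analysis.fit()
        cdir = out / "concordance"
        cdir.mkdir(exist_ok=True)
        for name, table in conc.tables.items():
            table.to_tsv(cdir / f"{name}.tsv")
        pd.DataFrame(
            {
                "gene": sorted(conc.exclusion_sets.all_convergent)
                + sorted(conc.exclusion_sets.all_divergent),
                "set": ["all_convergent"] * len(conc.exclusion_sets.all_convergent)
                + ["all_divergent"] * len(conc.exclusion_sets.all_divergent),
            }
        ).to_csv(cdir / "exclusion_sets.tsv", sep="\t", index=False)
        residual_gmt = GeneSetCollection()
        for name, res in conc.residuals.items():
            for side, genes in (("convergent", res.convergent), ("divergent", res.divergent)):
                (cdir / f"residual_{name}_{side}.txt").write_text(
                    "\n".join(sorted(genes)) + ("\n" if genes else "")
                )
                if genes:
                    residual_gmt.add(
                        GeneSet(f"{name}__{side}", "residual concordance set",
                                tuple(sorted(genes)))
                    )
        if len(residual_gmt):
            write_gmt(residual_gmt, cdir / "residual_sets.gmt")
        summary = conc.summary()
        summary.to_csv(cdir / "summary.tsv", sep="\t", float_format=FLOAT_FMT)
        stage_counts = {}
        for name, table in conc.tables.items():
            counts = {lab: int((table.frame["label"] == lab).sum()) for lab in LABELS}
            if sum(counts.values()) != len(ref_degs):
                raise PipelineError(
                    "concordance",
                    f"label counts for {name} do not sum to the DEG count",
                )
            stage_counts[name] = counts
        manifest["stages"]["concordance"] = stage_counts

        stage = "enrichment"
        edir = out / "enrichment"
        edir.mkdir(exist_ok=True)
        enr = cfg.enrichment
        ora_frames = {}
        for name, res in conc.residuals.items():
            universe = set(
                model_results[name].frame.index[model_results[name].frame["pvalue"].notna()]
            )
            for cname, coll in collections.items():
                sides = {}
                for side, genes in (("convergent", res.convergent),
                                    ("divergent", res.divergent)):
                    if not genes:
                        logger.info("ORA skipped: empty %s residual for %s", side, name)
                        continue
                    frame = ora(genes, universe, coll,
                                min_overlap=enr["min_overlap"], tag=side)
                    frame.to_csv(edir / f"ora_{cname}_{name}_{side}.tsv",
                                 sep="\t", float_format=FLOAT_FMT)
                    sides[side] = frame
                lolli = lollipop_table(sides.get("convergent"), sides.get("divergent"))
                lolli.to_csv(edir / f"lollipop_{cname}_{name}.tsv", sep="\t",
                             index=False, float_format=FLOAT_FMT)
                ora_frames[(cname, name)] = sides
        gsea_retained = {}
        for name, res_ in model_results.items():
            for cname, coll in collections.items():
                if enr["permutation"] == "phenotype":
                    mc = next(c for c in cfg.contrasts["model"]
                              if f"{c['b']}_vs_{c['a']}" == name)
                    frame = gsea_from_counts(
                        mod_cm, mod_sheet, mc["a"], mc["b"], coll,
                        B=enr["gsea_B"], permutation="phenotype", seed=cfg.seed,
                        weight_exponent=enr["weight_exponent"], min_size=enr["min_size"],
                    )
                else:
                    ranked = rank_genes(res_, metric=enr["metric"])
                    frame = gsea(ranked, coll, B=enr["gsea_B"], seed=cfg.seed,
                                 weight_exponent=enr["weight_exponent"],
                                 min_size=enr["min_size"])
                frame.to_csv(edir / f"gsea_{cname}_{name}.tsv", sep="\t",
                             float_format=FLOAT_FMT)
                gsea_retained[f"{cname}/{name}"] = int((frame["p_adjust"] < 0.05).sum())
        manifest["stages"]["enrichment"] = {"gsea_sets_retained": gsea_retained}

        stage = "report"
        rdir = out / "report"
        rdir.mkdir(exist_ok=True)
        if len(ref_degs):
            from .diffexp import estimate_size_factors

            sf = estimate_size_factors(mod_cm, pseudo_reference=True)
            norm = mod_cm.data / sf
            deg_in_model = [g for g in ref_degs.genes if g in norm.index]
            if deg_in_model:
                z = zscore_rows(norm, deg_in_model)
                z.to_csv(rdir / "zscore_reference_degs.tsv", sep="\t",
                         index_label="gene", float_format=FLOAT_FMT)

        stage = "plots"
        if cfg.plots:
            from . import plots

            pdir = out / "plots"
            pdir.mkdir(exist_ok=True)
            for tsv in sorted(edir.glob("lollipop_*.tsv")):
                plots.plot_lollipop(tsv, pdir / (tsv.stem + ".svg"))
            ztsv = rdir / "zscore_reference_degs.tsv"
            if ztsv.exists():
                plots.plot_heatmap(ztsv, pdir / "zscore_heatmap.svg")

        stage = "manifest"
        _check_bookkeeping(manifest, conc)
        manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return RunResult(out_dir=out, manifest=manifest)
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def _check_bookkeeping(manifest: dict, conc) -> None:
    """genes_tested >= n_degs >= sum of residual-set sizes, per contrast."""
    n_degs = manifest["stages"]["reference_de"]["n_degs"]
    if manifest["stages"]["reference_de"]["genes_tested"] < n_degs:
        raise PipelineError("manifest", "DEG count exceeds tested genes")
    for name, res in conc.residuals.items():
        if len(res.convergent) + len(res.divergent) > n_degs:
            raise PipelineError(
                "manifest", f"residual sets of {name} exceed the DEG count"
            )
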