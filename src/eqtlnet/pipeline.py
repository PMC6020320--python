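"""End-to-end orchestration: simulate/load -> filter -> map -> hotspots ->
overlap -> phenotype ANOVA -> promoter scan -> stratified networks -> enrichment.

A single YAML config (all keys optional; unknown keys rejected) drives the
run; the effective config is serialized next to the outputs, and a manifest
records every stage output with a sha256 checksum so reruns can be diffed.
All stochastic stages draw child seeds from the one master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import io as eio
from . import motifs, network, overlap, phenotype, simulate
from .eqtl import EqtlScan, filter_variants
from .hotspots import HotspotDetector

__all__ = ["PipelineConfig", "validate_config", "load_config", "run_all"]

_DEFAULTS: dict[str, dict] = {
    "filter": {"min_call_rate": 0.95, "min_maf": 0.05, "drop_sex_chroms": True},
    "eqtl": {"fdr": 0.05, "cis_window": 1_000_000, "pooled_fdr": False,
             "inverse_normal": False},
    "hotspots": {"n_perm": 1000, "quantile": 0.95, "r2_merge": 0.5, "null": "max"},
    "overlap": {"n_perm": 1000, "pad": 100_000, "alternative": "greater"},
    "assoc": {"fdr_scope": "per_hotspot"},
    "tfbs": {"p_threshold": 0.05, "pseudocount": 0.25},
    "network": {"soft_power": 6, "min_module_size": 30, "deep_split": 2,
                "merge_height": 0.25, "scale_quantile": 0.95,
                "min_traits": 3, "p_threshold": 0.1, "top_hubs": 20},
    "enrichment": {"fdr": 0.05},
}

_INPUT_KEYS = {
    "genotypes", "expression", "genes", "covariates", "phenotypes",
    "known_qtl", "promoters", "pfm", "gene_sets", "chrom_sizes",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "eqtlnet_results"
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    eqtl: dict = field(default_factory=dict)
    hotspots: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    assoc: dict = field(default_factory=dict)
    tfbs: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)


def validate_config(raw: dict | None) -> PipelineConfig:
    """Type- and range-check a raw config dict, filling defaults."""
    raw = dict(raw or {})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    problems = []
    for section, defaults in _DEFAULTS.items():
        given = getattr(cfg, section)
        bad = set(given) - set(defaults)
        if bad:
            problems.append(f"{section}: unknown keys {sorted(bad)}")
        setattr(cfg, section, {**defaults, **given})
    if cfg.sim:
        bad = set(cfg.sim) - set(simulate.SimConfig.__dataclass_fields__)
        if bad:
            problems.append(f"sim: unknown keys {sorted(bad)}")
    bad_inputs = set(cfg.inputs) - _INPUT_KEYS
    if bad_inputs:
        problems.append(f"inputs: unknown keys {sorted(bad_inputs)}")
    for q_key, section in (("quantile", "hotspots"), ("scale_quantile", "network")):
        q = getattr(cfg, section)[q_key]
        if not (0 < q < 1):
            problems.append(f"{section}.{q_key} must be in (0, 1), got {q}")
    for frac_key, section in (("fdr", "eqtl"), ("p_threshold", "tfbs"), ("fdr", "enrichment")):
        v = getattr(cfg, section)[frac_key]
        if not (0 <= v <= 1):
            problems.append(f"{section}.{frac_key} must be in [0, 1], got {v}")
    if not cfg.simulate:
        required = {"genotypes", "expression", "genes", "covariates", "phenotypes"}
        missing = required - set(cfg.inputs)
        if missing:
            problems.append(
                f"simulate is disabled but required input paths are missing: {sorted(missing)}"
            )
    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
    return cfg


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) if path else None
    return validate_config(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seed(seed: int, offset: int) -> list[int]:
    return [int(seed), offset]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    def record(stage: str, name: str, path: Path) -> None:
        manifest.setdefault(stage, {})[name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    # --- stage 1: simulate or load -------------------------------------
    if config.simulate:
        sim_cfg = simulate.SimConfig(**{**config.sim, "seed": config.seed})
        data = simulate.simulate_dataset(sim_cfg)
        input_dir = out / "inputs"
        paths = simulate.write_dataset(data, input_dir)
        for name, p in paths.items():
            record("simulate", name, Path(p))
        variant_table, dosage = data.variant_table, data.dosage
        expression, gene_table = data.expression, data.gene_table
        covariates, phenotypes = data.covariates, data.phenotypes
        promoters, pfm = data.promoters, data.pfm
        known_qtl, gene_sets = data.regions, data.gene_sets
        lengths = data.chrom_lengths
    else:
        variant_table, dosage = eio.read_genotypes(config.inputs["genotypes"])
        expression = eio.read_expression(config.inputs["expression"])
        gene_table = eio.read_gene_table_gff3(config.inputs["genes"])
        covariates = eio.read_table(config.inputs["covariates"])
        phenotypes = eio.read_table(config.inputs["phenotypes"])
        promoters = (
            eio.read_fasta(config.inputs["promoters"])
            if "promoters" in config.inputs else None
        )
        pfm = eio.read_pfm_jaspar(config.inputs["pfm"]) if "pfm" in config.inputs else None
        known_qtl = (
            eio.read_regions_bed(config.inputs["known_qtl"], label="known_qtl")
            if "known_qtl" in config.inputs else None
        )
        gene_sets = (
            eio.read_gmt(config.inputs["gene_sets"]) if "gene_sets" in config.inputs else None
        )
        lengths = (
            eio.read_chrom_sizes(config.inputs["chrom_sizes"])
            if "chrom_sizes" in config.inputs
            else {
                c: int(variant_table.loc[variant_table["chromosome"] == c, "position"].max())
                for c in variant_table["chromosome"].unique()
            }
        )

    cfg_path = out / "effective_config.yaml"
    cfg_path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    record("config", "effective_config", cfg_path)

    # --- stage 2: variant filtering ------------------------------------
    fkw = config.filter
    variant_table = filter_variants(
        variant_table,
        min_call_rate=fkw["min_call_rate"],
        min_maf=fkw["min_maf"],
        drop_sex_chroms=fkw["drop_sex_chroms"],
    )
    dosage = dosage[variant_table["variant_id"]]
    p = out / "variants_filtered.tsv"
    variant_table.to_csv(p, sep="\t", index=False)
    record("filter", "variants", p)

    # --- stage 3: eQTL scan --------------------------------------------
    ekw = config.eqtl
    results = EqtlScan(
        expression, dosage, variant_table, gene_table,
        covariates=covariates,
        cis_window=ekw["cis_window"],
        inverse_normal=ekw["inverse_normal"],
    ).fit(fdr=ekw["fdr"], pooled_fdr=ekw["pooled_fdr"])
    for cls in ("cis", "trans"):
        p = out / f"eqtls_{cls}.tsv"
        results.significant(cls).to_csv(p, sep="\t", index=False, float_format="%.6g")
        record("map_eqtl", cls, p)

    # --- stage 4: hotspot detection ------------------------------------
    hkw = config.hotspots
    hres = HotspotDetector(
        results, dosage, variant_table, lengths, r2_merge=hkw["r2_merge"]
    ).fit(
        n_perm=hkw["n_perm"],
        quantile=hkw["quantile"],
        seed=_child_seed(config.seed, 67),
        null=hkw["null"],
    ) if len(results.significant("trans")) else None
    hotspot_frame = hres.to_frame() if hres else pd.DataFrame()
    p = out / "hotspots.tsv"
    hotspot_frame.to_csv(p, sep="\t", index=False)
    record("hotspots", "hotspots", p)
    if hres and hres.calls:
        windows = eio.RegionSet(
            label="hotspot_windows",
            intervals=pd.DataFrame(
                [c.window for c in hres.calls], columns=["chromosome", "start", "end"]
            ),
        )
        p = out / "hotspot_windows.bed"
        eio.write_regions_bed(windows, p)
        record("hotspots", "windows", p)

    # --- stage 5: overlap with known QTL regions -----------------------
    okw = config.overlap
    if known_qtl is not None and len(results.significant()):
        sig_variants = results.significant()["variant_id"].unique()
        vt = variant_table.set_index("variant_id").loc[sig_variants]
        pad = int(okw["pad"])
        regions_a = eio.RegionSet(
            label="eqtl_regions",
            intervals=pd.DataFrame(
                {
                    "chromosome": vt["chromosome"].to_numpy(),
                    "start": np.maximum(1, vt["position"].to_numpy() - pad),
                    "end": vt["position"].to_numpy() + pad,
                }
            ),
        )
        otest = overlap.permutation_overlap_test(
            regions_a, known_qtl, lengths,
            n_perm=okw["n_perm"],
            seed=_child_seed(config.seed, 71),
            alternative=okw["alternative"],
        )
        categories = overlap.classify_all_pairs(regions_a, known_qtl)
        p = out / "overlap_test.json"
        p.write_text(json.dumps(asdict(otest), indent=2))
        record("overlap", "test", p)
        p = out / "overlap_categories.tsv"
        categories.to_csv(p, sep="\t", index=False)
        record("overlap", "categories", p)

    # --- stage 6: hotspot-phenotype ANOVA ------------------------------
    anchors = [c.anchor_variant for c in hres.calls] if hres else []
    if anchors:
        assoc = phenotype.associate_hotspots(
            anchors, dosage, phenotypes, covariates,
            fdr_scope=config.assoc["fdr_scope"],
        )
        p = out / "hotspot_assoc.tsv"
        assoc.to_csv(p, sep="\t", index=False, float_format="%.6g")
        record("assoc", "hotspot_assoc", p)

    # --- stage 7: promoter TFBS scan -----------------------------------
    if promoters is not None and pfm is not None:
        tkw = config.tfbs
        pssm = motifs.pfm_to_pssm(pfm, pseudocount=tkw["pseudocount"])
        hits, gene_summary = motifs.scan_promoters(
            pssm, promoters, p_threshold=tkw["p_threshold"]
        )
        p = out / "tfbs_hits.tsv"
        hits.to_csv(p, sep="\t", index=False, float_format="%.6g")
        record("tfbs", "hits", p)
        p = out / "tfbs_gene_summary.tsv"
        gene_summary.to_csv(p, sep="\t", index=False, float_format="%.6g")
        record("tfbs", "gene_summary", p)

    # --- stage 8: genotype-stratified networks -------------------------
    nkw = config.network
    module_trait = {}
    networks = None
    if anchors:
        anchor = anchors[0]
        adjusted = pd.DataFrame(
            {t: phenotype.adjust_phenotype(phenotypes[t], covariates)
             for t in phenotypes.columns}
        )
        params = network.NetworkParams(
            soft_power=nkw["soft_power"],
            min_module_size=nkw["min_module_size"],
            deep_split=nkw["deep_split"],
            merge_height=nkw["merge_height"],
            scale_quantile=nkw["scale_quantile"],
        )
        networks = network.compare_genotype_networks(
            expression, dosage[anchor], traits=adjusted, params=params
        )
        for name in ("AA", "AB"):
            res = networks["networks"][name]
            p = out / f"modules_{name}.tsv"
            res.labels.to_frame("module").to_csv(p, sep="\t", index_label="gene_id")
            record("network", f"modules_{name}", p)
            p = out / f"eigengenes_{name}.tsv"
            res.eigengenes.to_csv(p, sep="\t", index_label="module", float_format="%.6g")
            record("network", f"eigengenes_{name}", p)
            cor = networks["module_trait"][name]
            module_trait[name] = cor
            p = out / f"module_trait_{name}.tsv"
            pd.concat({"r": cor.r, "p": cor.p}, axis=1).to_csv(
                p, sep="\t", index_label="module", float_format="%.6g"
            )
            record("network", f"module_trait_{name}", p)
            hubs = {
                mod: ",".join(res.hub_genes(mod, k=nkw["top_hubs"]))
                for mod in res.modules
            }
            p = out / f"hubs_{name}.tsv"
            pd.Series(hubs, name="hub_genes").to_csv(p, sep="\t", index_label="module")
            record("network", f"hubs_{name}", p)

    # --- stage 9: enrichment -------------------------------------------
    if networks is not None and gene_sets:
        frames = []
        for name in ("AA", "AB"):
            res = networks["networks"][name]
            selected = network.select_trait_modules(
                module_trait[name],
                min_traits=nkw["min_traits"],
                p_threshold=nkw["p_threshold"],
            )
            module_genes = {m: res.module_genes(m) for m in selected}
            table = enrich_mod.enrich_modules(
                module_genes, gene_sets, list(res.labels.index),
                fdr=config.enrichment["fdr"],
            )
            table.insert(0, "genotype", name)
            frames.append(table)
        frames = [f for f in frames if len(f)]
        enrichment = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        p = out / "enrichment.tsv"
        enrichment.to_csv(p, sep="\t", index=False, float_format="%.6g")
        record("enrichment", "enrichment", p)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
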