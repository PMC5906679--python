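"""End-to-end orchestration: simulate/load -> GWAS -> loci -> clusters ->
comparative annotation -> haplotype screen -> reports and figures.

A run is driven by a single YAML config with one section per stage; every
threshold (6.0/3.0, merge gaps, minimum haplotype carriers, alphas) is
surfaced there with the analysis defaults.  A manifest (config hash, seed,
package versions) is written alongside the outputs so that identical
config + seed reproduces identical TSVs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import gmcqtl

from . import compare, core_io, gwas, haplotypes, loci, simulate

logger = logging.getLogger("gmcqtl")

DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_X": 150, "n_G": 150, "n_chrom": 5, "snps_per_chrom": 1000,
        "fst": 0.15, "seed": 0, "causal_genes": [],
    },
    "gwas": {"traits": list(core_io.TRAITS), "pcs": "auto", "k_max": 5,
             "p3d": True, "maf_threshold": 0.01},
    "loci": {"strict": loci.STRICT_THRESHOLD, "loose": loci.LOOSE_THRESHOLD,
             "merge_gap": loci.DEFAULT_MERGE_GAP},
    "cluster": {"max_gap": loci.DEFAULT_CLUSTER_GAP},
    "haplotypes": {"traits": ["Fe", "Zn", "Cd"], "min_count": 5},
    "plots": True,
}


def demo_config(seed: int = 1, n_per_subset: int = 150,
                n_chrom: int = 5, snps_per_chrom: int = 1000) -> dict:
    """A self-contained demo: simulated panel with three planted causal
    genes (Zn, Fe and Cd), sized for a quick end-to-end run."""
    return _merge(DEFAULT_CONFIG, {
        "simulate": {
            "n_X": n_per_subset, "n_G": n_per_subset,
            "n_chrom": n_chrom, "snps_per_chrom": snps_per_chrom,
            "seed": seed,
            "causal_genes": [
                {"gene_id": "OsSim01g01", "chrom": "1",
                 "start": 10_000_000, "end": 10_400_000,
                 "trait": "Zn", "effects": [0.0, 2.0]},
                {"gene_id": "OsSim02g01", "chrom": "2",
                 "start": 5_000_000, "end": 5_400_000,
                 "trait": "Fe", "effects": [0.0, 0.9]},
                {"gene_id": "OsSim03g01", "chrom": "3",
                 "start": 20_000_000, "end": 20_400_000,
                 "trait": "Cd", "effects": [0.0, 0.009]},
            ],
        },
    })


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _causal_genes_from_config(entries: list[dict]) -> tuple:
    out = []
    for e in entries:
        gene = core_io.GeneModel(e["gene_id"], str(e["chrom"]),
                                 int(e["start"]), int(e["end"]))
        out.append(simulate.CausalGene(gene, e["trait"],
                                       tuple(float(x) for x in e["effects"])))
    return tuple(out)


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Run every stage and write all reports under ``out_dir``."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ data
    if "inputs" in cfg:
        ins = cfg["inputs"]
        for key in ("vcf", "phenotypes"):
            if key in ins and not Path(ins[key]).exists():
                raise FileNotFoundError(f"missing input: {ins[key]}")
        subset_map = {}
        G = core_io.read_genotypes(ins["vcf"], subset_map=None)
        pheno = core_io.read_phenotypes(ins["phenotypes"])
        sub = dict(zip(pheno["accession_id"], pheno["subset"]))
        G.subset = [sub.get(a, "UNKNOWN") for a in G.accession_ids]
        genes = (core_io.read_gene_models(ins["genes"])
                 if "genes" in ins else [])
        support = (core_io.read_support_intervals(ins["support"])
                   if "support" in ins else [])
        truth = None
    else:
        sim = dict(cfg["simulate"])
        if seed is not None:
            sim["seed"] = seed
        causal = _causal_genes_from_config(sim.pop("causal_genes", []))
        sim_cfg = simulate.SimulationConfig(causal_genes=causal, **sim)
        G, pheno, truth = simulate.simulate_panel(sim_cfg)
        genes = [cg.gene for cg in causal]
        support = []
        core_io.write_genotypes(G, out / "panel.vcf")
        core_io.write_phenotypes(pheno, out / "phenotypes.tsv")

    # ------------------------------------------------------------------ gwas
    gcfg = cfg["gwas"]
    K = gwas.vanraden_kinship(G)
    eig = gwas._eigendecompose(K)
    all_loci: list[loci.QtlLocus] = []
    assoc_by_trait: dict[str, pd.DataFrame] = {}
    for trait in gcfg["traits"]:
        y = pheno.set_index("accession_id")[trait] \
                 .reindex(G.accession_ids).to_numpy(float)
        if gcfg["pcs"] == "auto":
            k = gwas.select_pcs_bic(y, G, K, gcfg["k_max"], eig=eig)
        else:
            k = int(gcfg["pcs"])
        X = gwas.genotype_pca(G, k)
        assoc = gwas.scan_mlm(y, X, K, G, p3d=gcfg["p3d"],
                              maf_threshold=gcfg["maf_threshold"])
        assoc_by_trait[trait] = assoc
        gwas.write_association(assoc, out / f"assoc_{trait}.tsv")
        lam = gwas.genomic_control_lambda(assoc)
        logger.info("%s: %d SNPs scanned, %d PCs, lambda=%.3f",
                    trait, len(assoc), k, lam)

        # -------------------------------------------------------------- loci
        lcfg = cfg["loci"]
        called = loci.call_loci(assoc, trait, strict=lcfg["strict"],
                                loose=lcfg["loose"], support=support,
                                merge_gap=lcfg["merge_gap"])
        logger.info("%s: %d loci called", trait, len(called))
        all_loci.extend(called)

    cd_loci = [l for l in all_loci if l.trait == "Cd"]
    if cd_loci:
        clusters = loci.cluster_cd_loci(cd_loci,
                                        max_gap=cfg["cluster"]["max_gap"])
        logger.info("Cd: %d loci in %d clusters", len(cd_loci), len(clusters))
    compare.overlap_support(all_loci, support)

    table = loci.loci_to_table(all_loci)
    core_io.write_qtl_table(table, out / "qtl_table.tsv")
    summary = loci.summarize_qtl_table(table)
    _write_summary(summary, out / "qtl_summary.tsv")

    # ------------------------------------------------------------ haplotypes
    hcfg = cfg["haplotypes"]
    duncan_results: list[haplotypes.DuncanResult] = []
    if genes:
        screen = haplotypes.screen_genes(
            G, genes, pheno, traits=tuple(hcfg["traits"]),
            min_count=hcfg["min_count"])
        screen.to_csv(out / "gene_screen.tsv", sep="\t", index=False)
        for gene in genes:
            for subset in core_io.SUBSETS:
                assignment = haplotypes.build_haplotypes(
                    G, gene, subset, hcfg["min_count"])
                haplotypes.write_haplotype_assignment(
                    assignment, out / f"haplotypes_{gene.gene_id}_{subset}.tsv")
                sub_pheno = pheno[pheno["subset"] == subset]
                for trait in hcfg["traits"]:
                    duncan_results.append(haplotypes.star_level(
                        gene, trait, subset, assignment, sub_pheno))

    # ---------------------------------------------------------------- plots
    if cfg.get("plots", True):
        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        for trait, assoc in assoc_by_trait.items():
            plot_manhattan(assoc, fig_dir / f"manhattan_{trait}.png",
                           thresholds=(cfg["loci"]["loose"],
                                       cfg["loci"]["strict"]))
        plot_distributions(pheno, fig_dir)
        haplotypes.plot_haplotype_traits(duncan_results, fig_dir)

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": seed if seed is not None
                else cfg.get("simulate", {}).get("seed"),
        "gmcqtl_version": gmcqtl.__version__,
        "n_accessions": G.n_accessions,
        "n_snps": G.n_snps,
        "n_loci": len(all_loci),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out


def _write_summary(summary: dict, path: Path) -> None:
    rows = []
    for k, v in summary.items():
        if k == "per_trait":
            for t, stats in v.items():
                for sk, sv in stats.items():
                    rows.append((f"{t}.{sk}", _fmt(sv)))
        else:
            rows.append((k, _fmt(v)))
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        path, sep="\t", index=False)


def _fmt(v) -> str:
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_manhattan(assoc: pd.DataFrame, path,
                   thresholds: tuple[float, float] = (3.0, 6.0)):
    """Manhattan plot with alternating per-chromosome palette and horizontal
    lines at the loose and strict calling thresholds."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if assoc.empty:
        raise ValueError("empty association table")
    fig, ax = plt.subplots(figsize=(9, 3))
    palette = ("#1f78b4", "#a6cee3")
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(assoc.groupby("chrom", sort=False)):
        x = sub["pos"].to_numpy(float) + offset
        y = sub["minus_log10_p"].to_numpy(float)
        ax.scatter(x, y, s=4, color=palette[i % 2], rasterized=True)
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max() + 1
    for thr, style in zip(thresholds, ("--", "-")):
        ax.axhline(thr, color="red", linestyle=style, linewidth=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_distributions(pheno: pd.DataFrame, out_dir) -> list:
    """Per-trait histograms with the X and G subsets in distinct colors."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if pheno.empty:
        raise ValueError("empty phenotype table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    colors = {"X": "#e31a1c", "G": "#1f78b4"}
    for trait in core_io.TRAITS:
        if trait not in pheno.columns:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        for subset in core_io.SUBSETS:
            vals = pheno.loc[pheno["subset"] == subset, trait].dropna()
            if len(vals):
                ax.hist(vals, bins=30, alpha=0.6, label=f"{subset}-set",
                        color=colors[subset])
        ax.set_xlabel(f"{trait} (ppm)")
        ax.set_ylabel("accessions")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"dist_{trait}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
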