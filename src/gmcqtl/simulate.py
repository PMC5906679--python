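"""Synthetic two-subset rice germplasm panels with planted GMC genetics.

The generator emulates the structure of a 698-accession panel made of an
indica/Xian subset (X, 265 accessions) and a japonica/Geng subset (G, 433
accessions):

* Allele frequencies diverge between subsets around shared ancestral
  frequencies under a Balding-Nichols model with divergence parameter F.
* SNPs are drawn in blocks whose accessions copy from a small pool of
  founder block-haplotypes, inducing linkage disequilibrium so that genes
  carry few distinct haplotypes.
* Phenotypes are subset baseline + planted causal-haplotype effects +
  Gaussian noise; the default Cd baselines differ strongly between subsets,
  producing the bimodal pooled Cd distribution seen in such panels, while
  Se baselines overlap.

Default trait baselines target the pooled panel statistics (ppm): Fe mean
2.4, Zn 16.4, Cd 0.009, Mn 9.7, Cu 3.2, Se 0.04.  One integer seed fully
determines every output; per-stage substreams are spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (MISSING, SUBSETS, TRAITS, GeneModel, GenotypeMatrix,
                      Snp)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class CausalGene:
    """A gene whose haplotypes shift one trait by fixed ppm increments.

    ``effects[i]`` is added to carriers of the i-th most frequent haplotype
    over the gene span; haplotypes beyond the vector get 0.
    """

    gene: GeneModel
    trait: str
    effects: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ConfigError(f"unknown trait {self.trait!r}")
        if not all(np.isfinite(self.effects)):
            raise ConfigError(f"{self.gene.gene_id}: non-finite effect size")


# Per-subset (mean, SD) baselines in ppm.  X/G means reproduce the pooled
# panel means at the study's 265:433 subset sizes; G runs higher in Zn and
# Cu and much lower in Cd, Se overlaps between subsets.
DEFAULT_TRAIT_BASELINES: dict[str, dict[str, tuple[float, float]]] = {
    "Fe": {"X": (2.40, 0.90), "G": (2.40, 0.90)},
    "Zn": {"X": (14.80, 3.00), "G": (17.40, 3.00)},
    "Cd": {"X": (0.0175, 0.0060), "G": (0.0038, 0.0012)},
    "Mn": {"X": (9.70, 2.80), "G": (9.70, 2.80)},
    "Cu": {"X": (2.90, 0.95), "G": (3.38, 0.95)},
    "Se": {"X": (0.040, 0.016), "G": (0.040, 0.016)},
}


@dataclass
class SimulationConfig:
    """Panel-simulation settings; the defaults are the study conditions."""

    n_X: int = 265
    n_G: int = 433
    n_chrom: int = 12
    snps_per_chrom: int = 420
    fst: float = 0.15              # Balding-Nichols divergence between subsets
    block_size: int = 10           # SNPs per LD block
    n_founders: int = 6            # founder block-haplotypes per subset
    copy_eps: float = 0.02         # per-SNP escape from the copied founder
    het_rate: float = 0.0          # inbred panel: residual heterozygosity
    missing_rate: float = 0.0
    chrom_length: int = 30_000_000
    causal_genes: tuple[CausalGene, ...] = ()
    trait_baselines: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {t: dict(v) for t, v in
                                 DEFAULT_TRAIT_BASELINES.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_X <= 0 or self.n_G <= 0:
            raise ConfigError("accession counts must be positive")
        if self.n_chrom <= 0 or self.snps_per_chrom <= 0:
            raise ConfigError("SNP grid must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ConfigError("fst must be in (0, 1)")


@dataclass
class SimulationTruth:
    """What was planted: causal haplotype partitions, effects, baselines."""

    causal: list[dict]                      # per causal gene
    subset_means: dict[str, dict[str, float]]
    realized_h2: dict[str, float]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator
                        ) -> GenotypeMatrix:
    n = cfg.n_X + cfg.n_G
    subset = ["X"] * cfg.n_X + ["G"] * cfg.n_G
    ids = [f"X{i + 1:04d}" for i in range(cfg.n_X)] + \
          [f"G{i + 1:04d}" for i in range(cfg.n_G)]
    F = cfg.fst
    snps: list[Snp] = []
    cols: list[np.ndarray] = []
    for c in range(1, cfg.n_chrom + 1):
        m = cfg.snps_per_chrom
        step = max(1, cfg.chrom_length // (m + 1))
        pos = np.cumsum(rng.integers(max(1, step // 2), step + step // 2, m))
        alleles = np.empty((n, m), dtype=np.int8)
        for b0 in range(0, m, cfg.block_size):
            b1 = min(b0 + cfg.block_size, m)
            width = b1 - b0
            p_anc = rng.uniform(0.05, 0.95, width)
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            for lab, rows in (("X", slice(0, cfg.n_X)),
                              ("G", slice(cfg.n_X, n))):
                p_sub = np.clip(rng.beta(a, b), 0.001, 0.999)
                founders = (rng.random((cfg.n_founders, width)) <
                            p_sub[None, :]).astype(np.int8)
                n_sub = rows.stop - rows.start
                pick = rng.integers(0, cfg.n_founders, n_sub)
                block = founders[pick]
                esc = rng.random((n_sub, width)) < cfg.copy_eps
                fresh = (rng.random((n_sub, width)) < p_sub[None, :]).astype(np.int8)
                block = np.where(esc, fresh, block)
                alleles[rows, b0:b1] = block
        dose = (2 * alleles).astype(np.int8)
        if cfg.het_rate > 0:
            het = rng.random(dose.shape) < cfg.het_rate
            dose[het] = 1
        if cfg.missing_rate > 0:
            mis = rng.random(dose.shape) < cfg.missing_rate
            dose[mis] = MISSING
        ref_alt = rng.integers(0, 4, (m, 2))
        ref_alt[:, 1] = (ref_alt[:, 0] + 1 + rng.integers(0, 3, m)) % 4
        for j in range(m):
            snps.append(Snp(str(c), int(pos[j]), _BASES[ref_alt[j, 0]],
                            _BASES[ref_alt[j, 1]], f"chr{c}_{pos[j]}"))
        cols.append(dose)
    dosage = np.hstack(cols)
    return GenotypeMatrix(ids, subset, snps, dosage)


# ---------------------------------------------------------------------------
# Planted haplotype effects
# ---------------------------------------------------------------------------

def plant_haplotype_effect(G: GenotypeMatrix, gene: GeneModel,
                           effects: tuple[float, ...] | list[float]
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype increments from a planted per-haplotype effect vector.

    Accessions are partitioned by their raw dosage string over the SNPs in
    the gene span; haplotypes are ranked by carrier count (descending, ties
    by first occurrence) and ``effects[rank]`` is added to all carriers.

    Returns ``(increments, haplotype_index)`` — both length n_accessions.
    """
    idx = G.snps_in_span(gene.chrom, gene.start, gene.end)
    if idx.size == 0:
        raise ConfigError(
            f"{gene.gene_id}: gene span contains no simulated SNP")
    block = G.dosage[:, idx]
    keys = [tuple(row) for row in block]
    first_seen: dict[tuple, int] = {}
    counts: dict[tuple, int] = {}
    for i, k in enumerate(keys):
        if k not in first_seen:
            first_seen[k] = i
        counts[k] = counts.get(k, 0) + 1
    ranked = sorted(counts, key=lambda k: (-counts[k], first_seen[k]))
    if len(effects) > len(ranked):
        raise ConfigError(
            f"{gene.gene_id}: {len(effects)} effects for only "
            f"{len(ranked)} realized haplotypes")
    rank_of = {k: r for r, k in enumerate(ranked)}
    hap_index = np.array([rank_of[k] for k in keys], dtype=int)
    eff = np.zeros(len(ranked))
    eff[:len(effects)] = effects
    return eff[hap_index], hap_index


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(cfg: SimulationConfig
                   ) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Simulate genotypes, phenotypes and ground truth for one panel."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_geno, rng_pheno = [np.random.default_rng(s) for s in ss.spawn(2)]

    G = _simulate_genotypes(cfg, rng_geno)
    n = G.n_accessions
    subset = np.array(G.subset)

    genetic = {t: np.zeros(n) for t in TRAITS}
    causal_records = []
    for cg in cfg.causal_genes:
        inc, hap_index = plant_haplotype_effect(G, cg.gene, cg.effects)
        genetic[cg.trait] += inc
        causal_records.append({
            "gene_id": cg.gene.gene_id, "trait": cg.trait,
            "effects": tuple(cg.effects), "hap_index": hap_index,
        })

    pheno = {"accession_id": G.accession_ids, "subset": list(G.subset)}
    realized_h2 = {}
    subset_means = {}
    for t in TRAITS:
        vals = np.empty(n)
        subset_means[t] = {}
        for lab in SUBSETS:
            mu, sd = cfg.trait_baselines[t][lab]
            mask = subset == lab
            vals[mask] = mu + rng_pheno.normal(0.0, sd, mask.sum())
            subset_means[t][lab] = mu
        vals = vals + genetic[t]
        floor = 0.05 * min(cfg.trait_baselines[t][lab][0] for lab in SUBSETS)
        vals = np.maximum(vals, floor)   # concentrations are non-negative
        pheno[t] = vals
        tot = np.var(vals)
        realized_h2[t] = float(np.var(genetic[t]) / tot) if tot > 0 else 0.0

    truth = SimulationTruth(causal_records, subset_means, realized_h2)
    return G, pd.DataFrame(pheno), truth


def null_config(**overrides) -> SimulationConfig:
    """A config with no planted effects and equal subset baselines."""
    flat = {t: {"X": DEFAULT_TRAIT_BASELINES[t]["X"],
                "G": DEFAULT_TRAIT_BASELINES[t]["X"]} for t in TRAITS}
    kw = dict(causal_genes=(), trait_baselines=flat)
    kw.update(overrides)
    return SimulationConfig(**kw)
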