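"""QTL locus calling, Cd-locus clustering and published-table accounting.

Locus calling is dual-threshold: SNPs at -log10(P) >= 6.0 always seed loci,
while SNPs in [3.0, 6.0) seed loci only when they fall inside an external
support interval (a linkage-mapping or literature QTL for the same trait) —
the loose threshold trades type-II error against independent evidence.
Qualifying SNPs within ``merge_gap`` of each other merge into one locus.

Cd loci are additionally chained into positional clusters: consecutive
same-chromosome loci whose gap is at most ``max_gap`` share a cluster,
labeled ``Clst<chrom><a,b,c...>``.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import TRAIT_POLARITY, TRAITS, SupportInterval

logger = logging.getLogger("gmcqtl")

STRICT_THRESHOLD = 6.0
LOOSE_THRESHOLD = 3.0
DEFAULT_MERGE_GAP = 300_000     # bp between qualifying SNPs of one locus
DEFAULT_CLUSTER_GAP = 3_000_000  # bp between Cd loci of one cluster


@dataclass
class QtlLocus:
    """A trait-specific genomic interval called from the association scan."""

    name: str
    trait: str
    chrom: str
    start: int
    end: int
    peak_minus_log10: float
    fae: float
    peak_pos: int = 0
    n_snps: int = 1
    cluster_label: str = ""
    linkage_support: str = ""
    literature_support: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")


@dataclass
class QtlCluster:
    label: str
    chrom: str
    members: list[QtlLocus]

    @property
    def span(self) -> tuple[int, int]:
        return (min(l.start for l in self.members),
                max(l.end for l in self.members))

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Calling loci from an association scan
# ---------------------------------------------------------------------------

def _in_support(chrom: str, pos: int, trait: str,
                support: list[SupportInterval], trait_match: bool) -> bool:
    for iv in support:
        if iv.chrom != chrom or not (iv.start <= pos <= iv.end):
            continue
        if trait_match and iv.trait and iv.trait != trait:
            continue
        return True
    return False


def call_loci(assoc: pd.DataFrame, trait: str,
              strict: float = STRICT_THRESHOLD,
              loose: float = LOOSE_THRESHOLD,
              support: list[SupportInterval] | None = None,
              merge_gap: int = DEFAULT_MERGE_GAP,
              trait_match: bool = True) -> list[QtlLocus]:
    """Call named QTL loci for one trait from a per-SNP association table.

    ``assoc`` must carry chrom/pos/minus_log10_p/fae columns sorted by
    (chrom, pos).  See the module docstring for the dual-threshold rule.
    """
    if strict < loose:
        raise ValueError("strict threshold must be >= loose threshold")
    support = support or []
    if assoc.empty:
        return []
    mlp = assoc["minus_log10_p"].to_numpy(float)
    qual = mlp >= strict
    if loose < strict:
        candidates = np.nonzero((mlp >= loose) & ~qual)[0]
        for i in candidates:
            row = assoc.iloc[i]
            if _in_support(str(row["chrom"]), int(row["pos"]), trait,
                           support, trait_match):
                qual[i] = True
    idx = np.nonzero(qual)[0]
    if idx.size == 0:
        return []

    loci: list[QtlLocus] = []
    groups: list[list[int]] = []
    for i in idx:
        row = assoc.iloc[int(i)]
        if groups:
            prev = assoc.iloc[groups[-1][-1]]
            if (str(prev["chrom"]) == str(row["chrom"])
                    and int(row["pos"]) - int(prev["pos"]) <= merge_gap):
                groups[-1].append(int(i))
                continue
        groups.append([int(i)])

    for g in groups:
        sub = assoc.iloc[g]
        peak = sub.loc[sub["minus_log10_p"].idxmax()]
        loci.append(QtlLocus(
            name="", trait=trait, chrom=str(peak["chrom"]),
            start=int(sub["pos"].min()), end=int(sub["pos"].max()),
            peak_minus_log10=float(peak["minus_log10_p"]),
            fae=float(peak["fae"]), peak_pos=int(peak["pos"]),
            n_snps=len(g)))
    _name_loci(loci, trait)
    return loci


def _name_loci(loci: list[QtlLocus], trait: str) -> None:
    """q<Trait><chrom>[-k] in positional order; the -k suffix only when a
    chromosome carries more than one locus of the trait."""
    loci.sort(key=lambda l: (_chrom_key(l.chrom), l.start))
    per_chrom: dict[str, int] = {}
    for l in loci:
        per_chrom[l.chrom] = per_chrom.get(l.chrom, 0) + 1
    counter: dict[str, int] = {}
    for l in loci:
        counter[l.chrom] = counter.get(l.chrom, 0) + 1
        stem = f"q{trait}{l.chrom}"
        l.name = stem if per_chrom[l.chrom] == 1 else f"{stem}-{counter[l.chrom]}"


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr").removeprefix("Chr")
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# Cd locus clustering
# ---------------------------------------------------------------------------

def cluster_cd_loci(loci: list[QtlLocus],
                    max_gap: int = DEFAULT_CLUSTER_GAP) -> list[QtlCluster]:
    """Single-linkage chaining of Cd loci into positional clusters.

    Consecutive same-chromosome loci join one cluster when
    ``next.start - prev.end <= max_gap``; singletons form their own cluster.
    Labels are ``Clst<chrom><a,b,...>`` in positional order; the cluster
    label is written back onto each member locus.
    """
    bad = [l.name for l in loci if l.trait != "Cd"]
    if bad:
        raise ValueError(f"cluster_cd_loci takes Cd loci only, got {bad}")
    ordered = sorted(loci, key=lambda l: (_chrom_key(l.chrom), l.start))
    clusters: list[QtlCluster] = []
    current: list[QtlLocus] = []
    letters_used: dict[str, int] = {}

    def close(group: list[QtlLocus]) -> None:
        chrom = group[0].chrom
        i = letters_used.get(chrom, 0)
        letters_used[chrom] = i + 1
        label = f"Clst{chrom}{string.ascii_lowercase[i]}"
        for l in group:
            l.cluster_label = label
        clusters.append(QtlCluster(label, chrom, list(group)))

    for l in ordered:
        if current and l.chrom == current[-1].chrom \
                and l.start - current[-1].end <= max_gap:
            current.append(l)
        else:
            if current:
                close(current)
            current = [l]
    if current:
        close(current)
    return clusters


# ---------------------------------------------------------------------------
# Direction / favorability of a locus
# ---------------------------------------------------------------------------

def annotate_direction(locus: QtlLocus,
                       polarity: dict[str, int] = TRAIT_POLARITY
                       ) -> tuple[str, str]:
    """(increasing|decreasing, favorable|unfavorable) from the FAE sign.

    The germplasm minor allele increases the trait iff FAE > 0; it is
    health-favorable iff that direction matches the trait polarity
    (micronutrients up, Cd down).
    """
    if locus.fae == 0:
        raise ValueError(f"{locus.name}: FAE is 0; direction undefined")
    direction = "increasing" if locus.fae > 0 else "decreasing"
    favorable = (np.sign(locus.fae) == polarity[locus.trait])
    return direction, "favorable" if favorable else "unfavorable"


# ---------------------------------------------------------------------------
# published-table accounting
# ---------------------------------------------------------------------------

def summarize_qtl_table(table: pd.DataFrame) -> dict:
    """All headline statistics of a parsed QTL table.

    Regions = non-Cd loci + distinct Cd cluster labels.  Favorable loci are
    counted under trait polarity: FAE > 0 for the five micronutrients,
    FAE < 0 for Cd.
    """
    t = table
    n_loci = len(t)
    is_cd = t["trait"] == "Cd"
    cluster_labels = [c for c in t.loc[is_cd, "cluster"].unique() if c]
    sizes = t.loc[is_cd & (t["cluster"] != ""), "cluster"].value_counts()

    per_trait = {}
    for trait in TRAITS:
        sub = t[t["trait"] == trait]
        if len(sub) == 0:
            continue
        v = sub["minus_log10"]
        per_trait[trait] = {
            "n": int(len(sub)),
            "mean_minus_log10": float(v.mean()),
            "min_minus_log10": float(v.min()),
            "max_minus_log10": float(v.max()),
            "n_fae_positive": int((sub["fae"] > 0).sum()),
            "n_fae_negative": int((sub["fae"] < 0).sum()),
        }

    zero_fae = int((t["fae"] == 0).sum())
    if zero_fae:
        logger.warning("%d loci with FAE exactly 0 counted as neither "
                       "increasing nor decreasing", zero_fae)

    favorable = 0
    for _, r in t.iterrows():
        if r["fae"] != 0 and np.sign(r["fae"]) == TRAIT_POLARITY[r["trait"]]:
            favorable += 1

    return {
        "n_loci": int(n_loci),
        "n_cd_loci": int(is_cd.sum()),
        "n_non_cd_loci": int((~is_cd).sum()),
        "n_clusters": len(cluster_labels),
        "n_regions": int((~is_cd).sum()) + len(cluster_labels),
        "mean_minus_log10": float(t["minus_log10"].mean()) if n_loci else np.nan,
        "min_minus_log10": float(t["minus_log10"].min()) if n_loci else np.nan,
        "max_minus_log10": float(t["minus_log10"].max()) if n_loci else np.nan,
        "per_trait": per_trait,
        "n_increasing": int((t["fae"] > 0).sum()),
        "n_decreasing": int((t["fae"] < 0).sum()),
        "n_increasing_cd": int((is_cd & (t["fae"] > 0)).sum()),
        "n_decreasing_cd": int((is_cd & (t["fae"] < 0)).sum()),
        "n_favorable": int(favorable),
        "max_cluster_size": int(sizes.max()) if len(sizes) else 0,
        "n_singleton_clusters": int((sizes == 1).sum()),
        "n_multi_clusters": int((sizes >= 2).sum()),
        "n_linkage_supported": int((t["linkage_qtl"] != "").sum()),
        "n_literature_supported": int((t["literature"] != "").sum()),
        "pct_linkage_supported": float(100.0 * (t["linkage_qtl"] != "").sum()
                                       / n_loci) if n_loci else np.nan,
        "pct_literature_supported": float(100.0 * (t["literature"] != "").sum()
                                          / n_loci) if n_loci else np.nan,
    }


def loci_to_table(loci: list[QtlLocus]) -> pd.DataFrame:
    """Called loci as a printed-layout DataFrame (read_qtl_table schema)."""
    trait_order = {t: i for i, t in enumerate(TRAITS)}
    ordered = sorted(loci, key=lambda l: (trait_order.get(l.trait, 99),
                                          _chrom_key(l.chrom), l.start))
    rows = [{
        "trait": l.trait, "cluster": l.cluster_label, "locus": l.name,
        "chrom": l.chrom, "start": l.start, "end": l.end,
        "minus_log10": l.peak_minus_log10, "fae": l.fae,
        "linkage_qtl": l.linkage_support,
        "literature": "; ".join(l.literature_support),
    } for l in ordered]
    return pd.DataFrame(rows, columns=["trait", "cluster", "locus", "chrom",
                                       "start", "end", "minus_log10", "fae",
                                       "linkage_qtl", "literature"])


def table_to_loci(table: pd.DataFrame) -> list[QtlLocus]:
    """Parsed QTL-table rows as :class:`QtlLocus` objects."""
    out = []
    for _, r in table.iterrows():
        lits = [c.strip() for c in str(r["literature"]).split(";") if c.strip()]
        out.append(QtlLocus(
            name=r["locus"], trait=r["trait"], chrom=str(r["chrom"]),
            start=int(r["start"]), end=int(r["end"]),
            peak_minus_log10=float(r["minus_log10"]), fae=float(r["fae"]),
            cluster_label=r["cluster"], linkage_support=r["linkage_qtl"],
            literature_support=lits))
    return out
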