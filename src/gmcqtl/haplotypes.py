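"""Candidate-gene haplotype analysis and Duncan's multiple range test.

For each candidate gene and panel subset, every accession's allele string
over the polymorphic SNPs inside the gene span defines its haplotype.
Accessions with a missing or heterozygous call anywhere in the span are
excluded (the panels are near-homozygous inbred rice, so heterozygosity is
treated as a data problem rather than imputed), and haplotypes with fewer
than ``min_count`` carriers are dropped as rare.  Retained haplotypes are
named Hap1..HapN by descending carrier count.

Trait means across haplotypes are compared with Duncan's multiple range
test: a step-down range procedure on the ranked means using studentized-
range critical values at the protection level alpha_p = 1 - (1-alpha)^(p-1)
for a stretch of p means.  A compact letter display summarizes the result;
star levels (*, **, ***, ****) report the most stringent of the alphas
0.05, 0.01, 0.001, 0.0001 at which at least one pair of haplotypes
separates.

Favorable-haplotype classification codifies the breeding narrative for the
Fe/Zn/Cd trio: a haplotype is *favorable* when it significantly raises Fe
or Zn without a significant loss in the other micronutrient and without a
significant Cd increase; *conditional* when a micronutrient gain comes with
such a trade-off; *unfavorable* when it only loses micronutrients or gains
Cd; *neutral* otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .core_io import MISSING, GeneModel, GenotypeMatrix

logger = logging.getLogger("gmcqtl")

ALPHAS: tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001)
STARS: dict[float, str] = {0.05: "*", 0.01: "**", 0.001: "***", 0.0001: "****"}
DEFAULT_MIN_COUNT = 5

EXCLUDED_MISSING = "missing"
EXCLUDED_HET = "heterozygous"
EXCLUDED_RARE = "rare"


# ---------------------------------------------------------------------------
# Haplotype construction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAssignment:
    """Per-gene haplotype partition of one panel subset."""

    gene_id: str
    subset: str
    snp_positions: list[int]
    hap_strings: list[str]              # ranked Hap1..HapN allele strings
    hap_counts: list[int]
    accession_ids: list[str]
    hap_index: np.ndarray               # per accession; -1 if excluded
    excluded_reason: list[str]          # "" when assigned

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_strings)

    @property
    def hap_names(self) -> list[str]:
        return [f"Hap{i + 1}" for i in range(self.n_haplotypes)]

    def members(self, hap: int) -> np.ndarray:
        return np.nonzero(self.hap_index == hap)[0]


def build_haplotypes(G: GenotypeMatrix, gene: GeneModel, subset: str,
                     min_count: int = DEFAULT_MIN_COUNT,
                     snp_filter: np.ndarray | None = None
                     ) -> HaplotypeAssignment:
    """Assign accessions of one subset to gene haplotypes.

    ``snp_filter`` optionally restricts the span to a marked subset of SNP
    indices (e.g. coding SNPs) before the polymorphism filter.
    """
    acc_idx = np.nonzero(G.subset_mask(subset))[0]
    span = G.snps_in_span(gene.chrom, gene.start, gene.end)
    if snp_filter is not None:
        span = np.intersect1d(span, snp_filter)
    sub = G.dosage[np.ix_(acc_idx, span)]

    # polymorphic within this subset, among non-missing homozygous calls
    poly_cols = []
    for j in range(sub.shape[1]):
        col = sub[:, j]
        vals = set(col[(col == 0) | (col == 2)])
        if len(vals) > 1:
            poly_cols.append(j)
    if not poly_cols:
        logger.warning("%s/%s: no polymorphic SNP in gene span",
                       gene.gene_id, subset)
        return HaplotypeAssignment(
            gene.gene_id, subset, [], [], [],
            [G.accession_ids[i] for i in acc_idx],
            np.full(len(acc_idx), -1, dtype=int), [""] * len(acc_idx))

    positions = [G.snps[span[j]].pos for j in poly_cols]
    bases = [(G.snps[span[j]].ref, G.snps[span[j]].alt) for j in poly_cols]
    sub = sub[:, poly_cols]

    reasons = [""] * len(acc_idx)
    strings: list[str | None] = [None] * len(acc_idx)
    for i in range(len(acc_idx)):
        row = sub[i]
        if (row == MISSING).any():
            reasons[i] = EXCLUDED_MISSING
        elif (row == 1).any():
            reasons[i] = EXCLUDED_HET
        else:
            strings[i] = "".join(bases[j][0] if row[j] == 0 else bases[j][1]
                                 for j in range(len(poly_cols)))

    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for i, h in enumerate(strings):
        if h is None:
            continue
        if h not in first:
            first[h] = i
        counts[h] = counts.get(h, 0) + 1
    ranked = sorted(counts, key=lambda h: (-counts[h], first[h]))
    retained = [h for h in ranked if counts[h] >= min_count]
    rank_of = {h: r for r, h in enumerate(retained)}

    hap_index = np.full(len(acc_idx), -1, dtype=int)
    for i, h in enumerate(strings):
        if h is None:
            continue
        if h in rank_of:
            hap_index[i] = rank_of[h]
        else:
            reasons[i] = EXCLUDED_RARE
    return HaplotypeAssignment(
        gene.gene_id, subset, positions, retained,
        [counts[h] for h in retained],
        [G.accession_ids[i] for i in acc_idx], hap_index, reasons)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _duncan_critical_q(p: int, df: int, alpha: float) -> float:
    """Studentized-range quantile at Duncan's protection level
    alpha_p = 1 - (1 - alpha)^(p - 1) for a stretch of p ranked means."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(studentized_range.ppf(1.0 - alpha_p, p, df))


@dataclass
class MrtResult:
    """One Duncan run at a single alpha."""

    group_names: list[str]
    n: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    mse: float
    df: int
    alpha: float
    letters: list[str]                  # compact letter display, input order
    separated: np.ndarray               # boolean pair matrix, input order

    @property
    def any_separation(self) -> bool:
        return bool(self.separated.any())

    def significantly_higher(self, a: int, b: int) -> bool:
        return bool(self.separated[a, b] and self.means[a] > self.means[b])


def duncan_mrt(groups: dict[str, np.ndarray], alpha: float = 0.05) -> MrtResult:
    """Duncan's multiple range test over named groups of trait values.

    One-way ANOVA supplies MSE and error df; the step-down range procedure
    with Kramer's harmonic-mean adjustment (over the two groups of each
    comparison) decides which pairs separate; a stretch contained in a
    non-significant stretch is never declared significant.
    """
    names, data = [], []
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            logger.warning("group %s has no observations; dropped", name)
            continue
        names.append(name)
        data.append(vals)
    k = len(names)
    ns = np.array([len(v) for v in data])
    means = np.array([v.mean() for v in data])
    sds = np.array([v.std(ddof=1) if len(v) > 1 else 0.0 for v in data])
    N = int(ns.sum())
    dfree = N - k
    if k < 2 or dfree < 1:
        sep = np.zeros((k, k), dtype=bool)
        return MrtResult(names, ns, means, sds, np.nan, max(dfree, 0), alpha,
                         ["a"] * k, sep)
    sse = float(sum(((v - v.mean()) ** 2).sum() for v in data))
    mse = sse / dfree

    order = np.argsort(-means, kind="stable")   # descending
    m_sorted = means[order]
    n_sorted = ns[order]

    # step-down over stretches, longest first; suppression propagates inward
    sig = {}
    suppressed = np.zeros((k, k), dtype=bool)
    for length in range(k, 1, -1):
        for i in range(0, k - length + 1):
            j = i + length - 1
            if suppressed[i, j]:
                s = False
            else:
                rng = m_sorted[i] - m_sorted[j]
                nh = 2.0 / (1.0 / n_sorted[i] + 1.0 / n_sorted[j])
                crit = _duncan_critical_q(length, dfree, alpha) \
                    * np.sqrt(mse / nh)
                s = rng > crit
            sig[(i, j)] = s
            if not s:
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        suppressed[a, b] = True

    sep_sorted = np.zeros((k, k), dtype=bool)
    for (i, j), s in sig.items():
        sep_sorted[i, j] = sep_sorted[j, i] = s

    letters_sorted = _letter_display(sep_sorted)

    sep = np.zeros((k, k), dtype=bool)
    letters = [""] * k
    for a in range(k):
        letters[order[a]] = letters_sorted[a]
        for b in range(k):
            sep[order[a], order[b]] = sep_sorted[a, b]
    return MrtResult(names, ns, means, sds, mse, dfree, alpha, letters, sep)


def _letter_display(sep_sorted: np.ndarray) -> list[str]:
    """Compact letter display for mean-sorted groups.

    Non-separated pairs of a range procedure form contiguous stretches in
    the sorted order, so the display is the classical underlining: one
    letter per maximal non-significant stretch, redundant stretches dropped.
    """
    k = sep_sorted.shape[0]
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and not sep_sorted[i, j + 1]:
            j += 1
        intervals.append((i, j))
    maximal = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                   for o in intervals):
            maximal.append(iv)
    letters = [""] * k
    for li, (i, j) in enumerate(maximal):
        ch = _letter(li)
        for a in range(i, j + 1):
            letters[a] += ch
    for a in range(k):
        if not letters[a]:          # fully separated singleton
            letters[a] = _letter(len(maximal))
            maximal.append((a, a))
    return letters


def _letter(i: int) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    while True:
        out = alphabet[i % 26] + out
        i = i // 26 - 1
        if i < 0:
            return out


# ---------------------------------------------------------------------------
# Star levels (Table-2 cells)
# ---------------------------------------------------------------------------

@dataclass
class DuncanResult:
    """Duncan comparisons of one gene x trait x subset across haplotypes."""

    gene_id: str
    trait: str
    subset: str
    hap_names: list[str]
    n: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    mse: float
    df: int
    letters: dict[float, list[str]]     # alpha -> compact letter display
    mrt: dict[float, MrtResult] = field(repr=False, default_factory=dict)
    star: str = "ns"
    reason: str = ""


def star_level(gene: GeneModel, trait: str, subset: str,
               assignment: HaplotypeAssignment,
               phenotypes: pd.DataFrame) -> DuncanResult:
    """Run Duncan's test at every alpha and report the star level.

    The star is the most stringent alpha at which at least one haplotype
    pair separates; ``ns`` when none does or fewer than two haplotypes are
    retained.
    """
    pheno = phenotypes.set_index("accession_id")[trait]
    groups: dict[str, np.ndarray] = {}
    for h, name in enumerate(assignment.hap_names):
        ids = [assignment.accession_ids[i] for i in assignment.members(h)]
        vals = pheno.reindex(ids).to_numpy(float)
        groups[name] = vals[np.isfinite(vals)]

    if assignment.n_haplotypes < 2:
        k = assignment.n_haplotypes
        return DuncanResult(gene.gene_id, trait, subset,
                            assignment.hap_names,
                            np.array([len(groups[n]) for n in groups]),
                            np.array([np.mean(groups[n]) if len(groups[n])
                                      else np.nan for n in groups]),
                            np.zeros(k), np.nan, 0, {}, {}, "ns",
                            "fewer than 2 retained haplotypes")

    letters: dict[float, list[str]] = {}
    mrts: dict[float, MrtResult] = {}
    star = "ns"
    for alpha in ALPHAS:                # loosest to most stringent
        res = duncan_mrt(groups, alpha)
        letters[alpha] = res.letters
        mrts[alpha] = res
        if res.any_separation:
            star = STARS[alpha]
    base = mrts[ALPHAS[0]]
    return DuncanResult(gene.gene_id, trait, subset, base.group_names,
                        base.n, base.means, base.sds, base.mse, base.df,
                        letters, mrts, star, "")


# ---------------------------------------------------------------------------
# Favorable-haplotype classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FavorableCall:
    gene_id: str
    subset: str
    haplotype: str
    verdict: str                        # favorable/conditional/unfavorable/neutral
    detail: dict[str, str]              # per-trait direction summary


def classify_favorable(results: dict[str, DuncanResult],
                       alpha: float = 0.05) -> list[FavorableCall]:
    """Classify each haplotype from its Fe, Zn and Cd Duncan results.

    All three results must come from one haplotype assignment (same
    haplotype set of one gene and subset).
    """
    for t in ("Fe", "Zn", "Cd"):
        if t not in results:
            logger.warning("classification skipped: missing %s result", t)
            return []
    fe, zn, cd = results["Fe"], results["Zn"], results["Cd"]
    if not (fe.hap_names == zn.hap_names == cd.hap_names):
        raise ValueError("Fe/Zn/Cd results must share one haplotype assignment")
    haps = fe.hap_names
    k = len(haps)

    def rel(res: DuncanResult, h: int) -> tuple[bool, bool]:
        mrt = res.mrt.get(alpha)
        if mrt is None:
            return False, False
        higher = any(mrt.significantly_higher(h, o) for o in range(k) if o != h)
        lower = any(mrt.significantly_higher(o, h) for o in range(k) if o != h)
        return higher, lower

    calls = []
    for h, name in enumerate(haps):
        fe_up, fe_dn = rel(fe, h)
        zn_up, zn_dn = rel(zn, h)
        cd_up, cd_dn = rel(cd, h)
        gain = fe_up or zn_up
        nutrient_loss = fe_dn or zn_dn
        if gain and not nutrient_loss and not cd_up:
            verdict = "favorable"
        elif gain:
            verdict = "conditional"
        elif nutrient_loss or cd_up:
            verdict = "unfavorable"
        else:
            verdict = "neutral"
        detail = {
            "Fe": "up" if fe_up else ("down" if fe_dn else "ns"),
            "Zn": "up" if zn_up else ("down" if zn_dn else "ns"),
            "Cd": "up" if cd_up else ("down" if cd_dn else "ns"),
        }
        calls.append(FavorableCall(fe.gene_id, fe.subset, name, verdict, detail))
    return calls


# ---------------------------------------------------------------------------
# Gene-screen report and plotting
# ---------------------------------------------------------------------------

def screen_genes(G: GenotypeMatrix, genes: list[GeneModel],
                 phenotypes: pd.DataFrame,
                 traits: tuple[str, ...] = ("Fe", "Zn", "Cd"),
                 subsets: tuple[str, ...] = ("X", "G"),
                 min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Star-level table over genes x (subset x trait) — the screen report."""
    rows = []
    for gene in genes:
        row: dict[str, object] = {"gene_id": gene.gene_id,
                                  "region": f"Chr{gene.chrom}:"
                                            f"{gene.start}-{gene.end}"}
        for subset in subsets:
            assignment = build_haplotypes(G, gene, subset, min_count)
            sub_pheno = phenotypes[phenotypes["subset"] == subset]
            for trait in traits:
                res = star_level(gene, trait, subset, assignment, sub_pheno)
                row[f"{subset}_{trait}"] = res.star
        rows.append(row)
    return pd.DataFrame(rows)


def plot_haplotype_traits(results: list[DuncanResult], out_dir,
                          fmt: str = "png") -> list:
    """One bar plot per gene x trait x subset with letter annotations."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for res in results:
        if not res.hap_names:
            continue
        fig, ax = plt.subplots(figsize=(1.0 + 0.9 * len(res.hap_names), 3.2))
        x = np.arange(len(res.hap_names))
        err = np.where(res.n > 1, res.sds / np.sqrt(np.maximum(res.n, 1)), 0.0)
        ax.bar(x, res.means, yerr=err, color="#74a9cf", capsize=3)
        letters = res.letters.get(0.05, [""] * len(x))
        span = (np.nanmax(res.means + err) - np.nanmin(res.means)) or 1.0
        for i in x:
            ax.text(i, res.means[i] + err[i] + 0.04 * span, letters[i],
                    ha="center", fontsize=9)
        ax.set_xticks(x, res.hap_names)
        ax.set_ylabel(f"{res.trait} (ppm)")
        ax.set_title(f"{res.gene_id} {res.subset}-set {res.trait} [{res.star}]",
                     fontsize=10)
        fig.tight_layout()
        path = out_dir / f"{res.gene_id}_{res.subset}_{res.trait}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def write_haplotype_assignment(assignment: HaplotypeAssignment, path) -> None:
    rows = []
    for i, acc in enumerate(assignment.accession_ids):
        h = assignment.hap_index[i]
        rows.append({
            "accession_id": acc,
            "gene_id": assignment.gene_id,
            "subset": assignment.subset,
            "haplotype": assignment.hap_names[h] if h >= 0
                         else f"EXCLUDED({assignment.excluded_reason[i]})",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
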