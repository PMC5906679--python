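"""Readers, writers and canonical containers for panel genotype/phenotype data.

Conventions used throughout the package:

* Coordinates are 1-based inclusive (VCF style).  Any half-open arithmetic is
  confined to private helpers.
* Genotypes are biallelic SNP dosages counting ALT alleles: 0, 1 (het), 2,
  or :data:`MISSING` (-1).
* The six grain-mineral-concentration (GMC) traits are fixed: Fe, Zn, Cd,
  Mn, Cu, Se, all in ppm of milled-grain dry weight.
* Tab-delimited UTF-8 text everywhere; ``.`` denotes a missing field.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gmcqtl")

MISSING: int = -1
TRAITS: tuple[str, ...] = ("Fe", "Zn", "Cd", "Mn", "Cu", "Se")
SUBSETS: tuple[str, ...] = ("X", "G")

#: Health polarity of each trait: +1 if raising the mineral is beneficial
#: (micronutrients), -1 if harmful (toxic heavy metal).
TRAIT_POLARITY: dict[str, int] = {
    "Fe": +1, "Zn": +1, "Cd": -1, "Mn": +1, "Cu": +1, "Se": +1,
}


class ParseError(ValueError):
    """Raised when an input file violates its expected layout."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically empty."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Snp:
    chrom: str
    pos: int  # 1-based bp
    ref: str
    alt: str
    id: str


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with a RAP-DB-style identifier (e.g. Os06g0489500)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosage matrix (accessions x SNPs).

    ``dosage[i, j]`` counts ALT alleles of accession ``i`` at SNP ``j``;
    heterozygotes are 1 and missing calls are :data:`MISSING`.
    """

    accession_ids: list[str]
    subset: list[str]
    snps: list[Snp]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if len(self.accession_ids) != n or len(self.subset) != n:
            raise ValueError("accession metadata does not match dosage rows")
        if len(self.snps) != m:
            raise ValueError("snp metadata does not match dosage columns")
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession_ids must be unique")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")
        last: dict[str, int] = {}
        for s in self.snps:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(
                    f"positions not strictly increasing on {s.chrom} at {s.pos}")
            last[s.chrom] = s.pos

    # -- basic accessors ---------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    def alt_freq(self) -> np.ndarray:
        """ALT allele frequency per SNP, ignoring missing calls."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def take_accessions(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.accession_ids[i] for i in idx],
            [self.subset[i] for i in idx],
            list(self.snps),
            self.dosage[idx, :],
        )

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.accession_ids),
            list(self.subset),
            [self.snps[i] for i in idx],
            self.dosage[:, idx],
        )

    def subset_mask(self, label: str) -> np.ndarray:
        return np.array([s == label for s in self.subset])

    def snps_in_span(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of SNPs inside [start, end] (1-based inclusive) on chrom."""
        ch = self.chroms
        pos = self.positions
        return np.nonzero((ch == chrom) & (pos >= start) & (pos <= end))[0]


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path,
                   subset_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are dropped.  Heterozygous calls are
    coded 1, missing calls :data:`MISSING`.  Accessions absent from
    ``subset_map`` are labeled ``UNKNOWN`` with a warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise ParseError(f"{path}: not a readable VCF ({exc})") from exc

    samples = list(vcf.samples)
    subset_map = subset_map or {}
    subset = []
    for s in samples:
        lab = subset_map.get(s)
        if lab is None:
            logger.warning("accession %s absent from subset map; labeled UNKNOWN", s)
            lab = "UNKNOWN"
        subset.append(lab)

    snps: list[Snp] = []
    rows: list[np.ndarray] = []
    for i, var in enumerate(vcf):
        try:
            if len(var.ALT) != 1:
                continue
            ref, alt = var.REF, var.ALT[0]
            if len(ref) != 1 or len(alt) != 1 or "<" in alt:
                continue
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            g = np.asarray(var.gt_types, dtype=np.int8)
            g[g == 3] = MISSING
            snps.append(Snp(var.CHROM, var.POS, ref, alt,
                            var.ID or f"{var.CHROM}_{var.POS}"))
            rows.append(g)
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"{path}: malformed VCF record #{i + 1} ({exc})") from exc

    if not snps:
        dosage = np.zeros((len(samples), 0), dtype=np.int8)
        return GenotypeMatrix(samples, subset, [], dosage)

    order = sorted(range(len(snps)), key=lambda j: (snps[j].chrom, snps[j].pos))
    dosage = np.stack([rows[j] for j in order], axis=1)
    return GenotypeMatrix(samples, subset, [snps[j] for j in order], dosage)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file."""
    path = Path(path)
    contigs = list(dict.fromkeys(s.chrom for s in G.snps))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gmcqtl\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.accession_ids) + "\n")
        for j, s in enumerate(G.snps):
            gts = "\t".join(_GT_STR[int(d)] for d in G.dosage[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype table (accession, subset, Fe..Se in ppm)."""
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str, "subset": str},
                     na_values=["."])
    required = ["accession_id", "subset", *TRAITS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing phenotype columns {missing}")
    for t in TRAITS:
        df[t] = pd.to_numeric(df[t], errors="raise")
        if (df[t].dropna() < 0).any():
            raise ParseError(f"{path}: negative {t} concentration")
    return df[required]


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    out = pheno.copy()
    for t in TRAITS:
        out[t] = out[t].map(lambda v: "." if pd.isna(v) else format(v, ".6g"))
    out.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV (gene_id/chrom/start/end[/strand/annotation])
    or a GFF3 file (``gene`` features, ID attribute)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.read(512)
    if head.startswith("##gff-version") or path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gene_models_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = []
    for _, r in df.iterrows():
        genes.append(GeneModel(r["gene_id"], str(r["chrom"]), int(r["start"]),
                               int(r["end"]), str(r.get("strand", "+")),
                               str(r.get("annotation", "") or "")))
    _check_unique_genes(genes)
    return genes


def _read_gene_models_gff3(path: Path) -> list[GeneModel]:
    genes = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln}: not 9 GFF3 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                raise ParseError(f"{path}:{ln}: gene feature without ID")
            genes.append(GeneModel(gid, parts[0], int(parts[3]), int(parts[4]),
                                   parts[6], attrs.get("Note", "")))
    _check_unique_genes(genes)
    return genes


def _check_unique_genes(genes: list[GeneModel]) -> None:
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"duplicate gene ids: {dup}")


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.annotation or ".")
            for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand",
                                "annotation"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QTL table (printed-table layout)
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^\s*([\d,]+)\s*~\s*([\d,]+)\s*$")

QTL_COLUMNS = ["trait", "cluster", "locus", "chrom", "start", "end",
               "minus_log10", "fae", "linkage_qtl", "literature"]


def _num(text: str, what: str, where: str) -> float:
    # tolerate thousands separators and the typographic minus sign
    cleaned = text.replace(",", "").replace("−", "-").strip()
    try:
        return float(cleaned)
    except ValueError as exc:
        raise ParseError(f"{where}: non-numeric {what} {text!r}") from exc


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    """Parse a QTL table in the printed-table layout.

    Trait and Cd-cluster labels appear only on the first row of their block
    and are propagated downward; ranges are ``start~end`` with optional
    thousands separators.  Returns a DataFrame with :data:`QTL_COLUMNS`.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=QTL_COLUMNS)
    if raw.empty:
        return pd.DataFrame(columns=QTL_COLUMNS)
    need = {"trait", "cluster", "locus", "chrom", "range", "minus_log10", "fae"}
    if not need.issubset(raw.columns):
        raise ParseError(f"{path}: expected columns {sorted(need)}")

    rows = []
    trait = ""
    cluster = ""
    for _, r in raw.iterrows():
        if r["trait"].strip():
            trait = r["trait"].strip()
            cluster = ""  # cluster blocks never span traits
        locus = r["locus"].strip()
        where = f"{path}: locus {locus or '?'}"
        if trait == "Cd":
            if r["cluster"].strip():
                cluster = r["cluster"].strip()
            clab = cluster
        else:
            clab = ""  # only Cd loci carry cluster labels
        m = _RANGE_RE.match(r["range"])
        if not m:
            raise ParseError(f"{where}: bad range {r['range']!r}")
        start = int(_num(m.group(1), "range start", where))
        end = int(_num(m.group(2), "range end", where))
        if start > end:
            raise ParseError(f"{where}: range start {start} > end {end}")
        rows.append({
            "trait": trait,
            "cluster": clab,
            "locus": locus,
            "chrom": str(r["chrom"]).strip(),
            "start": start,
            "end": end,
            "minus_log10": _num(r["minus_log10"], "-log10", where),
            "fae": _num(r["fae"], "FAE", where),
            "linkage_qtl": (r.get("linkage_qtl") or "").strip(),
            "literature": (r.get("literature") or "").strip(),
        })
    df = pd.DataFrame(rows, columns=QTL_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_qtl_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a QTL table back in the printed layout (round-trips with
    :func:`read_qtl_table`)."""
    out_rows = []
    prev_trait = prev_cluster = None
    for _, r in table.iterrows():
        trait = r["trait"] if r["trait"] != prev_trait else ""
        if trait:
            prev_cluster = None
        clab = r["cluster"]
        cluster = clab if (clab and clab != prev_cluster) else ""
        out_rows.append({
            "trait": trait, "cluster": cluster, "locus": r["locus"],
            "chrom": r["chrom"], "range": f"{int(r['start'])}~{int(r['end'])}",
            "minus_log10": format(r["minus_log10"], "g"),
            "fae": format(r["fae"], "g"),
            "linkage_qtl": r.get("linkage_qtl", ""),
            "literature": r.get("literature", ""),
        })
        prev_trait, prev_cluster = r["trait"], clab or prev_cluster
    pd.DataFrame(out_rows).to_csv(path, sep="\t", index=False)


def load_published_qtl_table() -> pd.DataFrame:
    """The packaged published QTL table (80 GMC loci) as a parsed DataFrame."""
    with resources.as_file(resources.files("gmcqtl").joinpath("data/published_qtl_table.tsv")) as p:
        return read_qtl_table(p)


# ---------------------------------------------------------------------------
# Support intervals (linkage-mapping QTL and literature QTL)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SupportInterval:
    """An externally mapped QTL interval used as confirming evidence."""

    name: str
    chrom: str
    start: int
    end: int
    source: str  # "linkage" or "literature"
    trait: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")


_TRAIT_FROM_NAME = re.compile(r"^q([A-Z][a-z]?)")


def infer_trait_from_name(name: str) -> str:
    m = _TRAIT_FROM_NAME.match(name)
    if m and m.group(1) in TRAITS:
        return m.group(1)
    return ""


def read_support_intervals(path: str | Path) -> list[SupportInterval]:
    """Read support intervals (name, chrom, start, end, source[, trait]).

    Names are labels, not keys: duplicates are retained.  When no trait
    column is given the trait is inferred from a ``q<Trait>...`` name.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return []
    need = {"name", "chrom", "start", "end", "source"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(need)}")
    out = []
    for _, r in df.iterrows():
        trait = r.get("trait", "") or infer_trait_from_name(r["name"])
        try:
            iv = SupportInterval(r["name"], str(r["chrom"]),
                                 int(_num(r["start"], "start", r["name"])),
                                 int(_num(r["end"], "end", r["name"])),
                                 r["source"], trait)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        out.append(iv)
    return out


def write_support_intervals(intervals: Iterable[SupportInterval],
                            path: str | Path) -> None:
    rows = [(iv.name, iv.chrom, iv.start, iv.end, iv.source, iv.trait)
            for iv in intervals]
    pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "source",
                                "trait"]).to_csv(path, sep="\t", index=False)


def support_from_qtl_table(table: pd.DataFrame) -> list[SupportInterval]:
    """Build support intervals from a QTL table's own support columns.

    Each locus with a linkage (or literature) annotation contributes one
    interval named after the supporting QTL, spanning the locus range — a
    self-consistent support set for regression tests and re-annotation.
    """
    out = []
    for _, r in table.iterrows():
        if r["linkage_qtl"]:
            out.append(SupportInterval(r["linkage_qtl"], r["chrom"],
                                       int(r["start"]), int(r["end"]),
                                       "linkage", r["trait"]))
        if r["literature"]:
            for code in str(r["literature"]).split(";"):
                code = code.strip()
                if code:
                    out.append(SupportInterval(code, r["chrom"],
                                               int(r["start"]), int(r["end"]),
                                               "literature", r["trait"]))
    return out


# ---------------------------------------------------------------------------
# Shared-marker extraction
# ---------------------------------------------------------------------------

def shared_markers(a: GenotypeMatrix, b: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Indices of SNPs shared by two genotype sets.

    Markers match on (chrom, pos, ref, alt) — position plus allele identity.
    Returns aligned index arrays (idx_a, idx_b).
    """
    key_a = {(s.chrom, s.pos, s.ref, s.alt): j for j, s in enumerate(a.snps)}
    ia, ib = [], []
    for j, s in enumerate(b.snps):
        k = (s.chrom, s.pos, s.ref, s.alt)
        if k in key_a:
            ia.append(key_a[k])
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)
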