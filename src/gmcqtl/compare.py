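"""Comparative mapping: confirm called loci against external QTL intervals.

A locus is supported by a linkage-mapping or literature QTL interval iff
the two ranges share at least one base pair on the same chromosome
(1-based inclusive, so touching endpoints count) and — by default — concern
the same trait: a Cd locus can only be confirmed by a Cd QTL.
"""

from __future__ import annotations

from .core_io import SupportInterval
from .loci import QtlLocus


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """1-based inclusive interval intersection (>= 1 shared bp)."""
    return a_start <= b_end and b_start <= a_end


def overlap_support(loci: list[QtlLocus], support: list[SupportInterval],
                    trait_match: bool = True) -> list[QtlLocus]:
    """Fill linkage_support / literature_support on each locus in place.

    Multi-source support is preserved: one linkage name (first match) plus
    every distinct literature code.  Returns the same list for chaining.
    """
    for locus in loci:
        linkage = ""
        literature: list[str] = []
        for iv in support:
            if iv.chrom != locus.chrom:
                continue
            if trait_match and iv.trait and iv.trait != locus.trait:
                continue
            if not intervals_overlap(locus.start, locus.end, iv.start, iv.end):
                continue
            if iv.source == "linkage":
                if not linkage:
                    linkage = iv.name
            elif iv.name not in literature:
                literature.append(iv.name)
        locus.linkage_support = linkage
        locus.literature_support = literature
    return loci


def count_joint_support(loci: list[QtlLocus]) -> tuple[int, int, int]:
    """(n with linkage support, n with literature support, n with both)."""
    n_link = sum(1 for l in loci if l.linkage_support)
    n_lit = sum(1 for l in loci if l.literature_support)
    n_multi = sum(1 for l in loci if l.linkage_support and l.literature_support)
    return n_link, n_lit, n_multi
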