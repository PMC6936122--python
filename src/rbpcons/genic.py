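"""Strand-aware genic thirds and positional conservation comparisons.

Each gene span is cut into three segments of (near-)equal length,
labeled 5', middle and 3' in the direction of transcription: on a '-'
strand gene the 5' segment has the larger genomic coordinates. Binding
sites are assigned to the segment containing their midpoint, and
per-region conservation distributions are compared pairwise with
rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .conservation import ConservationRecord, compare_groups
from .io import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

REGIONS = ("5prime", "middle", "3prime")
PAIRWISE = (("3prime", "5prime"), ("3prime", "middle"), ("middle", "5prime"))


@dataclass
class GeneSegments:
    gene: GeneModel
    five_prime: GenomicInterval
    middle: GenomicInterval
    three_prime: GenomicInterval

    def region_of(self, position: int) -> str | None:
        """Region label of a genomic position, or None if outside the gene."""
        for label, seg in (
            ("5prime", self.five_prime),
            ("middle", self.middle),
            ("3prime", self.three_prime),
        ):
            if seg.start <= position < seg.end:
                return label
        return None


def segment_gene(
    gene: GeneModel, remainder: Literal["last", "first"] = "last"
) -> GeneSegments:
    """Cut a gene span into transcription-ordered thirds.

    Integer division leaves 0-2 remainder bp, distributed one each to
    the transcriptionally-last segments by default (``remainder="first"``
    gives them to the earliest segments instead). Segment lengths never
    differ by more than 1 bp.
    """
    length = len(gene)
    if length < 3:
        raise ValueError(f"gene {gene.gene_id}: length {length} < 3")
    base, rem = divmod(length, 3)
    lengths = [base, base, base]  # transcription order: 5', middle, 3'
    extra_positions = range(2, 2 - rem, -1) if remainder == "last" else range(rem)
    for i in extra_positions:
        lengths[i] += 1
    if gene.strand == "-":
        lengths = lengths[::-1]  # genomic order = reversed transcription order
    b0 = gene.start
    b1 = b0 + lengths[0]
    b2 = b1 + lengths[1]
    genomic = [
        GenomicInterval(gene.chrom, b0, b1),
        GenomicInterval(gene.chrom, b1, b2),
        GenomicInterval(gene.chrom, b2, gene.end),
    ]
    if gene.strand == "+":
        five, mid, three = genomic
    else:
        three, mid, five = genomic
    return GeneSegments(gene, five, mid, three)


@dataclass
class RegionAssignment:
    site: GenomicInterval
    gene_id: str
    region: str
    percent: float
    rbp_name: str = ""


def assign_sites(
    records: Iterable[ConservationRecord],
    genes: Sequence[GeneModel],
    rbp_name: str = "",
    remainder: Literal["last", "first"] = "last",
) -> list[RegionAssignment]:
    """Assign mapped binding sites to genic thirds by site midpoint.

    A site overlapping several genes yields one assignment per gene
    whose span contains the site's midpoint; intergenic sites are
    dropped. Only mapped records (with a defined conservation percent)
    are assigned.
    """
    trees: dict[str, IntervalTree] = {}
    segments: dict[str, GeneSegments] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
        segments[g.gene_id] = segment_gene(g, remainder=remainder)
    out: list[RegionAssignment] = []
    for rec in records:
        if not rec.mapped:
            continue
        mid = rec.site.midpoint
        tree = trees.get(rec.site.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.at(mid), key=lambda iv: iv.data):
            region = segments[hit.data].region_of(mid)
            if region is not None:
                out.append(
                    RegionAssignment(rec.site, hit.data, region, rec.percent, rbp_name)
                )
    return out


def region_comparison(
    assignments: Iterable[RegionAssignment], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Per-RBP region medians and pairwise rank-sum tests.

    Returns (medians, tests, summary): ``medians`` has one row per
    (rbp, region) with site count and median conservation percent;
    ``tests`` one row per (rbp, comparison) with the two-sided rank-sum
    p-value (raw, per the per-RBP testing scheme); ``summary`` counts
    RBPs where the 3' region is significantly more conserved than the
    5' at the given alpha ("n_3prime_gt_5prime" out of "n_tested").
    RBPs with fewer than two non-empty regions are skipped with a
    warning.
    """
    frame = pd.DataFrame(
        [
            {"rbp": a.rbp_name, "region": a.region, "percent": a.percent}
            for a in assignments
        ]
    )
    if frame.empty:
        raise ValueError("no assignments to compare")
    median_rows, test_rows = [], []
    n_sig_3v5 = 0
    n_tested = 0
    for rbp, sub in frame.groupby("rbp", sort=True):
        values = {
            r: sub.loc[sub.region == r, "percent"].to_numpy() for r in REGIONS
        }
        nonempty = [r for r in REGIONS if values[r].size > 0]
        for r in REGIONS:
            if values[r].size:
                median_rows.append(
                    {
                        "rbp": rbp, "region": r, "n_sites": int(values[r].size),
                        "median_percent": float(np.median(values[r])),
                    }
                )
        if len(nonempty) < 2:
            logger.warning("RBP %s: all sites in one region, skipped", rbp)
            continue
        for ra, rb in PAIRWISE:
            if values[ra].size == 0 or values[rb].size == 0:
                continue
            _, p = compare_groups(values[ra], values[rb])
            test_rows.append(
                {"rbp": rbp, "comparison": f"{ra}_vs_{rb}", "p_value": p}
            )
            if ra == "3prime" and rb == "5prime":
                n_tested += 1
                if p < alpha and np.median(values[ra]) > np.median(values[rb]):
                    n_sig_3v5 += 1
    medians = pd.DataFrame(
        median_rows, columns=["rbp", "region", "n_sites", "median_percent"]
    )
    tests = pd.DataFrame(test_rows, columns=["rbp", "comparison", "p_value"])
    summary = {"n_3prime_gt_5prime": n_sig_3v5, "n_tested": n_tested}
    return medians, tests, summary
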