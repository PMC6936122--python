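"""Binding-site conservation: block mapping and the conservation percent P.

A 20 bp binding site "maps" when it is fully contained in the reference
span of one alignment block; the conservation percent of a mapped site is

    P = (N / total_species) * 100

where N is the number of distinct species with a row in that block
(reference included). Unmapped sites are excluded from distributions by
default but counted; a ``P = 0`` treatment is available via
``unmapped_as_zero``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import GenomicInterval, MafBlock

logger = logging.getLogger(__name__)

#: species count of the UCSC 46-way vertebrate alignment (reference included)
DEFAULT_TOTAL_SPECIES = 46


@dataclass
class BlockIndex:
    """Per-chromosome interval index over block reference spans.

    Lookup returns every stored block whose reference span fully
    contains the query interval.
    """

    _trees: dict[str, IntervalTree] = field(default_factory=dict)
    blocks: list[MafBlock] = field(default_factory=list)

    def add(self, block: MafBlock) -> int:
        block_id = len(self.blocks)
        self.blocks.append(block)
        tree = self._trees.setdefault(block.ref_chrom, IntervalTree())
        tree.addi(block.ref_start, block.ref_end, block_id)
        return block_id

    def containing(self, chrom: str, start: int, end: int) -> list[int]:
        """Ids of blocks whose reference span contains [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        return sorted(
            iv.data for iv in hits if iv.begin <= start and iv.end >= end
        )

    def __len__(self) -> int:
        return len(self.blocks)


def index_blocks(blocks: Iterable[MafBlock]) -> BlockIndex:
    """Build a containment index over block reference spans."""
    index = BlockIndex()
    for block in blocks:
        index.add(block)
    return index


@dataclass
class ConservationRecord:
    site: GenomicInterval
    mapped: bool
    block_id: int | None = None
    n_species: int = 0
    percent: float = float("nan")
    species: frozenset[str] = frozenset()


def _select_block(index: BlockIndex, candidate_ids: Sequence[int]) -> int:
    # highest score wins; ties broken by lowest reference start
    return min(
        candidate_ids,
        key=lambda i: (-index.blocks[i].score, index.blocks[i].ref_start),
    )


def map_site(
    site: GenomicInterval, index: BlockIndex, total_species: int = DEFAULT_TOTAL_SPECIES
) -> ConservationRecord:
    """Map one binding site to its containing block and compute P.

    A site maps only when fully contained in a single block's reference
    span; when several blocks contain it (possible in non-multiz input)
    the highest-scoring block is chosen, ties broken by lowest reference
    start. Unmapped sites get ``mapped=False`` and an undefined P.
    """
    if total_species < 1:
        raise ValueError("total_species must be >= 1")
    ids = index.containing(site.chrom, site.start, site.end)
    if not ids:
        return ConservationRecord(site=site, mapped=False)
    block_id = _select_block(index, ids)
    species = index.blocks[block_id].species_set
    n = len(species)
    return ConservationRecord(
        site=site,
        mapped=True,
        block_id=block_id,
        n_species=n,
        percent=n / total_species * 100.0,
        species=species,
    )


@dataclass
class ConservationProfile:
    """All conservation records of one RBP's binding sites."""

    rbp_name: str
    records: list[ConservationRecord]
    total_species: int

    @property
    def n_mapped(self) -> int:
        return sum(r.mapped for r in self.records)

    @property
    def n_unmapped(self) -> int:
        return len(self.records) - self.n_mapped

    def percents(self, unmapped_as_zero: bool = False) -> np.ndarray:
        """Conservation percents; by default over mapped sites only."""
        if unmapped_as_zero:
            return np.array(
                [r.percent if r.mapped else 0.0 for r in self.records]
            )
        return np.array([r.percent for r in self.records if r.mapped])

    def median(self, unmapped_as_zero: bool = False) -> float:
        values = self.percents(unmapped_as_zero)
        if values.size == 0:
            return float("nan")
        return float(np.median(values))

    def quartiles(self) -> tuple[float, float, float]:
        values = self.percents()
        if values.size == 0:
            return (float("nan"),) * 3
        q1, q2, q3 = np.percentile(values, [25, 50, 75])
        return float(q1), float(q2), float(q3)


def profile_rbp(
    sites: Iterable[GenomicInterval],
    index: BlockIndex,
    total_species: int = DEFAULT_TOTAL_SPECIES,
    rbp_name: str = "",
) -> ConservationProfile:
    """Score every binding site of one RBP against the block index."""
    records = [map_site(s, index, total_species) for s in sites]
    profile = ConservationProfile(rbp_name, records, total_species)
    if profile.n_mapped == 0:
        logger.warning("RBP %s: no binding site mapped to any block", rbp_name)
    return profile


def species_presence_matrix(
    profiles: Sequence[ConservationProfile],
    species_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-RBP, per-species presence matrix (percent of mapped sites).

    Cell (r, s) = 100 x fraction of RBP r's mapped sites whose block
    contains species s. The reference species column is 100 for any RBP
    with at least one mapped site.
    """
    all_species: set[str] = set()
    for p in profiles:
        for r in p.records:
            if r.mapped:
                all_species.update(r.species)
    columns = list(species_order) if species_order is not None else sorted(all_species)
    data = np.zeros((len(profiles), len(columns)))
    col_pos = {s: j for j, s in enumerate(columns)}
    for i, p in enumerate(profiles):
        mapped = [r for r in p.records if r.mapped]
        if not mapped:
            data[i, :] = np.nan
            continue
        for r in mapped:
            for s in r.species:
                if s in col_pos:
                    data[i, col_pos[s]] += 1
        data[i, :] *= 100.0 / len(mapped)
    return pd.DataFrame(data, index=[p.rbp_name for p in profiles], columns=columns)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Exact enumeration for groups of at most 50 without ties; otherwise
    the tie-corrected normal approximation. Returns (U statistic, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= 50 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def clade_comparison(
    matrix: pd.DataFrame, clade_map: Mapping[str, str], clade_a: str, clade_b: str
) -> tuple[float, float]:
    """Compare presence values between two clades of species columns.

    Pools the matrix cells of each clade's species columns (e.g. the 37
    mammals vs the 9 lower vertebrates) and applies the rank-sum test.
    """
    cols_a = [s for s in matrix.columns if clade_map.get(s) == clade_a]
    cols_b = [s for s in matrix.columns if clade_map.get(s) == clade_b]
    if not cols_a or not cols_b:
        raise ValueError(f"no species columns for clade {clade_a!r} or {clade_b!r}")
    vals_a = matrix[cols_a].to_numpy().ravel()
    vals_b = matrix[cols_b].to_numpy().ravel()
    vals_a = vals_a[~np.isnan(vals_a)]
    vals_b = vals_b[~np.isnan(vals_b)]
    return compare_groups(vals_a, vals_b)


def records_to_frame(profile: ConservationProfile) -> pd.DataFrame:
    """Flatten a profile into the TSV-ready record table."""
    rows = []
    for r in profile.records:
        rows.append(
            {
                "chrom": r.site.chrom,
                "start": r.site.start,
                "end": r.site.end,
                "name": r.site.name,
                "mapped": int(r.mapped),
                "block_id": r.block_id if r.mapped else -1,
                "n_species": r.n_species,
                "percent": r.percent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "mapped", "block_id",
            "n_species", "percent",
        ],
    )
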