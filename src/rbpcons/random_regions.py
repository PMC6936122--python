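"""Random-region null sets for conservation comparisons.

Random 20 bp regions drawn from genomic, exonic, intronic or
protein-coding annotation spaces serve as the null against which
binding-site conservation is compared. Sampling is uniform over
eligible start positions pooled across the space's intervals
(length-weighted interval choice); overlaps among draws are allowed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .conservation import BlockIndex, ConservationProfile, compare_groups, profile_rbp
from .io import GenomicInterval

logger = logging.getLogger(__name__)

REGION_TYPES = ("genomic", "exonic", "intronic", "coding")


@dataclass
class AnnotationSpace:
    """A sampleable set of intervals of one region type."""

    region_type: str
    intervals: list[GenomicInterval]
    chrom_sizes: Mapping[str, int]

    def __post_init__(self):
        if self.region_type not in REGION_TYPES:
            raise ValueError(
                f"region_type must be one of {REGION_TYPES}, got {self.region_type!r}"
            )
        for iv in self.intervals:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None or iv.end > size:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome bounds"
                )

    @classmethod
    def whole_genome(cls, chrom_sizes: Mapping[str, int]) -> "AnnotationSpace":
        intervals = [
            GenomicInterval(c, 0, size) for c, size in chrom_sizes.items()
        ]
        return cls("genomic", intervals, dict(chrom_sizes))


def sample_regions(
    space: AnnotationSpace, count: int, length: int, seed: int
) -> list[GenomicInterval]:
    """Draw ``count`` regions of exactly ``length`` bp from the space.

    Each draw lands fully inside one interval of the space, uniformly
    over all eligible start positions (intervals weighted by their
    number of eligible positions). Intervals shorter than ``length``
    are skipped with a warning. Deterministic under ``seed``.
    """
    if count <= 0:
        raise ValueError("count must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    eligible = []
    weights = []
    for iv in space.intervals:
        n_pos = len(iv) - length + 1
        if n_pos <= 0:
            logger.warning(
                "skipping interval %s:%d-%d: shorter than %d bp",
                iv.chrom, iv.start, iv.end, length,
            )
            continue
        eligible.append(iv)
        weights.append(n_pos)
    if not eligible:
        raise ValueError("no interval in the space can hold a region of this length")
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    which = rng.choice(len(eligible), size=count, p=weights / weights.sum())
    out = []
    for k, idx in enumerate(which):
        iv = eligible[idx]
        start = iv.start + int(rng.integers(0, len(iv) - length + 1))
        out.append(
            GenomicInterval(
                iv.chrom, start, start + length,
                name=f"{space.region_type}_rand_{k}",
            )
        )
    return out


def null_profile(
    space: AnnotationSpace,
    count: int,
    length: int,
    n_replicates: int,
    seed_base: int,
    index: BlockIndex,
    total_species: int,
) -> tuple[list[ConservationProfile], dict[str, float]]:
    """Score ``n_replicates`` independent random-region datasets.

    Returns the replicate profiles plus a replicate-agreement summary:
    the minimum and maximum pairwise rank-sum p over all replicate
    pairs (a non-significant minimum means even the most discrepant
    pair of replicates is statistically indistinguishable, justifying
    the use of a single representative replicate).
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    profiles = []
    for rep in range(n_replicates):
        regions = sample_regions(space, count, length, seed=seed_base + rep)
        profiles.append(
            profile_rbp(
                regions, index, total_species,
                rbp_name=f"{space.region_type}_null_rep{rep}",
            )
        )
    pvals = []
    for p1, p2 in itertools.combinations(profiles, 2):
        a, b = p1.percents(), p2.percents()
        if a.size and b.size:
            pvals.append(compare_groups(a, b)[1])
    agreement = {
        "min_pairwise_p": float(min(pvals)) if pvals else float("nan"),
        "max_pairwise_p": float(max(pvals)) if pvals else float("nan"),
    }
    return profiles, agreement
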