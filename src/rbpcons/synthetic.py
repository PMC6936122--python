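"""Synthetic fixtures with planted, recoverable ground truth.

Every generator emulates one input of the conservation pipeline:

* ``simulate_maf`` — alignment blocks tiling a reference genome, each
  non-reference species present independently with its clade's
  retention probability (the primate-to-fish conservation gradient is
  planted as a high-retention vs low-retention clade split).
* ``simulate_sites`` — 20 bp binding sites per RBP, placed inside
  blocks (mappable) or across block boundaries (a planted unmappable
  fraction), optionally routed to designated gene thirds or to a
  designated block class.
* ``simulate_feature_table`` — an RBP-centric feature table whose
  response is a linear function of one planted informative feature
  plus Gaussian noise.
* ``simulate_gene_sets`` — a gene-set collection with one planted set
  whose member scores are shifted upward.

All generators are deterministic under their seed, and each returns a
truth table from which the expected downstream statistic can be
computed up to sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneScoreTable
from .genic import RegionAssignment, segment_gene
from .io import AlignmentRow, GeneModel, GeneSet, GenomicInterval, MafBlock

_ALPHABET = np.array(list("ACGT"))

#: Table-1-style RBP-centric feature names (the planted table's columns)
FEATURE_NAMES = [
    "tsi_tau",
    "n_binding_sites",
    "transcript_length",
    "ppi_count",
    "protein_expression_median",
    "transcript_expression_median",
    "rna_binding_domains",
    "n_paralogs",
    "subcellular_compartments",
    "rbp_conservation",
    "rbp_rbp_interactions",
]


@dataclass(frozen=True)
class CladeSpec:
    """A clade of species sharing one block-retention probability."""

    name: str
    species: tuple[str, ...]
    retention_prob: float

    def __post_init__(self):
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in [0, 1]")


def default_clades() -> list[CladeSpec]:
    """37 mammal-like + 9 lower-vertebrate-like species (46 with the
    reference), echoing the 46-way vertebrate alignment's composition.

    Retention 0.9 vs 0.2 plants the strong-in-mammals, weak-in-lower-
    vertebrates gradient the real alignments show.
    """
    mammals = CladeSpec(
        "mammal", tuple(f"mam{i:02d}" for i in range(1, 37)), 0.9
    )
    lower = CladeSpec(
        "lower_vertebrate", tuple(f"low{i:02d}" for i in range(1, 10)), 0.2
    )
    return [mammals, lower]


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic run.

    Defaults mirror the real study's shape at desk scale: 46 species
    (reference + 36 high-retention + 9 low-retention), 60 RBPs with
    20 bp sites, a 10% unmappable site fraction, and one planted
    informative feature and gene set.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000}
    )
    block_length_range: tuple[int, int] = (100, 300)
    gap_fraction: float = 0.0
    reference_species: str = "hg"
    clades: list[CladeSpec] = field(default_factory=default_clades)
    #: class name -> (fraction of blocks, retention multiplier)
    block_classes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"background": (1.0, 1.0)}
    )
    n_rbps: int = 60
    sites_per_rbp: int = 200
    site_length: int = 20
    unmappable_fraction: float = 0.1
    #: when set, mappable sites prefer blocks of this class
    site_block_class: str | None = None
    #: per-RBP probability of choosing site_block_class (None -> always)
    rbp_tiers: list[float] | None = None
    #: region label -> routing probability for mappable sites
    positional_bias: dict[str, float] | None = None
    #: (feature name, effect size on the response, in percent points)
    planted_feature: tuple[str, float] | None = ("n_binding_sites", -15.0)
    feature_noise_sd: float = 5.0
    #: (set name, score shift in percent points)
    planted_gene_set: tuple[str, float] | None = ("planted_set", 30.0)
    n_gene_sets: int = 10
    gene_set_size: int = 30
    gene_length_range: tuple[int, int] = (1500, 3000)
    gene_gap_range: tuple[int, int] = (200, 500)
    seed: int = 0

    def __post_init__(self):
        if self.n_rbps <= 0 or self.sites_per_rbp < 0 or self.site_length <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.unmappable_fraction <= 1.0:
            raise ValueError("unmappable_fraction must be in [0, 1]")
        seen: set[str] = set()
        for clade in self.clades:
            overlap = seen & set(clade.species)
            if overlap:
                raise ValueError(f"species in multiple clades: {sorted(overlap)}")
            seen.update(clade.species)

    @property
    def total_species(self) -> int:
        return 1 + sum(len(c.species) for c in self.clades)

    @property
    def clade_map(self) -> dict[str, str]:
        out = {self.reference_species: "reference"}
        for clade in self.clades:
            for s in clade.species:
                out[s] = clade.name
        return out

    @property
    def rbp_names(self) -> list[str]:
        return [f"RBP{i:02d}" for i in range(1, self.n_rbps + 1)]


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def simulate_maf(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[list[MafBlock], pd.DataFrame]:
    """Generate alignment blocks plus a per-block truth table.

    Blocks tile each chromosome without overlap (a ``gap_fraction`` of
    tiles is skipped to create unmappable territory). The reference
    species is always present; every other species is present
    independently with its clade's retention probability, scaled by the
    block class's retention multiplier. Sequence content is uniform
    random A/C/G/T placeholder text, irrelevant to every downstream
    statistic.

    Truth columns: block_id, chrom, start, end, block_class, n_species,
    species (comma-joined).
    """
    if not scenario.chrom_lengths:
        raise ValueError("scenario must define at least one chromosome")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    lo, hi = scenario.block_length_range
    class_names = list(scenario.block_classes)
    class_fracs = np.array([scenario.block_classes[c][0] for c in class_names])
    class_fracs = class_fracs / class_fracs.sum()

    species_all: list[str] = []
    retention: list[float] = []
    for clade in scenario.clades:
        for s in clade.species:
            species_all.append(s)
            retention.append(clade.retention_prob)
    retention_arr = np.array(retention)

    blocks: list[MafBlock] = []
    truth_rows = []
    for chrom, chrom_len in scenario.chrom_lengths.items():
        pos = 0
        while pos + lo <= chrom_len:
            length = int(rng.integers(lo, hi + 1))
            length = min(length, chrom_len - pos)
            start = pos
            pos += length
            if scenario.gap_fraction > 0 and rng.random() < scenario.gap_fraction:
                continue
            cls = class_names[int(rng.choice(len(class_names), p=class_fracs))]
            mult = scenario.block_classes[cls][1]
            probs = np.minimum(1.0, retention_arr * mult)
            present = rng.random(len(species_all)) < probs
            text = "".join(rng.choice(_ALPHABET, size=length))
            rows = [
                AlignmentRow(
                    src=f"{scenario.reference_species}.{chrom}",
                    start=start, size=length, strand="+",
                    src_size=chrom_len, text=text,
                )
            ]
            for s, keep in zip(species_all, present):
                if keep:
                    rows.append(
                        AlignmentRow(
                            src=f"{s}.{chrom}_scaf", start=start, size=length,
                            strand="+", src_size=chrom_len, text=text,
                        )
                    )
            block = MafBlock(score=float(np.round(rng.uniform(0, 100000), 1)), rows=rows)
            blocks.append(block)
            truth_rows.append(
                {
                    "block_id": len(blocks) - 1,
                    "chrom": chrom,
                    "start": start,
                    "end": start + length,
                    "block_class": cls,
                    "n_species": 1 + int(present.sum()),
                    "species": ",".join(
                        [scenario.reference_species]
                        + [s for s, k in zip(species_all, present) if k]
                    ),
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "block_id", "chrom", "start", "end", "block_class", "n_species", "species",
        ],
    )
    return blocks, truth


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------


def simulate_genes(
    scenario: SyntheticScenario, seed: int | None = None
) -> list[GeneModel]:
    """Tile non-overlapping genes with random strands along each chromosome."""
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 101
    )
    glo, ghi = scenario.gene_length_range
    gap_lo, gap_hi = scenario.gene_gap_range
    genes: list[GeneModel] = []
    idx = 0
    for chrom, chrom_len in scenario.chrom_lengths.items():
        pos = int(rng.integers(gap_lo, gap_hi + 1))
        while pos + glo <= chrom_len:
            length = int(rng.integers(glo, ghi + 1))
            if pos + length > chrom_len:
                break
            idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{idx:04d}", symbol=f"GENE{idx}",
                    chrom=chrom, start=pos, end=pos + length,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            pos += length + int(rng.integers(gap_lo, gap_hi + 1))
    return genes


# ---------------------------------------------------------------------------
# Binding sites
# ---------------------------------------------------------------------------


def _block_spans(blocks: Sequence[MafBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block_id": range(len(blocks)),
            "chrom": [b.ref_chrom for b in blocks],
            "start": [b.ref_start for b in blocks],
            "end": [b.ref_end for b in blocks],
        }
    )


def simulate_sites(
    scenario: SyntheticScenario,
    blocks: Sequence[MafBlock],
    genes: Sequence[GeneModel] | None = None,
    block_truth: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[dict[str, list[GenomicInterval]], pd.DataFrame]:
    """Place per-RBP binding sites with known mappability and position.

    A fraction ``unmappable_fraction`` of sites straddles a block's end
    boundary (never fully contained in any block, hence unmapped under
    the containment rule). Mappable sites are placed fully inside a
    block; ``positional_bias`` routes them to designated gene thirds by
    rejection sampling, ``site_block_class`` restricts them to blocks
    of that class (per-RBP probability from ``rbp_tiers``).

    Truth columns: rbp, name, chrom, start, end, intended_mappable,
    block_class, intended_region.
    """
    if not blocks:
        raise ValueError("need at least one block")
    length = scenario.site_length
    min_block = min(b.ref_end - b.ref_start for b in blocks)
    if length > min_block:
        raise ValueError(
            f"site length {length} exceeds shortest block length {min_block}"
        )
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 202
    )
    by_class: dict[str, list[int]] = {}
    if block_truth is not None:
        for bid, cls in zip(block_truth["block_id"], block_truth["block_class"]):
            by_class.setdefault(cls, []).append(int(bid))
    all_ids = list(range(len(blocks)))

    segments = None
    if scenario.positional_bias:
        if genes is None:
            raise ValueError("positional_bias requires genes")
        segments = [segment_gene(g) for g in genes]
        bias_regions = list(scenario.positional_bias)
        bias_probs = np.array([scenario.positional_bias[r] for r in bias_regions])
        bias_probs = bias_probs / bias_probs.sum()

    beds: dict[str, list[GenomicInterval]] = {}
    truth_rows = []
    for r_idx, rbp in enumerate(scenario.rbp_names):
        sites: list[GenomicInterval] = []
        for s_idx in range(scenario.sites_per_rbp):
            name = f"{rbp}_site{s_idx}"
            mappable = rng.random() >= scenario.unmappable_fraction
            region = ""
            if not mappable:
                # straddle the end boundary of a random block
                for _ in range(1000):
                    b = blocks[int(rng.choice(all_ids))]
                    start = b.ref_end - length // 2
                    chrom_len = scenario.chrom_lengths.get(b.ref_chrom, b.ref_end)
                    if 0 <= start and start + length <= chrom_len:
                        site = GenomicInterval(b.ref_chrom, start, start + length, name)
                        break
                else:  # pragma: no cover - pathological scenario
                    raise RuntimeError("could not place unmappable site")
                cls = ""
            elif segments is not None:
                region = bias_regions[int(rng.choice(len(bias_regions), p=bias_probs))]
                site, cls = _place_in_region(
                    rng, blocks, segments, region, length, by_class
                )
            else:
                pool = all_ids
                cls = ""
                if scenario.site_block_class is not None:
                    tier = (
                        scenario.rbp_tiers[r_idx]
                        if scenario.rbp_tiers is not None
                        else 1.0
                    )
                    if rng.random() < tier:
                        pool = by_class.get(scenario.site_block_class, all_ids)
                        cls = scenario.site_block_class
                b = blocks[int(rng.choice(pool))]
                start = int(rng.integers(b.ref_start, b.ref_end - length + 1))
                site = GenomicInterval(b.ref_chrom, start, start + length, name)
            sites.append(site)
            truth_rows.append(
                {
                    "rbp": rbp, "name": name, "chrom": site.chrom,
                    "start": site.start, "end": site.end,
                    "intended_mappable": mappable,
                    "block_class": cls, "intended_region": region,
                }
            )
        beds[rbp] = sites
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "rbp", "name", "chrom", "start", "end",
            "intended_mappable", "block_class", "intended_region",
        ],
    )
    return beds, truth


def _place_in_region(rng, blocks, segments, region, length, by_class):
    """Rejection-sample a site fully inside one block with its midpoint
    in the requested gene third."""
    attr = {"5prime": "five_prime", "middle": "middle", "3prime": "three_prime"}[region]
    spans = _block_spans(blocks)
    for _ in range(10000):
        seg_obj = getattr(segments[int(rng.choice(len(segments)))], attr)
        if len(seg_obj) < 1:
            continue
        mid = int(rng.integers(seg_obj.start, seg_obj.end))
        start = mid - length // 2
        hits = spans[
            (spans.chrom == seg_obj.chrom)
            & (spans.start <= start)
            & (spans.end >= start + length)
        ]
        if hits.empty or start < 0:
            continue
        site_mid = (start + start + length) // 2
        if not (seg_obj.start <= site_mid < seg_obj.end):
            continue
        return (
            GenomicInterval(seg_obj.chrom, start, start + length),
            "",
        )
    raise RuntimeError(f"could not place site in region {region}")


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


def simulate_feature_table(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[pd.DataFrame, str | None]:
    """Feature table with one planted informative feature.

    The response (median conservation percent) is
    ``50 + effect * z(planted feature) + N(0, feature_noise_sd)``;
    all other features are independent standard-normal noise columns
    rescaled to plausible magnitudes. Returns (table frame, planted
    feature name or None).
    """
    if scenario.n_rbps < 10:
        raise ValueError("need at least 10 RBPs for a meaningful table")
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 303
    )
    n = scenario.n_rbps
    data = {}
    for j, feat in enumerate(FEATURE_NAMES):
        # arbitrary per-feature location/scale; only ordering information matters
        data[feat] = rng.normal(loc=10.0 * (j + 1), scale=3.0 * (j + 1), size=n)
    frame = pd.DataFrame(data, index=scenario.rbp_names)
    planted_name = None
    response = 50.0 + rng.normal(0.0, scenario.feature_noise_sd, size=n)
    if scenario.planted_feature is not None:
        planted_name, effect = scenario.planted_feature
        if planted_name not in frame.columns:
            raise ValueError(f"unknown planted feature {planted_name!r}")
        col = frame[planted_name].to_numpy()
        z = (col - col.mean()) / col.std()
        response = response + effect * z
    frame["response"] = response
    return frame, planted_name


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def simulate_gene_sets(
    scores: GeneScoreTable,
    scenario: SyntheticScenario,
    seed: int | None = None,
) -> tuple[list[GeneSet], GeneScoreTable, str | None]:
    """Gene-set collection with one planted high-scoring set.

    The planted set's member genes get the scenario's score shift added
    (the returned score table carries the shifted scores); the
    remaining sets are random draws of matched size. With shift 0 the
    planted set behaves exactly like a random one (calibration case).
    """
    if len(scores) == 0:
        raise ValueError("gene universe is empty")
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 404
    )
    universe = sorted(scores.universe)
    # keep sets small enough that the permutation pool (universe minus
    # overlap) can still supply a full draw
    size = min(scenario.gene_set_size, max(1, len(universe) // 4))
    shifted = dict(scores.scores)
    sets: list[GeneSet] = []
    planted_name = None
    if scenario.planted_gene_set is not None:
        planted_name, shift = scenario.planted_gene_set
        members = rng.choice(universe, size=size, replace=False)
        for g in members:
            shifted[g] = shifted[g] + shift
        sets.append(GeneSet(planted_name, "planted high-score set", frozenset(members)))
    n_random = scenario.n_gene_sets - len(sets)
    for i in range(n_random):
        members = rng.choice(universe, size=size, replace=False)
        sets.append(GeneSet(f"random_set_{i}", "random set", frozenset(members)))
    return sets, GeneScoreTable(shifted), planted_name


# ---------------------------------------------------------------------------
# Planted positional effect (for the genic-thirds analysis)
# ---------------------------------------------------------------------------


def simulate_positional_effect(
    n_rbps: int = 20,
    sites_per_region: int = 50,
    region_means: Mapping[str, float] = None,
    sd: float = 5.0,
    seed: int = 0,
) -> list[RegionAssignment]:
    """Region assignments with planted per-region conservation levels.

    Draws each region's conservation percents from a normal
    distribution (default: 3' at 70, middle at 55, 5' at 40, sd 5),
    clipped to [0, 100] — the planted analogue of the stronger 3'
    conservation seen in real data.
    """
    if region_means is None:
        region_means = {"5prime": 40.0, "middle": 55.0, "3prime": 70.0}
    rng = np.random.default_rng(seed)
    out: list[RegionAssignment] = []
    for r in range(n_rbps):
        rbp = f"RBP{r + 1:02d}"
        for region, mean in region_means.items():
            percents = np.clip(
                rng.normal(mean, sd, size=sites_per_region), 0.0, 100.0
            )
            for i, p in enumerate(percents):
                site = GenomicInterval("chrS", 100 * i, 100 * i + 20)
                out.append(RegionAssignment(site, "G0000", region, float(p), rbp))
    return out


def simulate_family_tree(members: Sequence[str], seed: int = 0) -> str:
    """Random Newick tree over the given leaves with branch lengths in
    (0, 0.5], for exercising the family-similarity analysis."""
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    rng = np.random.default_rng(seed)
    nodes = [f"{m}:{rng.uniform(0.05, 0.5):.4f}" for m in members]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.05, 0.5):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    # strip the root's branch length
    root = nodes[0]
    return root[: root.rfind(":")] + ";"
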