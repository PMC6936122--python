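"""End-to-end orchestration of the conservation analysis.

Stages run in dependency order — conserve, nulls, families, features,
regions, enrichment — with all inter-stage state passed through
headered TSV files under the output directory, and a run manifest
recording every output with a content checksum. All randomness flows
from the config seed, so a rerun with identical config and inputs
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from . import conservation, enrichment, family, genic, random_regions, relieff
from . import io as gio
from . import synthetic

logger = logging.getLogger(__name__)

ALL_STAGES = ("conserve", "nulls", "families", "features", "regions", "enrichment")


@dataclass
class RunConfig:
    out_dir: str
    scenario: synthetic.SyntheticScenario = field(
        default_factory=synthetic.SyntheticScenario
    )
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_null_regions: int = 2000
    n_null_replicates: int = 10
    n_perm: int = 200
    n_families: int = 3
    family_size: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scenario_kwargs = raw.pop("scenario", {})
        clades = scenario_kwargs.pop("clades", None)
        if clades is not None:
            scenario_kwargs["clades"] = [
                synthetic.CladeSpec(
                    c["name"], tuple(c["species"]), c["retention_prob"]
                )
                for c in clades
            ]
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(scenario=synthetic.SyntheticScenario(**scenario_kwargs), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages on the synthetic scenario; return the
    run manifest (also written as ``manifest.json`` in the output dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario
    manifest: dict = {"seed": config.seed, "stages": {}, "warnings": []}

    def record(stage: str, paths: list[Path], **extra) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in paths},
            **extra,
        }

    # --- shared synthetic inputs -----------------------------------------
    blocks, block_truth = synthetic.simulate_maf(scenario, seed=config.seed)
    genes = synthetic.simulate_genes(scenario, seed=config.seed)
    beds, site_truth = synthetic.simulate_sites(
        scenario, blocks, genes=genes, block_truth=block_truth, seed=config.seed
    )
    inputs_dir = out / "inputs"
    inputs_dir.mkdir(exist_ok=True)
    maf_path = inputs_dir / "alignment.maf"
    gio.write_maf(blocks, maf_path)
    gio.write_genes(genes, inputs_dir / "genes.tsv")
    for rbp, sites in beds.items():
        gio.write_bed(sites, inputs_dir / f"{rbp}.bed")
    index = conservation.index_blocks(blocks)
    total = scenario.total_species

    profiles: dict[str, conservation.ConservationProfile] = {}
    if "conserve" in config.stages:
        record_frames = []
        summary_rows = []
        for rbp, sites in beds.items():
            prof = conservation.profile_rbp(sites, index, total, rbp_name=rbp)
            profiles[rbp] = prof
            rec = conservation.records_to_frame(prof)
            rec.insert(0, "rbp", rbp)
            record_frames.append(rec)
            q1, q2, q3 = prof.quartiles()
            summary_rows.append(
                {
                    "rbp": rbp, "n_sites": len(prof.records),
                    "n_mapped": prof.n_mapped, "n_unmapped": prof.n_unmapped,
                    "q1": q1, "median": q2, "q3": q3,
                }
            )
        records_path = out / "conservation_records.tsv"
        _write_tsv(pd.concat(record_frames, ignore_index=True), records_path)
        summary_path = out / "conservation_summary.tsv"
        _write_tsv(pd.DataFrame(summary_rows), summary_path)
        matrix = conservation.species_presence_matrix(list(profiles.values()))
        matrix_path = out / "species_presence_matrix.tsv"
        matrix.to_csv(matrix_path, sep="\t", float_format="%.10g", index_label="rbp")
        clade_map = scenario.clade_map
        clades = [c.name for c in scenario.clades]
        stat, p = conservation.clade_comparison(
            matrix, clade_map, clades[0], clades[-1]
        )
        clade_path = out / "clade_comparison.tsv"
        _write_tsv(
            pd.DataFrame(
                [{"clade_a": clades[0], "clade_b": clades[-1],
                  "statistic": stat, "p_value": p}]
            ),
            clade_path,
        )
        record(
            "conserve",
            [records_path, summary_path, matrix_path, clade_path],
            n_mapped=int(sum(p.n_mapped for p in profiles.values())),
            n_unmapped=int(sum(p.n_unmapped for p in profiles.values())),
        )

    if "nulls" in config.stages:
        space = random_regions.AnnotationSpace.whole_genome(scenario.chrom_lengths)
        null_profiles, agreement = random_regions.null_profile(
            space, config.n_null_regions, scenario.site_length,
            config.n_null_replicates, config.seed + 1000, index, total,
        )
        rows = [
            {
                "replicate": i, "n_mapped": p.n_mapped,
                "n_unmapped": p.n_unmapped, "median": p.median(),
            }
            for i, p in enumerate(null_profiles)
        ]
        null_path = out / "null_genomic_summary.tsv"
        _write_tsv(pd.DataFrame(rows), null_path)
        agree_path = out / "null_replicate_agreement.tsv"
        _write_tsv(pd.DataFrame([agreement]), agree_path)
        record("nulls", [null_path, agree_path], **agreement)

    if "families" in config.stages:
        if not profiles:
            raise RuntimeError("families stage requires the conserve stage")
        rng = np.random.default_rng(config.seed + 2000)
        names = list(profiles)
        pair_frames = []
        family_rows = []
        for f_idx in range(config.n_families):
            members = [
                names[i]
                for i in rng.choice(
                    len(names), size=config.family_size, replace=False
                )
            ]
            newick = synthetic.simulate_family_tree(
                members, seed=config.seed + 2000 + f_idx
            )
            tree = gio.read_newick(_io.StringIO(newick))
            pairs = family.family_pairs(profiles, tree, members=members)
            frame = family.pairs_to_frame(pairs)
            frame.insert(0, "family", f"family{f_idx}")
            pair_frames.append(frame)
            try:
                chi2, dof, p = family.association_test(pairs, n_bins=2)
            except ValueError:
                chi2, dof, p = float("nan"), 0, float("nan")
            family_rows.append(
                {"family": f"family{f_idx}", "chi2": chi2, "dof": dof, "p_value": p}
            )
        pairs_path = out / "family_pairs.tsv"
        _write_tsv(pd.concat(pair_frames, ignore_index=True), pairs_path)
        assoc_path = out / "family_association.tsv"
        _write_tsv(pd.DataFrame(family_rows), assoc_path)
        record("families", [pairs_path, assoc_path])

    if "features" in config.stages:
        frame, planted = synthetic.simulate_feature_table(scenario, seed=config.seed)
        table = relieff.RbpFeatureTable(frame)
        k = min(10, len(frame) - 1)
        weights = relieff.rrelieff(table, k=k, m="all", sigma=20.0)
        weights_path = out / "feature_weights.tsv"
        _write_tsv(weights.to_frame(), weights_path)
        slope, intercept, pval = relieff.regress_response_on_feature(
            table, "n_binding_sites"
        )
        reg_path = out / "site_count_regression.tsv"
        _write_tsv(
            pd.DataFrame(
                [{"feature": "n_binding_sites", "slope": slope,
                  "intercept": intercept, "p_value": pval}]
            ),
            reg_path,
        )
        record(
            "features", [weights_path, reg_path],
            planted_feature=planted, top_feature=weights.rank[0],
        )

    if "regions" in config.stages:
        if not profiles:
            raise RuntimeError("regions stage requires the conserve stage")
        assignments = []
        for rbp, prof in profiles.items():
            assignments.extend(
                genic.assign_sites(prof.records, genes, rbp_name=rbp)
            )
        medians, tests, summary = genic.region_comparison(assignments)
        medians_path = out / "region_medians.tsv"
        _write_tsv(medians, medians_path)
        tests_path = out / "region_tests.tsv"
        _write_tsv(tests, tests_path)
        matrix = medians.pivot(index="rbp", columns="region", values="median_percent")
        matrix_path = out / "region_median_matrix.tsv"
        matrix.to_csv(matrix_path, sep="\t", float_format="%.10g")
        record("regions", [medians_path, tests_path, matrix_path], **summary)

    if "enrichment" in config.stages:
        if not profiles:
            raise RuntimeError("enrichment stage requires the conserve stage")
        site_to_gene = site_gene_map(
            [r for p in profiles.values() for r in p.records], genes
        )
        all_records = [r for p in profiles.values() for r in p.records]
        scores = enrichment.gene_scores(all_records, site_to_gene)
        sets, shifted_scores, planted = synthetic.simulate_gene_sets(
            scores, scenario, seed=config.seed
        )
        gio.write_gmt(sets, inputs_dir / "gene_sets.gmt")
        results = enrichment.enrich_collection(
            shifted_scores, sets, n_perm=config.n_perm, seed=config.seed + 3000
        )
        enrich_path = out / "enrichment.tsv"
        _write_tsv(enrichment.results_to_frame(results), enrich_path)
        record(
            "enrichment", [enrich_path],
            planted_set=planted, top_set=results[0].set_name if results else None,
        )

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def site_gene_map(records, genes) -> dict[str, list[str]]:
    """Site name -> gene symbols whose span contains the site midpoint."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.symbol)
    out: dict[str, list[str]] = {}
    for rec in records:
        tree = trees.get(rec.site.chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.at(rec.site.midpoint))
        if hits:
            out[rec.site.name] = hits
    return out
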