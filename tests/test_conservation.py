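import itertools

import numpy as np
import pytest

from rbpcons.conservation import (
    clade_comparison,
    compare_groups,
    index_blocks,
    map_site,
    profile_rbp,
    species_presence_matrix,
)
from rbpcons.io import GenomicInterval

from conftest import make_block, make_profile


def brute_force_containing(blocks, site):
    return sorted(
        i
        for i, b in enumerate(blocks)
        if b.ref_chrom == site.chrom
        and b.ref_start <= site.start
        and b.ref_end >= site.end
    )


class TestIndex:
    def test_query_inside_one_block(self):
        blocks = [
            make_block("chr1", 0, 100, ["a"]),
            make_block("chr1", 200, 100, ["a", "b"]),
            make_block("chr1", 400, 100, ["a"]),
        ]
        index = index_blocks(blocks)
        assert index.containing("chr1", 220, 240) == [1]

    def test_boundary_spanning_query_matches_nothing(self):
        blocks = [
            make_block("chr1", 0, 100, ["a"]),
            make_block("chr1", 100, 100, ["a"]),
        ]
        index = index_blocks(blocks)
        assert index.containing("chr1", 90, 110) == []

    def test_matches_brute_force_scan(self, rng):
        """Indexed containment lookup equals a linear scan over blocks."""
        blocks = [
            make_block(
                f"chr{rng.integers(1, 3)}",
                int(rng.integers(0, 5000)),
                int(rng.integers(20, 200)),
                ["a"],
            )
            for _ in range(200)
        ]
        index = index_blocks(blocks)
        for _ in range(1000):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 5200))
            end = start + int(rng.integers(1, 40))
            site = GenomicInterval(chrom, start, end)
            assert index.containing(chrom, start, end) == brute_force_containing(
                blocks, site
            )


class TestMapSite:
    def test_species_count_to_percent(self):
        block = make_block("chr1", 100, 50, [f"sp{i}" for i in range(22)])
        index = index_blocks([block])
        rec = map_site(GenomicInterval("chr1", 100, 120), index, total_species=46)
        assert rec.mapped and rec.n_species == 23
        assert rec.percent == pytest.approx(50.0)

    def test_site_past_block_end_unmapped(self):
        index = index_blocks([make_block("chr1", 100, 50, ["a"])])
        rec = map_site(GenomicInterval("chr1", 140, 160), index)
        assert not rec.mapped and rec.block_id is None

    def test_percent_endpoints(self):
        full = make_block("chr1", 0, 100, [f"sp{i}" for i in range(45)])
        solo = make_block("chr2", 0, 100, [])
        index = index_blocks([full, solo])
        assert map_site(
            GenomicInterval("chr1", 10, 30), index, 46
        ).percent == pytest.approx(100.0)
        assert map_site(
            GenomicInterval("chr2", 10, 30), index, 46
        ).percent == pytest.approx(100 / 46)

    def test_duplicate_species_rows_count_once(self):
        block = make_block("chr1", 0, 100, ["a", "a", "b"])
        index = index_blocks([block])
        assert map_site(GenomicInterval("chr1", 10, 30), index).n_species == 3

    def test_multiple_containing_blocks_highest_score_wins(self):
        b1 = make_block("chr1", 0, 100, ["a"], score=10)
        b2 = make_block("chr1", 0, 120, ["a", "b"], score=50)
        index = index_blocks([b1, b2])
        rec = map_site(GenomicInterval("chr1", 10, 30), index)
        assert rec.block_id == 1

    def test_score_tie_broken_by_lowest_start(self):
        b1 = make_block("chr1", 5, 100, ["a"], score=10)
        b2 = make_block("chr1", 0, 120, ["a", "b"], score=10)
        index = index_blocks([b1, b2])
        assert map_site(GenomicInterval("chr1", 10, 30), index).block_id == 1

    def test_invalid_total_species(self):
        index = index_blocks([make_block("chr1", 0, 100, ["a"])])
        with pytest.raises(ValueError):
            map_site(GenomicInterval("chr1", 10, 30), index, total_species=0)

    def test_oracle_equivalence_with_selection(self, rng):
        """map_site over the index equals a linear scan + the same
        block-selection rule on random instances."""
        blocks = [
            make_block(
                "chr1",
                int(rng.integers(0, 3000)),
                int(rng.integers(25, 150)),
                [f"sp{j}" for j in range(rng.integers(0, 10))],
                score=float(rng.integers(0, 5)),
            )
            for _ in range(150)
        ]
        index = index_blocks(blocks)
        for _ in range(1000):
            start = int(rng.integers(0, 3100))
            site = GenomicInterval("chr1", start, start + 20)
            rec = map_site(site, index, 46)
            ids = brute_force_containing(blocks, site)
            if not ids:
                assert not rec.mapped
            else:
                best = min(ids, key=lambda i: (-blocks[i].score, blocks[i].ref_start))
                assert rec.mapped and rec.block_id == best
                assert rec.n_species == len(blocks[best].species_set)
                assert rec.percent == pytest.approx(
                    len(blocks[best].species_set) / 46 * 100
                )

    def test_percent_scale_bounds(self, rng):
        """Any mapped record satisfies 100/total <= P <= 100."""
        blocks = [
            make_block("chr1", 100 * i, 80, [f"sp{j}" for j in range(rng.integers(0, 46))])
            for i in range(50)
        ]
        index = index_blocks(blocks)
        for i in range(50):
            rec = map_site(GenomicInterval("chr1", 100 * i + 5, 100 * i + 25), index, 46)
            assert rec.mapped
            assert 100 / 46 <= rec.percent <= 100


class TestProfile:
    def test_median_over_mapped(self):
        profile = make_profile("X", [20, 40, 60, 80])
        assert profile.median() == pytest.approx(50.0)

    def test_all_unmapped(self):
        profile = make_profile("X", [], n_unmapped=4)
        assert profile.n_unmapped == 4
        assert np.isnan(profile.median())

    def test_unmapped_as_zero_treatment(self):
        profile = make_profile("X", [40, 60], n_unmapped=2)
        assert profile.median() == pytest.approx(50.0)
        assert profile.median(unmapped_as_zero=True) == pytest.approx(20.0)

    def test_per_site_percent_matches_hand_recount(self):
        """P per site equals a direct recount of each block's rows."""
        species_per_block = [["a", "b"], ["a"], ["a", "b", "c", "d"]]
        blocks = [
            make_block("chr1", 100 * i, 80, sp)
            for i, sp in enumerate(species_per_block)
        ]
        sites = [GenomicInterval("chr1", 100 * i + 10, 100 * i + 30) for i in range(3)]
        profile = profile_rbp(sites, index_blocks(blocks), total_species=10)
        expected = [(len(sp) + 1) / 10 * 100 for sp in species_per_block]
        assert profile.percents().tolist() == pytest.approx(expected)


class TestPresenceMatrix:
    def test_always_and_never_present(self):
        blocks = [make_block("chr1", 100 * i, 80, ["every", "ref2"]) for i in range(3)]
        sites = [GenomicInterval("chr1", 100 * i + 10, 100 * i + 30) for i in range(3)]
        profile = profile_rbp(sites, index_blocks(blocks), 46, rbp_name="X")
        matrix = species_presence_matrix([profile], species_order=["hg", "every", "nope"])
        assert matrix.loc["X", "every"] == pytest.approx(100.0)
        assert matrix.loc["X", "nope"] == pytest.approx(0.0)
        assert matrix.loc["X", "hg"] == pytest.approx(100.0)  # reference column


class TestCompareGroups:
    def test_identical_lists_not_significant(self):
        _, p = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_exact_enumeration_oracle(self):
        """Exact p equals exhaustive enumeration of rank assignments."""
        a, b = [90.0, 91.0, 92.0], [10.0, 11.0, 12.0]
        _, p = compare_groups(a, b)
        pooled = sorted(a + b)
        n = len(a)
        u_obs = sum(1 for x in a for y in b if x > y)
        u_values = []
        for combo in itertools.combinations(range(len(pooled)), n):
            grp_a = [pooled[i] for i in combo]
            grp_b = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u_values.append(sum(1 for x in grp_a for y in grp_b if x > y))
        u_values = np.array(u_values)
        p_ge = np.mean(u_values >= u_obs)
        p_le = np.mean(u_values <= u_obs)
        expected = min(1.0, 2 * min(p_ge, p_le))
        assert p == pytest.approx(expected)
        assert p == pytest.approx(0.1)

    def test_large_shift_is_significant(self, rng):
        base = rng.uniform(0, 50, size=200)
        _, p = compare_groups(base + 50, base)
        assert p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestCladeComparison:
    def test_separated_clades(self):
        profiles = [make_profile(f"R{i}", [50.0] * 5) for i in range(3)]
        # fabricate a matrix via presence of distinct species sets
        import pandas as pd

        matrix = pd.DataFrame(
            {"m1": [90.0, 92, 88], "m2": [85.0, 91, 87], "f1": [20.0, 25, 15]},
            index=["R0", "R1", "R2"],
        )
        clade_map = {"m1": "mammal", "m2": "mammal", "f1": "fish"}
        _, p = clade_comparison(matrix, clade_map, "mammal", "fish")
        assert p < 0.05

    def test_unknown_clade(self):
        import pandas as pd

        matrix = pd.DataFrame({"m1": [1.0]}, index=["R"])
        with pytest.raises(ValueError):
            clade_comparison(matrix, {"m1": "mammal"}, "mammal", "bird")
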