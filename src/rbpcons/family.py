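"""RBP-family analysis: conservation-profile similarity vs tree distance.

For two RBPs with N1 and N2 mapped binding sites, the similarity score is

    SS = 2 * NBS / (N1 + N2)

where NBS counts binding sites conserved in the same percentage of
species. NBS is computed as the multiset intersection over the discrete
lattice of P values (k / total_species * 100): for each distinct P,
min(count1, count2) sites are matched, the only symmetric counting rule
bounded by min(N1, N2). Association between SS and patristic tree
distance is tested with a Pearson chi-square on quantile-binned pairs.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .conservation import ConservationProfile

logger = logging.getLogger(__name__)

# lattice resolution for "same % of species": P values are k/total*100,
# rounding to 9 decimals collapses float noise without merging lattice points
_LATTICE_DECIMALS = 9


@dataclass
class SimilarityResult:
    rbp1: str
    rbp2: str
    nbs: int
    n1: int
    n2: int
    ss: float
    evo_dist: float = float("nan")


def _discretize(percents: np.ndarray) -> Counter:
    return Counter(np.round(percents, _LATTICE_DECIMALS).tolist())


def similarity_score(
    profile1: ConservationProfile, profile2: ConservationProfile
) -> SimilarityResult:
    """Similarity of two RBPs' binding-site conservation distributions."""
    p1, p2 = profile1.percents(), profile2.percents()
    if p1.size == 0 or p2.size == 0:
        raise ValueError("both profiles need at least one mapped site")
    c1, c2 = _discretize(p1), _discretize(p2)
    nbs = sum(min(c1[v], c2[v]) for v in c1.keys() & c2.keys())
    n1, n2 = int(p1.size), int(p2.size)
    return SimilarityResult(
        rbp1=profile1.rbp_name,
        rbp2=profile2.rbp_name,
        nbs=nbs,
        n1=n1,
        n2=n2,
        ss=2.0 * nbs / (n1 + n2),
    )


def patristic_distances(
    tree: dendropy.Tree, normalize: bool = False
) -> pd.DataFrame:
    """Pairwise patristic distances (path sums of branch lengths).

    With ``normalize`` the table is divided by its maximum pairwise
    distance, mapping distances into [0, 1].
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[i], taxa[j])
        mat[i, j] = mat[j, i] = d
    if normalize:
        dmax = mat.max()
        if dmax > 0:
            mat = mat / dmax
    return pd.DataFrame(mat, index=labels, columns=labels)


def family_pairs(
    profiles: dict[str, ConservationProfile],
    tree: dendropy.Tree,
    members: list[str] | None = None,
    normalize_distances: bool = False,
) -> list[SimilarityResult]:
    """All within-family SimilarityResults with tree distances attached."""
    dist = patristic_distances(tree, normalize=normalize_distances)
    names = members if members is not None else sorted(profiles)
    missing = [n for n in names if n not in dist.index]
    if missing:
        raise ValueError(f"tree is missing leaves for: {missing}")
    out = []
    for a, b in itertools.combinations(names, 2):
        res = similarity_score(profiles[a], profiles[b])
        res.evo_dist = float(dist.loc[a, b])
        out.append(res)
    return out


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    codes = pd.qcut(values, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(codes)


def association_test(
    pairs: list[SimilarityResult], n_bins: int = 3
) -> tuple[float, int, float]:
    """Chi-square independence test of SS against evolutionary distance.

    Both axes are discretized into ``n_bins`` quantile bins and the
    Pearson chi-square test of independence is applied to the resulting
    contingency table. Returns (statistic, dof, p). Cells with expected
    count below 5 trigger a logged caution; a table degenerate on
    either axis is an error.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    ss = np.array([p.ss for p in pairs])
    dist = np.array([p.evo_dist for p in pairs])
    ss_bin = _quantile_bins(ss, n_bins)
    dist_bin = _quantile_bins(dist, n_bins)
    table = pd.crosstab(dist_bin, ss_bin).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            "degenerate contingency table: all pairs fall in one bin of an axis"
        )
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        logger.warning(
            "chi-square table has %d cells with expected count < 5; "
            "p-value may be unreliable",
            int((expected < 5).sum()),
        )
    return float(chi2), int(dof), float(p)


def pairs_to_frame(pairs: list[SimilarityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rbp1": p.rbp1, "rbp2": p.rbp2, "nbs": p.nbs,
                "n1": p.n1, "n2": p.n2, "ss": p.ss, "evo_dist": p.evo_dist,
            }
            for p in pairs
        ],
        columns=["rbp1", "rbp2", "nbs", "n1", "n2", "ss", "evo_dist"],
    )
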