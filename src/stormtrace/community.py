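"""Community-level comparison: dissimilarity, ordination, clustering,
rarefaction and differential abundance.

Thin, explicit wrappers over scipy / scikit-learn / statsmodels routines,
fixing the conventions used throughout the pipeline: Bray-Curtis on counts
or relative abundances, a Spearman-based dissimilarity (1 - rho)/2 in
[0, 1], non-metric MDS minimising Kruskal stress-1, average-linkage
agglomeration, hypergeometric rarefaction, and per-taxon Wilcoxon rank-sum
tests with Benjamini-Hochberg control restricted to taxa above a
rank-specific mean-abundance floor (1e-3 at phylum/class, 1e-2 at genus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .tables import AmpliconTable

__all__ = [
    "DissimilarityMatrix",
    "DifferentialResult",
    "Dendrogram",
    "bray_curtis",
    "spearman_dissim",
    "nmds",
    "hcluster",
    "rarefy",
    "differential_taxa",
    "ABUNDANCE_FLOORS",
]

# mean relative-abundance floors below which taxa are not tested
ABUNDANCE_FLOORS = {"phylum": 1e-3, "class": 1e-3, "genus": 1e-2}


@dataclass
class DissimilarityMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str  # bray_curtis | spearman_based

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        ).to_csv(path, sep="\t")


@dataclass(frozen=True)
class DifferentialResult:
    taxon: str
    group_means: tuple[float, float]
    direction: str  # '+' enriched in group 1, '-' depleted
    p_raw: float
    p_adj: float


def _columns(table: AmpliconTable | pd.DataFrame) -> pd.DataFrame:
    return table.counts if isinstance(table, AmpliconTable) else table


def bray_curtis(
    table: AmpliconTable | pd.DataFrame, use_relative: bool = False
) -> DissimilarityMatrix:
    """BC(i,j) = 1 - 2*sum_k min(x_ik, x_jk) / (sum x_i + sum x_j)."""
    df = _columns(table)
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    totals = df.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total: {zero}")
    X = (df / totals if use_relative else df).T.to_numpy(dtype=float)
    mat = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(tuple(df.columns), mat, "bray_curtis")


def spearman_dissim(table: AmpliconTable | pd.DataFrame) -> DissimilarityMatrix:
    """d(i,j) = (1 - rho_ij)/2 with Spearman rho over taxa (ties mid-ranked)."""
    df = _columns(table)
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if df.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    for sid in df.columns:
        if df[sid].nunique() == 1:
            raise ValueError(
                f"sample {sid!r} has a constant abundance vector; "
                "Spearman correlation undefined"
            )
    X = df.to_numpy(dtype=float)
    if df.shape[1] == 2:
        r = float(stats.spearmanr(X[:, 0], X[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(stats.spearmanr(X, axis=0).statistic)
    d = (1.0 - rho) / 2.0
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(tuple(df.columns), d, "spearman_based")


def nmds(
    dist: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS (best of ``n_starts`` restarts), Kruskal stress-1.

    Coordinates are centred.  Monotone regression of the configuration
    distances on the observed dissimilarity ranks is handled by the SMACOF
    implementation (pool-adjacent-violators via isotonic regression).
    """
    n = len(dist.sample_ids)
    if k >= n:
        raise ValueError("k must be < number of samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_starts,
            max_iter=max_iter,
            random_state=seed,
            normalized_stress=True,
        )
        coords = model.fit_transform(dist.values)
    coords = coords - coords.mean(axis=0)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=dist.sample_ids, columns=cols), float(
        model.stress_
    )


@dataclass
class Dendrogram:
    """Agglomerative clustering result (scipy linkage matrix + labels)."""

    linkage: np.ndarray
    sample_ids: tuple[str, ...]

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))

    def cophenetic(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.linkage))

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_dist: float) -> str:
            blen = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{blen:g}"
            left = walk(node.get_left(), node.dist)
            right = walk(node.get_right(), node.dist)
            return f"({left},{right}):{blen:g}"

        return walk(tree, tree.dist) + ";"


def hcluster(dist: DissimilarityMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering; merge heights are non-decreasing."""
    if len(dist.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    Z = hierarchy.linkage(dist.condensed(), method=linkage)
    return Dendrogram(Z, dist.sample_ids)


def rarefy(
    table: AmpliconTable | pd.DataFrame, depth: int, seed: int
) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning.  Column sums of the result equal ``depth`` exactly
    (multivariate hypergeometric draw per sample).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    df = _columns(table)
    totals = df.sum(axis=0)
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep).tolist()
    if dropped:
        warnings.warn(f"dropping samples below depth {depth}: {dropped}", stacklevel=2)
    if not len(keep):
        raise ValueError("no sample reaches the rarefaction depth")
    rng = np.random.default_rng(seed)
    out = {}
    for sid in keep:
        counts = df[sid].to_numpy(dtype=np.int64)
        out[sid] = rng.multivariate_hypergeometric(counts, depth)
    return pd.DataFrame(out, index=df.index)


def differential_taxa(
    table: AmpliconTable,
    groups: dict[str, Sequence[str]],
    rank: str = "genus",
    abundance_floor: float | None = None,
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Wilcoxon rank-sum per taxon at ``rank`` with BH adjustment.

    ``groups`` maps two group names to sample-id lists.  Sequence types are
    aggregated to the rank, converted to relative abundances, and only taxa
    whose mean relative abundance exceeds the floor in at least one group
    are tested (defaults per rank: 1e-3 phylum/class, 1e-2 genus).  The
    exact null distribution is used for combined n <= 20, the normal
    approximation with continuity correction otherwise.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (g1, ids1), (g2, ids2) = groups.items()
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValueError("each group needs >= 2 samples")
    if abundance_floor is None:
        abundance_floor = ABUNDANCE_FLOORS.get(rank, 1e-3)

    agg = table.aggregate_by_rank(rank)
    rel = agg / agg.sum(axis=0)
    a = rel[list(ids1)]
    b = rel[list(ids2)]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    tested = rel.index[(mean_a > abundance_floor) | (mean_b > abundance_floor)]
    if not len(tested):
        return []

    method = "exact" if len(ids1) + len(ids2) <= 20 else "asymptotic"
    pvals = stats.mannwhitneyu(
        a.loc[tested].to_numpy(),
        b.loc[tested].to_numpy(),
        axis=1,
        alternative="two-sided",
        method=method,
    ).pvalue
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    results = []
    for taxon, p_r, p_a in zip(tested, pvals, p_adj):
        direction = "+" if mean_a[taxon] >= mean_b[taxon] else "-"
        results.append(
            DifferentialResult(
                str(taxon),
                (float(mean_a[taxon]), float(mean_b[taxon])),
                direction,
                float(p_r),
                float(p_a),
            )
        )
    return results
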