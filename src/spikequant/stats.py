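"""Cross-ploidy statistical analysis of spike trait tables.

Covers the four analysis stages applied to per-image trait tables:
z-normalization of the nine traits, per-trait two-sided variance F-tests
between the tetraploid (4x) and hexaploid (6x) groups, species-level
hierarchical clustering under the 1 - r (Pearson) correlation distance with
average linkage (UPGMA), and 2-D t-SNE ordination of the per-image records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import f as f_dist

from .traits import TRAIT_COLUMNS


def zscore_normalize(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Center and scale trait columns to mean 0 and sample sd 1 (ddof = 1).

    Non-trait (metadata) columns pass through unchanged.  A constant trait
    column has no defined scale and raises, naming the trait.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to normalize")
    if columns is None:
        columns = [c for c in TRAIT_COLUMNS if c in table.columns]
    out = table.copy()
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        sd = np.std(vals, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"trait column {col!r} is constant; z-score is undefined")
        out[col] = (vals - vals.mean()) / sd
    return out


@dataclass
class VarianceTestResult:
    """Two-sided variance-ratio F-test for one trait."""

    trait: str
    F: float
    df1: int
    df2: int
    p: float
    alpha: float
    significant: bool


def variance_f_test(x, y, alpha: float = 0.05, trait: str = "") -> VarianceTestResult:
    """F-test of equal variances: F = var(x) / var(y), sample variances.

    The two-sided p-value is 2 * min(P(F <= f), P(F >= f)) under
    F(df1, df2) with df = n - 1 per sample, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vy == 0:
        raise ValueError("denominator sample has zero variance; F is undefined")
    F = float(vx / vy)
    df1, df2 = x.size - 1, y.size - 1
    p = float(min(1.0, 2.0 * min(f_dist.cdf(F, df1, df2), f_dist.sf(F, df1, df2))))
    return VarianceTestResult(trait=trait, F=F, df1=df1, df2=df2, p=p, alpha=alpha, significant=p < alpha)


def _one_image_per_plant(records: pd.DataFrame, protocol: str | None) -> pd.DataFrame:
    sub = records
    if protocol is not None and "protocol" in sub.columns:
        sub = sub[sub["protocol"] == protocol]
    if "plant" in sub.columns:
        by = ["projection"] if "projection" in sub.columns else []
        sub = sub.sort_values(by, kind="stable") if by else sub
        sub = sub.groupby("plant", sort=False).head(1)
    return sub


def ploidy_variance_screen(
    records: pd.DataFrame,
    protocol: str | None = "table",
    alpha: float = 0.05,
) -> list[VarianceTestResult]:
    """Per-trait variance F-tests between the hexaploid and tetraploid groups.

    Keeps one image per plant (the requested protocol's lowest-numbered
    projection, first row on ties), z-normalizes the nine traits over the
    retained records, then tests each trait independently with the
    hexaploid variance in the numerator.  No multiple-testing correction is
    applied: each trait is tested on its own at ``alpha``.
    """
    sub = _one_image_per_plant(records, protocol)
    if "ploidy" not in sub.columns:
        raise ValueError("trait table has no 'ploidy' column")
    hexa = sub[sub["ploidy"] == "6x"]
    tetra = sub[sub["ploidy"] == "4x"]
    if len(hexa) < 2 or len(tetra) < 2:
        raise ValueError(
            f"need at least 2 plants per ploidy group, got 6x: {len(hexa)}, 4x: {len(tetra)}"
        )
    norm = zscore_normalize(sub)
    hexa = norm[norm["ploidy"] == "6x"]
    tetra = norm[norm["ploidy"] == "4x"]
    return [
        variance_f_test(hexa[trait], tetra[trait], alpha=alpha, trait=trait)
        for trait in TRAIT_COLUMNS
    ]


def screen_to_frame(results: list[VarianceTestResult]) -> pd.DataFrame:
    """Tabulate screen results (one row per trait), Table-3 style."""
    return pd.DataFrame(
        [
            {"trait": r.trait, "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p, "significant": r.significant}
            for r in results
        ]
    )


def species_distance_matrix(summaries: pd.DataFrame, normalize_columns: bool = True) -> pd.DataFrame:
    """Pairwise 1 - r (Pearson) distances between species mean vectors.

    ``summaries`` is a species-by-trait frame of mean values.  By default
    each trait column is z-scored across species first, so that traits on
    mm, mm^2 and unitless scales contribute comparably to r.  Raises if any
    species vector is constant (Pearson undefined).
    """
    M = summaries.to_numpy(dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 species")
    if np.isnan(M).any():
        raise ValueError("species mean vectors contain missing values")
    if normalize_columns:
        sd = M.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = summaries.columns[np.flatnonzero(sd == 0)].tolist()
            raise ValueError(f"trait columns constant across species: {bad}")
        M = (M - M.mean(axis=0)) / sd
    row_sd = M.std(axis=1)
    if np.any(row_sd == 0):
        bad = summaries.index[np.flatnonzero(row_sd == 0)].tolist()
        raise ValueError(f"species vectors with zero variance (Pearson undefined): {bad}")
    D = 1.0 - np.corrcoef(M)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)  # symmetrize away rounding
    return pd.DataFrame(D, index=summaries.index, columns=summaries.index)


@dataclass
class ClusterTree:
    """Average-linkage (UPGMA) species tree.

    ``merge_heights`` lists the n - 1 merge distances in order; the raw
    scipy linkage matrix is kept for dendrogram plotting and flat cuts.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    metric: str = "1 - pearson r"

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def cut(self, k: int) -> dict[str, int]:
        """Flat cut into k groups; returns label -> group id (1-based)."""
        assignments = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from the merge heights."""
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def upgma_tree(D: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> ClusterTree:
    """UPGMA (average-linkage) tree from a symmetric distance matrix.

    Merge heights are non-decreasing (ultrametric output).  Raises on NaN,
    asymmetric input or a nonzero diagonal.
    """
    if isinstance(D, pd.DataFrame):
        labels = labels if labels is not None else [str(x) for x in D.index]
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        labels = labels if labels is not None else [str(i) for i in range(M.shape[0])]
    if np.isnan(M).any():
        raise ValueError("distance matrix contains NaN")
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(M), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if (M < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    Z = linkage(squareform(M, checks=False), method="average")
    return ClusterTree(labels=list(labels), linkage_matrix=Z)


@dataclass
class Ordination:
    """2-D t-SNE embedding of per-image trait records (row order preserved)."""

    coordinates: np.ndarray  # (n, 2)
    perplexity: float
    seed: int
    columns: list[str] = field(default_factory=lambda: ["component_1", "component_2"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coordinates, columns=self.columns)


def tsne_embed(
    table: pd.DataFrame | np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
    max_iter: int = 1000,
) -> Ordination:
    """Deterministic (seeded) 2-D t-SNE of a normalized trait table.

    Requires at least 3 * perplexity rows; each input row maps to one
    coordinate pair, in input order.
    """
    from sklearn.manifold import TSNE

    if isinstance(table, pd.DataFrame):
        cols = [c for c in TRAIT_COLUMNS if c in table.columns]
        X = table[cols].to_numpy(dtype=float) if cols else table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for n = {n} rows (need n >= 3 * perplexity)")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=max_iter,
    )
    coords = tsne.fit_transform(X)
    if not np.isfinite(coords).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return Ordination(coordinates=np.asarray(coords, dtype=float), perplexity=perplexity, seed=seed)
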