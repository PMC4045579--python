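"""Association machinery downstream of the family classification.

Hierarchy-aware enrichment (genes belong to all ancestors of their
direct categories; one-sided Fisher exact tests in both directions;
Benjamini–Hochberg FDR within each direction), bootstrap comparisons
of group means, the between/within variance separation ratio, Spearman
correlations, and hierarchical clustering of categories by shared
SRV+ genes.

The category dissimilarity is the Jaccard form
``d_AB = 1 - N(A ∩ B) / N(A ∪ B)`` over SRV+ gene sets: 0 when the two
categories hold exactly the same SRV+ genes, 1 when they share none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .seqio import AnnotationTable

__all__ = [
    "AnnotationHierarchy",
    "ContingencyTable2x2",
    "EnrichmentRecord",
    "BootstrapResult",
    "DissimilarityMatrix",
    "CorrelationResult",
    "SeparationResult",
    "propagate_hierarchy",
    "fisher_enrichment",
    "enrichment_table",
    "bh_fdr",
    "bootstrap_mean_difference",
    "separation_ratio",
    "spearman_correlation",
    "srv_sharing_dissimilarity",
    "hierarchical_cluster",
    "map_genes_to_family_calls",
    "significance_stars",
]


# ---------------------------------------------------------------------------
# Hierarchy propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationHierarchy:
    """Category DAG with direct and ancestor-propagated gene assignments."""

    table: AnnotationTable
    direct: dict = field(default_factory=dict)  # gene -> frozenset of categories
    propagated: dict = field(default_factory=dict)  # gene -> closure over parents

    def genes_of(self, category: str) -> frozenset[str]:
        """All genes assigned (after propagation) to a category."""
        return frozenset(
            g for g, cats in self.propagated.items() if category in cats
        )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.propagated)

    @property
    def categories(self) -> frozenset[str]:
        return self.table.categories


def propagate_hierarchy(table: AnnotationTable) -> AnnotationHierarchy:
    """Assign each gene to the ancestor closure of its direct categories.

    Propagation is idempotent and a gene reached through several paths
    of a diamond-shaped DAG is counted once per ancestor.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(table.categories)
    graph.add_edges_from(table.links)  # edge child -> parent
    ancestors: dict[str, frozenset[str]] = {}

    def closure(cat: str) -> frozenset[str]:
        if cat not in ancestors:
            ancestors[cat] = frozenset(nx.descendants(graph, cat)) | {cat}
        return ancestors[cat]

    direct: dict[str, set[str]] = {}
    for gene, cat in table.assignments:
        direct.setdefault(gene, set()).add(cat)
    propagated = {
        g: frozenset().union(*(closure(c) for c in cats))
        for g, cats in direct.items()
    }
    return AnnotationHierarchy(
        table=table,
        direct={g: frozenset(c) for g, c in direct.items()},
        propagated=propagated,
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (in-category feature+, in-category feature-, out feature+, out feature-)."""

    in_pos: int
    in_neg: int
    out_pos: int
    out_neg: int

    def __post_init__(self):
        if min(self.in_pos, self.in_neg, self.out_pos, self.out_neg) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.in_pos + self.in_neg + self.out_pos + self.out_neg


@dataclass(frozen=True)
class EnrichmentRecord:
    """One category, one direction of a one-sided Fisher test."""

    category: str
    direction: str  # "+" over-representation / "-" under-representation
    p_value: float
    q_value: float | None
    table: ContingencyTable2x2
    flagged_empty: bool = False


def fisher_enrichment(
    hierarchy: AnnotationHierarchy,
    feature_positive: set[str],
    category: str,
    universe: set[str] | None = None,
) -> tuple[EnrichmentRecord, EnrichmentRecord]:
    """One-sided hypergeometric tail tests for over/under-representation.

    The universe defaults to every gene carried by the hierarchy.
    Returns the (over, under) record pair with raw p-values (q-values
    are attached later by :func:`enrichment_table`).
    """
    universe = set(universe) if universe is not None else set(hierarchy.genes)
    members = hierarchy.genes_of(category) & universe
    positives = set(feature_positive) & universe
    in_pos = len(members & positives)
    in_neg = len(members) - in_pos
    out_pos = len(positives) - in_pos
    out_neg = len(universe) - len(members) - out_pos
    table = ContingencyTable2x2(in_pos, in_neg, out_pos, out_neg)
    if not members:
        rec_over = EnrichmentRecord(category, "+", 1.0, None, table, flagged_empty=True)
        rec_under = EnrichmentRecord(category, "-", 1.0, None, table, flagged_empty=True)
        return rec_over, rec_under
    contingency = [[in_pos, in_neg], [out_pos, out_neg]]
    p_over = float(stats.fisher_exact(contingency, alternative="greater")[1])
    p_under = float(stats.fisher_exact(contingency, alternative="less")[1])
    return (
        EnrichmentRecord(category, "+", p_over, None, table),
        EnrichmentRecord(category, "-", p_under, None, table),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    hierarchy: AnnotationHierarchy,
    feature_positive: set[str],
    categories=None,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Fisher tests over categories with BH correction per direction.

    BH is applied separately within the over- and under-representation
    families, mirroring separate +/- result tables.
    """
    categories = sorted(categories if categories is not None else hierarchy.categories)
    records = {"+": [], "-": []}
    for cat in categories:
        over, under = fisher_enrichment(hierarchy, feature_positive, cat, universe)
        records["+"].append(over)
        records["-"].append(under)
    rows = []
    for direction, recs in records.items():
        qs = bh_fdr([r.p_value for r in recs])
        for rec, q in zip(recs, qs):
            rows.append(
                {
                    "category": rec.category,
                    "direction": direction,
                    "p_value": rec.p_value,
                    "q_value": float(q),
                    "stars": significance_stars(float(q)),
                    "n_genes": rec.table.in_pos + rec.table.in_neg,
                    "n_feature_pos": rec.table.in_pos,
                    "flagged_empty": rec.flagged_empty,
                }
            )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Star notation at the 5%, 1% and 0.1% levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Bootstrap group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap of the difference of group means (A minus B)."""

    observed_difference: float
    interval_low: float
    interval_high: float
    n_resamples: int
    significant: bool  # the central 95% interval excludes zero
    resample_mean: float
    resample_sd: float


def bootstrap_mean_difference(
    values_a,
    values_b,
    n_resamples: int = 10_000,
    seed: int | None = None,
    coverage: float = 0.95,
) -> BootstrapResult:
    """Resample both groups with replacement; the difference is called
    significant when the central 95% of the bootstrap distribution does
    not include zero."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size == 1 or b.size == 1:
        warnings.warn(
            "bootstrap with a single-observation group is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_resamples, a.size))
    idx_b = rng.integers(0, b.size, size=(n_resamples, b.size))
    diffs = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    tail = (1.0 - coverage) / 2.0
    low, high = np.quantile(diffs, [tail, 1.0 - tail])
    return BootstrapResult(
        observed_difference=float(a.mean() - b.mean()),
        interval_low=float(low),
        interval_high=float(high),
        n_resamples=n_resamples,
        significant=bool(low > 0.0 or high < 0.0),
        resample_mean=float(diffs.mean()),
        resample_sd=float(diffs.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Separation ratio and correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeparationResult:
    """Between-groups to within-groups variance ratio."""

    f_ratio: float
    infinite: bool = False


def separation_ratio(values, labels) -> SeparationResult:
    """F = weighted between-group variance / pooled within-group variance."""
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(labels))
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    grand = values.mean()
    n = values.size
    between = sum(g.size * (g.mean() - grand) ** 2 for g in groups) / n
    within = sum(((g - g.mean()) ** 2).sum() for g in groups) / n
    if within == 0:
        return SeparationResult(f_ratio=np.inf, infinite=True)
    return SeparationResult(f_ratio=float(between / within))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float


def spearman_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation with midrank ties (large-sample p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p))


# ---------------------------------------------------------------------------
# SRV-sharing dissimilarity and clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric category dissimilarity in [0, 1] with zero diagonal."""

    categories: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.categories),) * 2:
            raise ValueError("matrix shape must match category count")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix must be symmetric with zero diagonal")

    def value(self, a: str, b: str) -> float:
        i, j = self.categories.index(a), self.categories.index(b)
        return float(self.matrix[i, j])


def srv_sharing_dissimilarity(
    hierarchy: AnnotationHierarchy,
    srv_positive: set[str],
    categories,
) -> DissimilarityMatrix:
    """Jaccard dissimilarity of per-category SRV+ gene sets.

    ``d_AB = 1 - N(A ∩ B)/N(A ∪ B)``; categories with no SRV+ gene are
    excluded with a warning.
    """
    srv_positive = set(srv_positive)
    kept, sets = [], []
    for cat in categories:
        genes = hierarchy.genes_of(cat) & srv_positive
        if not genes:
            warnings.warn(
                f"category {cat!r} has no SRV+ gene; excluded from clustering",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        kept.append(cat)
        sets.append(genes)
    n = len(kept)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            m[i, j] = m[j, i] = 1.0 - inter / union
    return DissimilarityMatrix(categories=tuple(kept), matrix=m)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result over categories."""

    categories: tuple[str, ...]  # lexicographically sorted leaf order
    linkage: np.ndarray  # scipy linkage matrix

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        if len(self.categories) == 1:
            return f"({self.categories[0]}:0);"
        tree = scipy_hierarchy.to_tree(self.linkage)

        def _fmt(node, parent_height):
            if node.is_leaf():
                return f"{self.categories[node.id]}:{parent_height:.6g}"
            inner = ",".join(_fmt(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{max(parent_height - node.dist, 0.0):.6g}"

        left, right = tree.left, tree.right
        inner = ",".join(_fmt(c, tree.dist) for c in (left, right))
        return f"({inner});"


def hierarchical_cluster(matrix: DissimilarityMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with deterministic lexicographic order.

    Categories are sorted lexicographically before linkage so that tied
    merges resolve identically regardless of input order.
    """
    order = np.argsort(np.asarray(matrix.categories))
    cats = tuple(np.asarray(matrix.categories)[order])
    m = matrix.matrix[np.ix_(order, order)]
    if len(cats) < 2:
        return Dendrogram(categories=cats, linkage=np.empty((0, 4)))
    condensed = squareform(m, checks=False)
    link = scipy_hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(categories=cats, linkage=link)


# ---------------------------------------------------------------------------
# Gene-level mapping of family calls
# ---------------------------------------------------------------------------


def map_genes_to_family_calls(
    gene_to_families: dict[str, set[str]],
    family_calls: dict[str, str],
) -> dict[str, bool]:
    """A gene is feature-positive iff >= 1 of its families carries the
    positive call ('SRV+' or 'PS+'); genes with no mapped family are
    excluded with a warning."""
    out = {}
    for gene, families in gene_to_families.items():
        mapped = [f for f in families if f in family_calls]
        if not mapped:
            warnings.warn(
                f"gene {gene!r} maps to no classified family; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[gene] = any(family_calls[f].endswith("+") for f in mapped)
    return out
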