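"""Synthetic inputs: trees, codon alignments with known site categories,
annotation hierarchies and per-gene attribute tables.

The generator emulates the shape of curated protein-family alignment
collections: small families (4–30 taxa, 50–500 codons) evolved on
random coalescent-shaped trees under the same codon models the engine
fits, with per-site synonymous and nonsynonymous rate categories
recorded as ground truth.  Transition matrices come from the likelihood
engine's own eigendecomposition path, so simulator and engine agree by
construction.

All randomness flows through one seeded generator per operation call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import GeneticCode, standard_code
from .codon_engine import (
    CodonFrequencies,
    CodonSubstitutionParams,
    DiscreteRateDistribution,
    build_rate_matrix,
    uniform_frequencies,
    _eigensystem,
)
from .seqio import CodonAlignment, PhyloTree, TreeNode, make_annotation_table

__all__ = [
    "SimulationSpec",
    "SimulatedTruth",
    "simulate_tree",
    "simulate_alignment",
    "generate_annotations",
    "generate_attribute_table",
    "symmetric_syn_distribution",
    "default_nonsyn_distribution",
]


def symmetric_syn_distribution(cv: float) -> DiscreteRateDistribution:
    """A mean-one, three-category symmetric dS distribution with the given CV.

    Categories (1-d, 1, 1+d) with weights (1/4, 1/2, 1/4) give
    CV = d/sqrt(2); ``cv = 0`` collapses to a single rate of one.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return DiscreteRateDistribution(rates=np.array([1.0]), weights=np.array([1.0]))
    d = cv * np.sqrt(2.0)
    if d >= 1.0:
        # symmetric form would need a negative rate; use rates (0, 1, r)
        # with a fixed 0.2 middle weight and solve the outer weights for
        # the requested CV at mean one (r = 0.8 / w2, w0 = 0.8 - w2)
        from scipy.optimize import brentq

        def cv2_of(w2):
            return 0.8 - w2 + (0.8 - w2) ** 2 / w2

        w2 = brentq(lambda w: cv2_of(w) - cv**2, 1e-6, 0.8 - 1e-9)
        r = 0.8 / w2
        return DiscreteRateDistribution(
            rates=np.array([0.0, 1.0, r]),
            weights=np.array([0.8 - w2, 0.2, w2]),
        )
    return DiscreteRateDistribution(
        rates=np.array([1.0 - d, 1.0, 1.0 + d]), weights=np.array([0.25, 0.5, 0.25])
    )


def default_nonsyn_distribution() -> DiscreteRateDistribution:
    """A purifying-selection-dominated omega distribution typical of
    conserved protein families: most sites strongly constrained, a
    minority near neutrality."""
    return DiscreteRateDistribution(
        rates=np.array([0.05, 0.3, 1.0]), weights=np.array([0.5, 0.35, 0.15])
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated codon alignment."""

    n_taxa: int = 8
    n_codons: int = 200
    syn_dist: DiscreteRateDistribution = field(default_factory=lambda: symmetric_syn_distribution(0.0))
    nonsyn_dist: DiscreteRateDistribution = field(default_factory=default_nonsyn_distribution)
    kappa: float = 2.0
    freqs: CodonFrequencies | None = None  # None -> uniform over sense codons
    mean_branch_length: float = 0.15
    seed: int = 0


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground truth recorded alongside a simulated alignment."""

    syn_category: np.ndarray  # per-site index into spec.syn_dist
    nonsyn_category: np.ndarray  # per-site index into spec.nonsyn_dist
    spec: SimulationSpec
    tree_newick: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": np.arange(len(self.syn_category)),
                "syn_category": self.syn_category,
                "nonsyn_category": self.nonsyn_category,
                "syn_rate": self.spec.syn_dist.rates[self.syn_category],
                "nonsyn_rate": self.spec.nonsyn_dist.rates[self.nonsyn_category],
            }
        )


def simulate_tree(n_taxa: int, mean_branch_length: float, seed: int | None = None) -> PhyloTree:
    """A random coalescent-shaped topology with exponential branch lengths.

    Lineages are merged in random pairs until one remains; every branch
    length is an independent Exponential draw with the given mean.  For
    ``n_taxa >= 3`` the root is trifurcating (unrooted convention).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    lineages = [TreeNode(name=f"t{i+1}") for i in range(n_taxa)]
    while len(lineages) > 3 if n_taxa >= 3 else len(lineages) > 2:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(TreeNode(name=None, children=[a, b]))
    root = TreeNode(name=None, children=lineages)
    tree = PhyloTree(root=root)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(rng.exponential(mean_branch_length))
    return tree


def simulate_alignment(
    spec: SimulationSpec, tree: PhyloTree | None = None
) -> tuple[CodonAlignment, SimulatedTruth]:
    """Evolve a codon alignment down a tree under the spec's mixture model.

    Per site, a (dS, dN) category pair is drawn from the spec's
    distributions; the root codon is drawn from the stationary
    frequencies and each branch applies ``exp(Q t)`` for that site's
    category.  Returns the alignment and the per-site truth.
    """
    code = standard_code()
    rng = np.random.default_rng(spec.seed)
    if tree is None:
        tree = simulate_tree(spec.n_taxa, spec.mean_branch_length, seed=int(rng.integers(2**31)))
    freqs = spec.freqs or uniform_frequencies(code)
    pi = freqs.values
    n_sites = spec.n_codons

    syn_cat = rng.choice(spec.syn_dist.k, size=n_sites, p=spec.syn_dist.weights)
    nonsyn_cat = rng.choice(spec.nonsyn_dist.k, size=n_sites, p=spec.nonsyn_dist.weights)

    # eigendecomposition per distinct category pair (engine-shared code path)
    systems = {}
    for i in range(spec.syn_dist.k):
        for j in range(spec.nonsyn_dist.k):
            params = CodonSubstitutionParams(
                kappa=spec.kappa,
                alpha=float(spec.syn_dist.rates[i]),
                beta=float(spec.nonsyn_dist.rates[j]),
                freqs=freqs,
            )
            q = build_rate_matrix(params, code)
            systems[(i, j)] = _eigensystem(q, pi)

    def transition(pair, t):
        lam, a, b = systems[pair]
        p = (a * np.exp(lam * t)[None, :]) @ b
        p = np.maximum(p, 0.0)
        p /= p.sum(axis=1, keepdims=True)
        return p

    # states per node, evolved root -> leaves
    root_states = rng.choice(len(pi), size=n_sites, p=pi)
    leaf_rows: dict[str, np.ndarray] = {}

    def _evolve(node: TreeNode, states: np.ndarray):
        if node.is_leaf:
            leaf_rows[node.name] = states
            return
        for child in node.children:
            child_states = states.copy()
            for pair in set(zip(syn_cat, nonsyn_cat)):
                mask = (syn_cat == pair[0]) & (nonsyn_cat == pair[1])
                p = transition(pair, child.length)
                # vectorized categorical draw per site via inverse CDF
                cdf = np.cumsum(p[states[mask]], axis=1)
                u = rng.random(mask.sum())
                child_states[mask] = (u[:, None] > cdf).sum(axis=1)
            _evolve(child, child_states)

    _evolve(tree.root, root_states)

    codons = code.sense_codons
    ids, rows = [], []
    for leaf in tree.leaves():
        ids.append(leaf.name)
        rows.append("".join(codons[s] for s in leaf_rows[leaf.name]))
    aln = CodonAlignment(ids=tuple(ids), rows=tuple(rows), code=code)
    truth = SimulatedTruth(
        syn_category=syn_cat,
        nonsyn_category=nonsyn_cat,
        spec=spec,
        tree_newick=tree.newick(),
    )
    return aln, truth


def generate_annotations(
    n_genes: int,
    n_categories: int,
    depth: int,
    planted_category: str | None = None,
    planted_odds_ratio: float = 1.0,
    feature_rate: float = 0.3,
    seed: int | None = None,
    assignments_per_gene: int = 2,
):
    """Random annotation DAG plus feature flags with a planted enrichment.

    Categories are arranged in ``depth`` levels; each non-root category
    links to one random parent in the level above (a tree-shaped DAG,
    with occasional second parents to exercise diamond closure).  Genes
    are assigned to random leaf-level categories.  Feature-positive
    labels are drawn at ``feature_rate`` baseline odds, shifted by
    ``planted_odds_ratio`` for genes inside the planted category.

    Returns ``(AnnotationTable, feature_flags: dict[str, bool])``.
    """
    if planted_odds_ratio <= 0:
        raise ValueError("odds ratio must be > 0")
    rng = np.random.default_rng(seed)
    levels: list[list[str]] = []
    remaining = n_categories
    for d in range(depth):
        size = max(1, remaining // (depth - d)) if d < depth - 1 else remaining
        levels.append([f"L{d}C{i}" for i in range(size)])
        remaining -= size
    links = []
    for d in range(1, depth):
        for cat in levels[d]:
            parent = levels[d - 1][rng.integers(len(levels[d - 1]))]
            links.append((cat, parent))
            if len(levels[d - 1]) > 1 and rng.random() < 0.1:
                second = levels[d - 1][rng.integers(len(levels[d - 1]))]
                if second != parent:
                    links.append((cat, second))
    leaf_level = levels[-1]
    genes = [f"g{i}" for i in range(n_genes)]
    assignments = []
    direct: dict[str, set[str]] = {}
    for g in genes:
        k = min(assignments_per_gene, len(leaf_level))
        cats = rng.choice(len(leaf_level), size=k, replace=False)
        direct[g] = {leaf_level[c] for c in cats}
        for c in cats:
            assignments.append((g, leaf_level[c]))
    table = make_annotation_table(assignments, links)

    base_odds = feature_rate / (1.0 - feature_rate)
    flags = {}
    for g in genes:
        odds = base_odds
        if planted_category is not None and planted_category in direct[g]:
            odds *= planted_odds_ratio
        flags[g] = bool(rng.random() < odds / (1.0 + odds))
    return table, flags


def generate_attribute_table(
    gene_flags: dict[str, bool],
    effect_sizes: dict[str, float],
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene attributes: flag-dependent mean shift plus Gaussian noise.

    ``effect_sizes`` maps attribute name to the difference between the
    flag-positive and flag-negative group means (in attribute units);
    flag-negative genes are centred at zero.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_flags)
    data = {"gene": genes}
    for attr, effect in effect_sizes.items():
        shift = np.array([effect if gene_flags[g] else 0.0 for g in genes])
        data[attr] = shift + rng.normal(0.0, noise_sd, size=len(genes))
    return pd.DataFrame(data).set_index("gene")
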