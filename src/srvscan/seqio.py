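"""Input/output for codon alignments, trees and annotation tables.

FASTA is the single supported alignment dialect (lowercase is folded to
uppercase and RNA ``U`` mapped to ``T``); Newick trees must carry branch
lengths; annotation tables are TSV.  Every reader validates its input
before anything downstream touches it: the likelihood engine assumes
in-frame, stop-free codon rows and a tree whose leaves match the
alignment exactly.

Ambiguity codes other than ``N`` are rejected because the likelihood
engine supports only the fully-missing state (gap or ``N``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import pandas as pd
from Bio import SeqIO

from .codes import GeneticCode, standard_code

VALID_CHARS = frozenset("ACGTN-")
MISSING_CHARS = frozenset("N-")


class SeqIOError(ValueError):
    """Base class for input validation failures."""


class FrameError(SeqIOError):
    """Sequence length is not a multiple of three."""


class StopCodonError(SeqIOError):
    """An in-frame stop codon was found in a coding row."""


class IdentityError(SeqIOError):
    """Duplicate or mismatched sequence identifiers."""


class TreeError(SeqIOError):
    """Malformed or invalid Newick input."""


class CycleError(SeqIOError):
    """Annotation parent links contain a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"annotation parent links contain a cycle: {self.cycle}")


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame alignment of protein-coding nucleotide sequences.

    Rows are aligned strings over ``{A,C,G,T,N,-}`` of equal length
    divisible by three; no ungapped in-frame codon may be a stop codon
    under the active genetic code.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        validate_codon_alignment(self.ids, self.rows, self.code)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Alignment length in nucleotides."""
        return len(self.rows[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, row: int, site: int) -> str:
        """The codon triplet of sequence ``row`` at codon ``site``."""
        return self.rows[row][3 * site : 3 * site + 3]

    def ungapped_codon_count(self, row: int) -> int:
        """Number of codons in a row containing no gap or N character."""
        seq = self.rows[row]
        return sum(
            1
            for i in range(0, len(seq), 3)
            if not (set(seq[i : i + 3]) & MISSING_CHARS)
        )

    def ungapped_sequence(self, row: int) -> str:
        """Concatenation of the fully-resolved codons of a row."""
        seq = self.rows[row]
        return "".join(
            seq[i : i + 3]
            for i in range(0, len(seq), 3)
            if not (set(seq[i : i + 3]) & MISSING_CHARS)
        )


def validate_codon_alignment(ids, rows, code: GeneticCode) -> None:
    if len(ids) != len(rows):
        raise IdentityError("number of identifiers does not match number of rows")
    if len(ids) < 2:
        raise SeqIOError("a codon alignment requires at least 2 sequences")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise IdentityError(f"duplicate sequence identifiers: {dupes}")
    length = len(rows[0])
    for name, row in zip(ids, rows):
        if len(row) != length:
            raise SeqIOError(f"row {name!r} has length {len(row)}, expected {length}")
    if length % 3 != 0:
        raise FrameError(f"alignment length {length} is not a multiple of 3")
    for name, row in zip(ids, rows):
        bad = set(row) - VALID_CHARS
        if bad:
            raise SeqIOError(
                f"row {name!r} contains unsupported characters {sorted(bad)}; "
                "only A,C,G,T,N,- are accepted"
            )
        for i in range(0, length, 3):
            codon = row[i : i + 3]
            if set(codon) & MISSING_CHARS:
                continue
            if code.is_stop(codon):
                raise StopCodonError(
                    f"in-frame stop codon {codon} in sequence {name!r} "
                    f"at codon position {i // 3 + 1}"
                )


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_codon_alignment(path, code: GeneticCode | None = None) -> CodonAlignment:
    """Read and validate an in-frame codon alignment from FASTA."""
    code = code or standard_code()
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalize(str(rec.seq)))
    if not ids:
        raise SeqIOError(f"no FASTA records found in {path}")
    return CodonAlignment(ids=tuple(ids), rows=tuple(rows), code=code)


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f">{name}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """A node of a rooted representation of an (unrooted) phylogeny."""

    name: str | None = None
    length: float = 0.0  # branch length above this node; 0 at the root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Phylogenetic tree with branch lengths.

    Stored rooted at an internal node; for ``T >= 3`` taxa the root is
    canonicalized to degree three so that the representation corresponds
    to an unrooted tree.  Branch lengths are non-negative and carry
    whatever unit the caller's pipeline assigns (expected substitutions
    per codon site for the likelihood engine; per amino-acid site for
    the divergence filter).
    """

    root: TreeNode

    def postorder(self):
        out = []

        def _walk(node):
            for child in node.children:
                _walk(child)
            out.append(node)

        _walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    @property
    def n_branches(self) -> int:
        return sum(1 for n in self.postorder() if n is not self.root)

    def scaled(self, factor: float) -> "PhyloTree":
        """A copy with every branch length multiplied by ``factor``."""

        def _copy(node, at_root):
            return TreeNode(
                name=node.name,
                length=0.0 if at_root else node.length * factor,
                children=[_copy(c, False) for c in node.children],
            )

        return PhyloTree(root=_copy(self.root, True))

    def copy(self) -> "PhyloTree":
        return self.scaled(1.0)

    def newick(self) -> str:
        def _fmt(node):
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(_fmt(c) for c in node.children)
            if node.length:
                return f"({inner}):{node.length:.10g}"
            return f"({inner})"

        inner = ",".join(_fmt(c) for c in self.root.children)
        return f"({inner});"


def _from_dendropy(node) -> TreeNode:
    length = node.edge.length
    children = node.child_nodes()
    return TreeNode(
        name=node.taxon.label if node.taxon is not None else None,
        # None is kept here so the missing-length check in parse_newick fires
        length=length if length is None else float(length),
        children=[_from_dendropy(c) for c in children],
    )


def _canonicalize_unrooted(root: TreeNode, n_leaves: int) -> TreeNode:
    """Suppress a degree-2 root so unrooted trees have a trifurcating root."""
    while len(root.children) == 2 and n_leaves >= 3:
        left, right = root.children
        # merge the root bifurcation into whichever child is internal
        internal = left if not left.is_leaf else right
        other = right if internal is left else left
        other = TreeNode(
            name=other.name,
            length=other.length + internal.length,
            children=other.children,
        )
        root = TreeNode(name=None, length=0.0, children=internal.children + [other])
    return root


def parse_newick(newick: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick input: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    tree = PhyloTree(root=root)
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise TreeError("a tree requires at least 2 leaves")
    names = [n.name for n in leaves]
    if None in names or len(set(names)) != len(names):
        raise TreeError("leaf labels must be present and unique")
    for node in tree.postorder():
        if node is tree.root:
            node.length = 0.0
            continue
        if node.length is None:
            raise TreeError(
                f"missing branch length above {node.name or 'an internal node'}"
            )
        if node.length < 0:
            raise TreeError(
                f"negative branch length {node.length} above "
                f"{node.name or 'an internal node'}"
            )
    tree.root = _canonicalize_unrooted(tree.root, len(leaves))
    tree.root.length = 0.0
    return tree


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise TreeError(f"empty Newick file: {path}")
    return parse_newick(text)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def check_tree_matches_alignment(tree: PhyloTree, aln: CodonAlignment) -> None:
    """Raise if tree leaf labels and alignment identifiers differ."""
    t, a = set(tree.leaf_names), set(aln.ids)
    if t != a:
        raise IdentityError(
            f"tree/alignment label mismatch: only in tree {sorted(t - a)}, "
            f"only in alignment {sorted(a - t)}"
        )


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationTable:
    """Gene-to-category assignments plus a parent-link DAG over categories."""

    assignments: tuple[tuple[str, str], ...]  # (gene, category)
    links: tuple[tuple[str, str], ...]  # (child category, parent category)

    def __post_init__(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.categories)
        graph.add_edges_from(self.links)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = [u for u, _ in nx.find_cycle(graph)]
            raise CycleError(cycle)

    @property
    def categories(self) -> frozenset[str]:
        cats = {c for _, c in self.assignments}
        for child, parent in self.links:
            cats.add(child)
            cats.add(parent)
        return frozenset(cats)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.assignments)


def make_annotation_table(assignments, links) -> AnnotationTable:
    """Build an :class:`AnnotationTable`, deduplicating assignments/links."""
    seen_a, dedup_a = set(), []
    for pair in assignments:
        pair = (str(pair[0]), str(pair[1]))
        if pair not in seen_a:
            seen_a.add(pair)
            dedup_a.append(pair)
    seen_l, dedup_l = set(), []
    for pair in links:
        pair = (str(pair[0]), str(pair[1]))
        if pair not in seen_l:
            seen_l.add(pair)
            dedup_l.append(pair)
    return AnnotationTable(assignments=tuple(dedup_a), links=tuple(dedup_l))


def read_annotation_table(path) -> AnnotationTable:
    """Read a TSV with columns gene, category, child, parent.

    Each row fills either (gene, category) — an assignment — or
    (child, parent) — a hierarchy link.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"gene", "category", "child", "parent"}
    missing = needed - set(df.columns)
    if missing:
        raise SeqIOError(f"annotation table missing columns: {sorted(missing)}")
    assignments = [
        (r.gene, r.category)
        for r in df.itertuples()
        if r.gene and r.category
    ]
    links = [(r.child, r.parent) for r in df.itertuples() if r.child and r.parent]
    return make_annotation_table(assignments, links)


def write_annotation_table(table: AnnotationTable, path) -> None:
    rows = [
        {"gene": g, "category": c, "child": "", "parent": ""}
        for g, c in table.assignments
    ] + [
        {"gene": "", "category": "", "child": ch, "parent": p}
        for ch, p in table.links
    ]
    pd.DataFrame(rows, columns=["gene", "category", "child", "parent"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Auxiliary TSV tables
# ---------------------------------------------------------------------------


def read_optimal_codons(path) -> dict[str, frozenset[str]]:
    """TSV with columns ``amino_acid`` and ``codon`` -> optimal codon sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.amino_acid, set()).add(_normalize(r.codon))
    return {aa: frozenset(cs) for aa, cs in out.items()}


def read_trna_mapping(path) -> dict[str, str]:
    """TSV with columns ``codon`` and ``trna`` -> codon-to-tRNA mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {_normalize(r.codon): r.trna for r in df.itertuples()}


def read_attribute_table(path) -> pd.DataFrame:
    """Per-gene attribute TSV; first column must be ``gene``."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise SeqIOError("attribute table must start with a 'gene' column")
    return df.set_index("gene")


def alignment_from_strings(text: str, code: GeneticCode | None = None) -> CodonAlignment:
    """Parse FASTA text held in memory (convenience for tests/pipelines)."""
    code = code or standard_code()
    ids, rows = [], []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        ids.append(rec.id)
        rows.append(_normalize(str(rec.seq)))
    if not ids:
        raise SeqIOError("no FASTA records in input text")
    return CodonAlignment(ids=tuple(ids), rows=tuple(rows), code=code)
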