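"""Domain types shared by the whole toolkit.

Orthologs are delineated at *levels of orthology*: internal nodes of a rooted
species tree, each standing for the radiation (last common ancestor) of the
species in its subtree.  This module holds the entities every other stage
consumes — genes, proteomes, the species tree with addressable levels — plus
dataset validation.

Species identifiers are free strings; they are not required to be taxonomy
ids, so simulated and real datasets are handled uniformly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class OrthokitError(Exception):
    """Base class for all toolkit errors."""


class NewickParseError(OrthokitError):
    """Malformed Newick input; message names the character offset where known."""


class ValidationError(OrthokitError):
    """An invariant of a domain type was violated."""


class UnknownLabelError(OrthokitError, KeyError):
    """A species/level label does not name a node of the tree."""

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class Gene:
    """One protein-coding gene: the atom of orthology.

    ``gene_id`` must be globally unique across the dataset; ``sequence`` is an
    amino-acid string over the 20 standard residues plus ``X``.
    """

    gene_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be nonempty")
        if not self.species_id:
            raise ValidationError(f"gene {self.gene_id!r}: species_id must be nonempty")
        if not self.sequence:
            raise ValidationError(f"gene {self.gene_id!r}: sequence must be nonempty")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValidationError(
                f"gene {self.gene_id!r}: illegal residue {self.sequence[pos]!r} "
                f"at position {pos}"
            )


@dataclass
class Proteome:
    """All genes of one species, in a stable order."""

    species_id: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.species_id != self.species_id:
                raise ValidationError(
                    f"gene {g.gene_id!r} has species {g.species_id!r}, "
                    f"expected {self.species_id!r}"
                )
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r} in proteome")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


class SpeciesTree:
    """Rooted species tree whose labelled internal nodes are orthology levels.

    Leaf labels are species ids.  Internal nodes without a label in the input
    receive deterministic synthetic labels ``nd1``, ``nd2``, ... in preorder,
    so every level is addressable by name.  Branch lengths are optional
    (required only by the gene-family simulator).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_nodes()
        self._index()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return parse_newick(text)

    def _label_nodes(self) -> None:
        counter = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is not None and node.label is None:
                    node.label = node.taxon.label
            elif not node.label:
                counter += 1
                node.label = f"nd{counter}"

    def _index(self) -> None:
        self._nodes: dict[str, dendropy.Node] = {}
        leaves: list[str] = []
        internals: list[str] = []
        for node in self._tree.preorder_node_iter():
            label = node.label
            if label is None or label == "":
                raise ValidationError("tree contains an unlabelled leaf")
            if label in self._nodes:
                kind = "leaf" if node.is_leaf() else "internal"
                raise ValidationError(f"duplicate {kind} label {label!r} in tree")
            self._nodes[label] = node
            (leaves if node.is_leaf() else internals).append(label)
        self._leaf_labels = leaves
        self._internal_labels = internals
        # leaf sets per node, computed once
        self._species_under: dict[str, frozenset[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                self._species_under[node.label] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for child in node.child_nodes():
                    acc |= self._species_under[child.label]
                self._species_under[node.label] = frozenset(acc)

    # -- queries ---------------------------------------------------------

    @property
    def species(self) -> list[str]:
        """Leaf labels in preorder."""
        return list(self._leaf_labels)

    @property
    def levels(self) -> list[str]:
        """Internal-node labels in preorder (root first)."""
        return list(self._internal_labels)

    @property
    def root_label(self) -> str:
        return self._tree.seed_node.label

    def has_node(self, label: str) -> bool:
        return label in self._nodes

    def is_leaf(self, label: str) -> bool:
        return self._node(label).is_leaf()

    def _node(self, label: str) -> dendropy.Node:
        try:
            return self._nodes[label]
        except KeyError:
            raise UnknownLabelError(f"no node labelled {label!r} in species tree") from None

    def species_under(self, label: str) -> frozenset[str]:
        """Leaf set of the subtree rooted at ``label`` (singleton for a leaf)."""
        self._node(label)
        return self._species_under[label]

    def children(self, label: str) -> list[str]:
        return [c.label for c in self._node(label).child_nodes()]

    def parent(self, label: str) -> str | None:
        p = self._node(label).parent_node
        return None if p is None else p.label

    def branch_length(self, label: str) -> float | None:
        """Length of the branch above ``label`` (None at the root or if absent)."""
        return self._node(label).edge.length

    def has_branch_lengths(self) -> bool:
        return all(
            n.edge.length is not None
            for n in self._tree.preorder_node_iter()
            if n.parent_node is not None
        )

    def postorder_labels(self) -> list[str]:
        return [n.label for n in self._tree.postorder_node_iter()]

    def ancestors(self, label: str) -> list[str]:
        """Labels from the node's parent up to the root, in that order."""
        out: list[str] = []
        node = self._node(label).parent_node
        while node is not None:
            out.append(node.label)
            node = node.parent_node
        return out

    def level(self, label: str) -> "Level":
        node = self._node(label)
        if node.is_leaf():
            raise ValidationError(f"{label!r} is a leaf, not a level of orthology")
        return Level(label=label, species_set=self._species_under[label])

    # -- output ----------------------------------------------------------

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self._tree.write(
            file=buf,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_leaf_taxon_labels=False,
            real_value_format_specifier=".12g",
        )
        return buf.getvalue().strip()


@dataclass(frozen=True)
class Level:
    """A level of orthology: a named internal node and the species below it."""

    label: str
    species_set: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.species_set) < 2:
            raise ValidationError(
                f"level {self.label!r} spans {len(self.species_set)} species; "
                "a level of orthology needs at least 2"
            )


def parse_newick(text: str) -> SpeciesTree:
    """Parse a single rooted Newick tree into a :class:`SpeciesTree`.

    Unlabelled internal nodes receive synthetic preorder labels ``nd1``,
    ``nd2``, ...  Raises :class:`NewickParseError` on malformed input (naming
    the character offset where it can be determined) and
    :class:`ValidationError` on duplicate leaf labels.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick input at character offset 0")
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"Newick tree not terminated by ';' at character offset {len(text)}"
        )
    try:
        tree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf labels in tree: {exc}") from exc
        offset = getattr(exc, "col_num", None)
        loc = f" at character offset {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed Newick{loc}: {exc}") from exc
    st = SpeciesTree(tree)
    for bl in (st.branch_length(lbl) for lbl in st._nodes):
        if bl is not None and bl < 0:
            raise ValidationError("negative branch length in species tree")
    return st


def species_under(tree: SpeciesTree, level_label: str) -> frozenset[str]:
    """Leaf set of the subtree below ``level_label`` (module-level convenience)."""
    return tree.species_under(level_label)


@dataclass
class ValidationReport:
    """Report-only dataset check; callers decide whether to abort."""

    missing_proteomes: list[str] = field(default_factory=list)
    extra_proteomes: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing_proteomes or self.extra_proteomes or self.errors)

    def lines(self) -> list[str]:
        out = [f"missing proteome: {s}" for s in self.missing_proteomes]
        out += [f"proteome not in tree: {s}" for s in self.extra_proteomes]
        out += [f"error: {msg}" for msg in self.errors]
        return out


def validate_dataset(
    proteomes: Iterable[Proteome], tree: SpeciesTree
) -> ValidationReport:
    """Cross-check proteomes against tree leaves and gene-id uniqueness."""
    report = ValidationReport()
    proteomes = list(proteomes)
    have = {p.species_id for p in proteomes}
    leaves = set(tree.species)
    report.missing_proteomes = sorted(leaves - have)
    report.extra_proteomes = sorted(have - leaves)
    owner: dict[str, str] = {}
    for p in sorted(proteomes, key=lambda p: p.species_id):
        for g in p:
            if g.gene_id in owner:
                report.errors.append(
                    f"duplicate gene_id {g.gene_id!r} in species "
                    f"{owner[g.gene_id]!r} and {p.species_id!r}"
                )
            else:
                owner[g.gene_id] = p.species_id
    return report


def species_of_map(proteomes: Iterable[Proteome]) -> dict[str, str]:
    """gene_id -> species_id over a collection of proteomes."""
    out: dict[str, str] = {}
    for p in proteomes:
        for g in p:
            out[g.gene_id] = g.species_id
    return out


def sequence_map(proteomes: Iterable[Proteome]) -> dict[str, str]:
    """gene_id -> sequence over a collection of proteomes."""
    return {g.gene_id: g.sequence for p in proteomes for g in p}
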