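"""Best-reciprocal-hit delineation of orthologous groups.

For each pair of species, a gene pair in which each gene is the other's
highest-scoring hit (a best-reciprocal-hit, BRH) is a candidate ortholog
pair: the BRH criterion is a proxy for reconciling the gene tree with that
species pair.  Candidates are clustered into orthologous groups (OGs) as
connected components of the BRH graph, per level of orthology.  Recent
within-species duplicates (in-paralogs) can be attached to a clustered gene
when they are closer to it than that gene's best cross-species partner.

Two clustering modes are provided: per-level ab-initio clustering
(:func:`cluster_level`) and a tree mode (:func:`cluster_tree_mode`) that
walks the species tree post-order, merging child clusters only through BRH
edges that cross between child subtrees, which yields a nested hierarchy by
construction.

All tie-breaks are lexicographic so identical inputs give byte-identical
outputs regardless of input order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core import OrthokitError, SpeciesTree, UnknownLabelError
from .homology import HitTable


@dataclass(frozen=True, order=True)
class BRHPair:
    """A best-reciprocal-hit between two genes of different species.

    ``gene_a < gene_b`` lexicographically; both directed hits exist in the
    source hit table.
    """

    gene_a: str
    gene_b: str
    score_ab: float
    score_ba: float

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError("BRHPair genes must be in lexicographic order")

    @property
    def score(self) -> float:
        return max(self.score_ab, self.score_ba)

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class OrthologousGroup:
    """Genes descending from a single ancestral gene at one level."""

    og_id: str
    level_label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"OG {self.og_id}: needs >= 2 members")

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass
class OGHierarchy:
    """Per-level OG sets with parent links (tree mode output).

    ``by_level`` maps a level label to its OGs; ``parents`` maps an og_id to
    {ancestral level label: containing og_id}.  Child members are a subset of
    the parent's members at every link.
    """

    by_level: dict[str, list[OrthologousGroup]] = field(default_factory=dict)
    parents: dict[str, dict[str, str]] = field(default_factory=dict)
    unassigned: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def levels(self) -> list[str]:
        return list(self.by_level)

    def ogs_at(self, level_label: str) -> list[OrthologousGroup]:
        try:
            return self.by_level[level_label]
        except KeyError:
            raise UnknownLabelError(f"no OGs computed at level {level_label!r}") from None

    def all_ogs(self) -> list[OrthologousGroup]:
        return [og for ogs in self.by_level.values() for og in ogs]

    def parent_of(self, og_id: str, ancestor_level: str) -> str | None:
        return self.parents.get(og_id, {}).get(ancestor_level)


def best_hits(
    hits: HitTable, from_species: str, to_species: str
) -> dict[str, tuple[str, float]]:
    """Best-scoring target in ``to_species`` for each gene of ``from_species``.

    Ties go to the lexicographically smallest target gene id.  Genes with no
    hit into the target species are absent from the map.
    """
    if from_species == to_species:
        raise ValueError("best_hits requires two distinct species")
    best: dict[str, tuple[str, float]] = {}
    for q, t, s in hits.items():
        if hits.species_of.get(q) != from_species:
            continue
        if hits.species_of.get(t) != to_species:
            continue
        cur = best.get(q)
        if cur is None or s > cur[1] or (s == cur[1] and t < cur[0]):
            best[q] = (t, s)
    return best


def brh_pairs(hits: HitTable, species_a: str, species_b: str) -> set[BRHPair]:
    """Reciprocal best hits between two species."""
    fwd = best_hits(hits, species_a, species_b)
    rev = best_hits(hits, species_b, species_a)
    out: set[BRHPair] = set()
    for ga, (gb, s_ab) in fwd.items():
        back = rev.get(gb)
        if back is not None and back[0] == ga:
            x, y = sorted((ga, gb))
            sxy = s_ab if x == ga else back[1]
            syx = back[1] if x == ga else s_ab
            out.add(BRHPair(x, y, sxy, syx))
    return out


def brh_pairs_at_level(hits: HitTable, species: Iterable[str]) -> set[BRHPair]:
    """Union of BRH pairs over every species pair within a level."""
    present = sorted(set(species) & set(hits.species_of.values()))
    out: set[BRHPair] = set()
    for a, b in combinations(present, 2):
        out |= brh_pairs(hits, a, b)
    return out


def attach_inparalogs(
    hits: HitTable, brh: set[BRHPair], level_species: Iterable[str]
) -> list[tuple[str, str]]:
    """Attach unplaced within-species duplicates to BRH-anchored genes.

    A gene g (of a level species, in no BRH pair at this level) is attached
    to a same-species anchor m that is in a BRH pair iff the within-species
    score(g, m) is at least the best BRH score of m — i.e. g is closer to m
    than m's closest cross-species ortholog, the usual in-paralog criterion.
    Each gene attaches to at most one anchor (best score, then smallest id).
    Returns (gene, anchor) edges.
    """
    level_species = set(level_species)
    anchors: set[str] = set()
    brh_max: dict[str, float] = {}
    for pair in brh:
        for g in pair.genes:
            anchors.add(g)
            brh_max[g] = max(brh_max.get(g, 0.0), pair.score)
    attachments: list[tuple[str, str]] = []
    genes_by_species: dict[str, list[str]] = {}
    for gid, sp in hits.species_of.items():
        if sp in level_species:
            genes_by_species.setdefault(sp, []).append(gid)
    for sp in sorted(genes_by_species):
        sp_anchors = sorted(a for a in anchors if hits.species_of[a] == sp)
        if not sp_anchors:
            continue
        for g in sorted(genes_by_species[sp]):
            if g in anchors:
                continue
            best: tuple[float, str] | None = None
            for m in sp_anchors:
                s = hits.symmetric_score(g, m)
                if s is None or s < brh_max[m]:
                    continue
                if best is None or s > best[0] or (s == best[0] and m < best[1]):
                    best = (s, m)
            if best is not None:
                attachments.append((g, best[1]))
    return attachments


def _components_to_ogs(
    components: Iterable[frozenset[str]],
    level_label: str,
    species_of: Mapping[str, str],
) -> tuple[list[OrthologousGroup], list[tuple[str, str]]]:
    """Turn gene components into numbered OGs; single-species ones are unassigned."""
    keep: list[frozenset[str]] = []
    unassigned: list[tuple[str, str]] = []
    for comp in components:
        n_species = len({species_of[g] for g in comp})
        if n_species >= 2:
            keep.append(comp)
        else:
            reason = "no_brh" if len(comp) == 1 else "single_species"
            unassigned.extend((g, reason) for g in sorted(comp))
    keep.sort(key=lambda c: (-len(c), min(c)))
    ogs = [
        OrthologousGroup(f"og{i}at{level_label}", level_label, comp)
        for i, comp in enumerate(keep, start=1)
    ]
    unassigned.sort()
    return ogs, unassigned


def cluster_level(
    brh: set[BRHPair],
    attachments: Sequence[tuple[str, str]],
    species_of: Mapping[str, str],
    tree: SpeciesTree,
    level_label: str,
) -> tuple[list[OrthologousGroup], list[tuple[str, str]]]:
    """Ab-initio OGs at one level: connected components of the BRH graph.

    Vertices are all genes of the level's species; edges are BRH pairs whose
    species both lie within the level, plus in-paralog attachments.
    Components touching a single species are not OGs; their genes are
    returned as (gene_id, reason) unassigned records alongside genes with no
    edges at all.  OG ids are ``og{n}at{level}`` with n ordered by descending
    size then smallest member gene id.
    """
    level_species = tree.species_under(level_label)
    if len(level_species) < 2:
        raise OrthokitError(
            f"level {level_label!r} spans fewer than 2 species; cannot cluster"
        )
    graph: nx.Graph = nx.Graph()
    for gid, sp in species_of.items():
        if sp in level_species:
            graph.add_node(gid)
    for pair in brh:
        sa = species_of.get(pair.gene_a)
        sb = species_of.get(pair.gene_b)
        if sa in level_species and sb in level_species:
            graph.add_edge(pair.gene_a, pair.gene_b)
    for g, anchor in attachments:
        if species_of.get(g) in level_species and species_of.get(anchor) in level_species:
            graph.add_edge(g, anchor)
    components = [frozenset(c) for c in nx.connected_components(graph)]
    return _components_to_ogs(components, level_label, species_of)


def cluster_at_level(
    hits: HitTable,
    tree: SpeciesTree,
    level_label: str,
    inparalogs: bool = True,
) -> tuple[list[OrthologousGroup], list[tuple[str, str]]]:
    """Convenience: BRH computation + optional in-paralog attachment + clustering."""
    species = tree.species_under(level_label)
    brh = brh_pairs_at_level(hits, species)
    attachments = attach_inparalogs(hits, brh, species) if inparalogs else []
    return cluster_level(brh, attachments, hits.species_of, tree, level_label)


def cluster_tree_mode(
    hits: HitTable,
    tree: SpeciesTree,
    inparalogs: bool = True,
    min_crossing_edges: int = 1,
) -> OGHierarchy:
    """Hierarchical clustering along the species tree (tree mode).

    Post-order over internal nodes: each node inherits its children's
    clusters (leaves contribute single genes) and merges clusters joined by
    at least ``min_crossing_edges`` BRH edges crossing between different
    child subtrees; in-paralog attachments for the node's level are then
    applied as additional merges.  Because clusters are only ever merged on
    the way up, every child-level OG is contained in exactly one cluster at
    each ancestral level, so the hierarchy nests by construction.
    """
    if len(tree.species) < 2:
        raise OrthokitError("tree mode needs a tree with >= 2 leaves")
    species_of = hits.species_of
    all_brh: set[BRHPair] = brh_pairs_at_level(hits, tree.species)

    # union-find over genes, grown post-order
    parent: dict[str, str] = {g: g for g in species_of}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            if rb < ra:  # smallest id as representative, for determinism
                ra, rb = rb, ra
            parent[rb] = ra

    hierarchy = OGHierarchy()
    member_og: dict[str, dict[str, str]] = {}  # level -> gene -> og_id
    level_order: list[str] = []  # post-order, so ancestors come after children

    for label in tree.postorder_labels():
        if tree.is_leaf(label):
            continue
        children = tree.children(label)
        subtree_of: dict[str, str] = {}
        for child in children:
            for sp in tree.species_under(child):
                subtree_of[sp] = child
        crossing = [
            pair
            for pair in all_brh
            if subtree_of.get(species_of[pair.gene_a]) is not None
            and subtree_of.get(species_of[pair.gene_b]) is not None
            and subtree_of[species_of[pair.gene_a]] != subtree_of[species_of[pair.gene_b]]
        ]
        if min_crossing_edges <= 1:
            for pair in sorted(crossing):
                union(pair.gene_a, pair.gene_b)
        else:
            _merge_with_support(crossing, find, union, min_crossing_edges)
        level_species = tree.species_under(label)
        if inparalogs:
            level_brh = {
                p
                for p in all_brh
                if species_of[p.gene_a] in level_species
                and species_of[p.gene_b] in level_species
            }
            for g, anchor in attach_inparalogs(hits, level_brh, level_species):
                union(g, anchor)
        # snapshot clusters restricted to this subtree
        clusters: dict[str, set[str]] = {}
        for g, sp in species_of.items():
            if sp in level_species:
                clusters.setdefault(find(g), set()).add(g)
        ogs, unassigned = _components_to_ogs(
            (frozenset(c) for c in clusters.values()), label, species_of
        )
        hierarchy.by_level[label] = ogs
        hierarchy.unassigned[label] = unassigned
        member_og[label] = {g: og.og_id for og in ogs for g in og.members}
        level_order.append(label)

    # parent links: later entries in post-order that contain a member
    for i, label in enumerate(level_order):
        ancestors = set(tree.ancestors(label))
        for og in hierarchy.by_level[label]:
            probe = min(og.members)
            links: dict[str, str] = {}
            for anc in level_order[i + 1 :]:
                if anc in ancestors and probe in member_og[anc]:
                    links[anc] = member_og[anc][probe]
            hierarchy.parents[og.og_id] = links
    return hierarchy


def _merge_with_support(crossing, find, union, min_edges: int) -> None:
    """Merge clusters joined by >= min_edges crossing edges, to a fixpoint."""
    while True:
        support: dict[tuple[str, str], int] = {}
        for pair in crossing:
            ra, rb = find(pair.gene_a), find(pair.gene_b)
            if ra == rb:
                continue
            key = (ra, rb) if ra < rb else (rb, ra)
            support[key] = support.get(key, 0) + 1
        merged = False
        for (ra, rb), n in sorted(support.items()):
            if n >= min_edges and find(ra) != find(rb):
                union(ra, rb)
                merged = True
        if not merged:
            return


OG_TABLE_COLUMNS = ["og_id", "level_label", "gene_id", "species_id"]


def write_og_table(
    ogs: Iterable[OrthologousGroup] | OGHierarchy,
    path: str,
    species_of: Mapping[str, str],
) -> None:
    """Write OGs as TSV rows (og_id, level_label, gene_id, species_id).

    Rows are sorted by og_id then gene_id; :func:`read_og_table` inverts
    exactly.  A hierarchy is written with all levels in one file.
    """
    if isinstance(ogs, OGHierarchy):
        ogs = ogs.all_ogs()
    rows = sorted(
        (og.og_id, og.level_label, g, species_of[g])
        for og in ogs
        for g in og.members
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(OG_TABLE_COLUMNS)
        writer.writerows(rows)


def read_og_table(path: str) -> tuple[list[OrthologousGroup], dict[str, str]]:
    """Read an OG table written by :func:`write_og_table`.

    Returns the OGs (sorted by og_id) and the gene -> species map the file
    carries.
    """
    members: dict[tuple[str, str], set[str]] = {}
    species_of: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != OG_TABLE_COLUMNS:
            raise OrthokitError(f"{path}: not an OG table (bad header {header})")
        for row in reader:
            if len(row) != 4:
                raise OrthokitError(f"{path}: malformed OG table row {row}")
            og_id, level_label, gene_id, sp = row
            members.setdefault((og_id, level_label), set()).add(gene_id)
            species_of[gene_id] = sp
    ogs = [
        OrthologousGroup(og_id, level_label, frozenset(m))
        for (og_id, level_label), m in sorted(members.items())
    ]
    return ogs, species_of


def write_unassigned(
    entries: Iterable[tuple[str, str]],
    level_label: str,
    path: str,
    species_of: Mapping[str, str],
) -> None:
    """Sidecar TSV of genes placed in no OG, with reason codes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "species_id", "level_label", "reason"])
        for gene_id, reason in sorted(entries):
            writer.writerow([gene_id, species_of[gene_id], level_label, reason])
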