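"""Simulated gene families with known orthology truth.

Gene content evolves along a rooted species tree with branch lengths by a
per-gene birth-death process — on a branch of length t each gene is lost
with probability 1 - exp(-lambda t) and, if it survives, duplicated (one
extra copy) with probability 1 - exp(-delta t) — while sequences diverge by
per-site substitution with probability 1 - exp(-mu t), uniformly to one of
the 19 other residues.  Loss is drawn before duplication within a branch, so
a copy never duplicates and disappears on the same branch.

The substitution model is deliberately uniform rather than an empirical
exchangeability matrix: recovery tests would be circular if the simulator
shared the scorer's BLOSUM62 assumptions.

The recorded truth is exactly the quantity the delineation pipeline
estimates: at every internal node, each gene copy present at that node
founds one truth OG containing all its extant descendants.  The three rate
knobs (duplication, loss, substitution) span the difficulty axis from
trivially recoverable single-copy families (all rates 0) to tangled
multi-gene families.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .brh import OrthologousGroup, write_og_table
from .core import Gene, OrthokitError, Proteome, SpeciesTree

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Rates are per gene per unit branch length (``dup_rate``/``loss_rate``)
    and per site per unit branch length (``sub_scale``); root sequence
    lengths are Normal(mean, sd) truncated below at ``min_length`` residues.
    """

    seed: int
    tree_newick: str
    n_families: int = 100
    root_length_mean: float = 300.0
    root_length_sd: float = 50.0
    min_length: int = 50
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    sub_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if min(self.dup_rate, self.loss_rate, self.sub_scale) < 0:
            raise ValueError("rates must be >= 0")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class TruthSet:
    """True orthologous groups per level, plus per-gene provenance.

    ``by_level[level][copy_lineage_id]`` is the set of extant gene ids
    descending from that ancestral copy; ``family_of``/``lineage_of`` give
    each extant gene's family and copy-lineage ids.
    """

    by_level: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    family_of: dict[str, str] = field(default_factory=dict)
    lineage_of: dict[str, str] = field(default_factory=dict)

    def ogs_at(
        self, level_label: str, species_of: dict[str, str]
    ) -> list[OrthologousGroup]:
        """Observable truth OGs at a level, numbered like predicted OGs.

        Ancestral copies whose extant descendants span fewer than two
        species are omitted — they are not orthologous groups by definition,
        and the pipeline cannot (and should not) report them.
        """
        groups = [
            genes
            for genes in self.by_level[level_label].values()
            if genes and len({species_of[g] for g in genes}) >= 2
        ]
        groups.sort(key=lambda g: (-len(g), min(g)))
        return [
            OrthologousGroup(f"og{i}at{level_label}", level_label, frozenset(g))
            for i, g in enumerate(groups, start=1)
        ]

    def partition_at(self, level_label: str) -> dict[str, frozenset[str]]:
        """All nonempty truth blocks at a level (including single-gene ones)."""
        return {
            lineage: genes
            for lineage, genes in self.by_level[level_label].items()
            if genes
        }

    def refogs(self, root_label: str) -> dict[str, frozenset[str]]:
        """Root-level truth as a refOG mapping (nonempty copies only)."""
        out: dict[str, frozenset[str]] = {}
        n = 0
        for lineage in sorted(self.by_level[root_label]):
            genes = self.by_level[root_label][lineage]
            if genes:
                n += 1
                out[f"refog{n}"] = genes
        return out


def _mutate(seq: np.ndarray, t: float, mu: float, rng: np.random.Generator) -> np.ndarray:
    if mu <= 0 or t <= 0:
        return seq.copy()
    p = 1.0 - np.exp(-mu * t)
    hit = rng.random(seq.size) < p
    out = seq.copy()
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the 19 other residues: shift past the current one
        cur_idx = np.searchsorted(AMINO_ACIDS, out[hit])
        offset = rng.integers(1, 20, size=n_hit)
        out[hit] = AMINO_ACIDS[(cur_idx + offset) % 20]
    return out


def simulate(
    config: SimConfig,
) -> tuple[list[Proteome], TruthSet, list[str]]:
    """Run the simulator; returns (proteomes, truth, provenance log).

    Fully reproducible from ``config.seed``: the species tree is traversed
    in a fixed order and all draws come from one seeded generator.
    """
    tree = SpeciesTree.from_newick(config.tree_newick)
    if not tree.has_branch_lengths():
        raise OrthokitError("simulator requires branch lengths on every edge")
    rng = np.random.default_rng(config.seed)
    log: list[str] = [f"seed={config.seed}", f"n_families={config.n_families}"]
    truth = TruthSet()
    for label in tree.levels:
        truth.by_level[label] = {}
    genes_per_species: dict[str, list[Gene]] = {sp: [] for sp in tree.species}
    fam_width = len(str(config.n_families))

    for fam_idx in range(1, config.n_families + 1):
        fam = f"f{fam_idx:0{fam_width}d}"
        length = max(
            config.min_length,
            int(round(rng.normal(config.root_length_mean, config.root_length_sd))),
        )
        root_seq = AMINO_ACIDS[rng.integers(0, 20, size=length)]
        root_lineage = f"{fam}.c1"
        descendants = _evolve_copy(
            tree, tree.root_label, root_seq, fam, root_lineage, config, rng,
            genes_per_species, truth,
        )
        log.append(f"{fam}: root_length={length} extant={len(descendants)}")

    proteomes = [
        Proteome(sp, sorted(genes_per_species[sp], key=lambda g: g.gene_id))
        for sp in sorted(genes_per_species)
    ]
    _check_truth(truth, proteomes, tree)
    return proteomes, truth, log


def _evolve_copy(
    tree: SpeciesTree,
    node_label: str,
    seq: np.ndarray,
    fam: str,
    lineage: str,
    config: SimConfig,
    rng: np.random.Generator,
    genes_per_species: dict[str, list[Gene]],
    truth: TruthSet,
) -> frozenset[str]:
    """Evolve one gene copy present at ``node_label``; returns extant descendants."""
    if tree.is_leaf(node_label):
        gene_id = f"{node_label}_{lineage}"
        gene = Gene(gene_id, node_label, seq.tobytes().decode("ascii"))
        genes_per_species[node_label].append(gene)
        truth.family_of[gene_id] = fam
        truth.lineage_of[gene_id] = lineage
        return frozenset([gene_id])

    extant: set[str] = set()
    for child in tree.children(node_label):
        t = tree.branch_length(child)
        # loss first: a copy cannot duplicate and vanish on the same branch
        if config.loss_rate > 0 and rng.random() < 1.0 - np.exp(-config.loss_rate * t):
            continue
        n_copies = 1
        if config.dup_rate > 0 and rng.random() < 1.0 - np.exp(-config.dup_rate * t):
            n_copies = 2
        for copy_idx in range(n_copies):
            child_lineage = lineage if n_copies == 1 else f"{lineage}.{copy_idx}"
            child_seq = _mutate(seq, t, config.sub_scale, rng)
            extant |= _evolve_copy(
                tree, child, child_seq, fam, child_lineage, config, rng,
                genes_per_species, truth,
            )
    frozen = frozenset(extant)
    truth.by_level[node_label][lineage] = frozen
    return frozen


def _check_truth(
    truth: TruthSet, proteomes: list[Proteome], tree: SpeciesTree
) -> None:
    """Assert per-level disjointness and completeness of the recorded truth."""
    species_of = {g.gene_id: g.species_id for p in proteomes for g in p}
    for level in tree.levels:
        level_species = tree.species_under(level)
        seen: set[str] = set()
        for lineage, genes in truth.by_level[level].items():
            overlap = seen & genes
            if overlap:
                raise AssertionError(
                    f"truth OGs overlap at level {level}: {sorted(overlap)[:3]}"
                )
            seen |= genes
        expected = {g for g, sp in species_of.items() if sp in level_species}
        if seen != expected:
            raise AssertionError(f"truth at level {level} does not cover all genes")


def expected_copy_number(config: SimConfig, species_id: str) -> float:
    """Branching-process approximation exp((delta - lambda) * path length)."""
    tree = SpeciesTree.from_newick(config.tree_newick)
    path = 0.0
    label = species_id
    while tree.parent(label) is not None:
        path += tree.branch_length(label) or 0.0
        label = tree.parent(label)
    return float(np.exp((config.dup_rate - config.loss_rate) * path))


def write_fixture(
    proteomes: list[Proteome],
    truth: TruthSet,
    tree: SpeciesTree,
    config: SimConfig,
    directory: str,
) -> dict[str, str]:
    """Write per-species FASTA, per-level truth OG tables, refOG TSV, config.

    Re-running with the same seed reproduces byte-identical files.  Returns
    {artifact name: path}.
    """
    from .io import write_fasta  # local import to avoid a cycle

    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    species_of = {g.gene_id: g.species_id for p in proteomes for g in p}
    for p in proteomes:
        path = os.path.join(directory, f"{p.species_id}.fasta")
        write_fasta(((g.gene_id, g.sequence) for g in p), path)
        paths[f"fasta:{p.species_id}"] = path
    for level in tree.levels:
        ogs = truth.ogs_at(level, species_of)
        path = os.path.join(directory, f"truth_{level}.tsv")
        write_og_table(ogs, path, species_of)
        paths[f"truth:{level}"] = path
    refog_path = os.path.join(directory, "refogs.tsv")
    from .benchmark import RefOGSet

    RefOGSet(truth.refogs(tree.root_label)).to_tsv(refog_path)
    paths["refogs"] = refog_path
    config_path = os.path.join(directory, "sim_config.json")
    config.to_json(config_path)
    paths["config"] = config_path
    return paths


def checksum_files(paths: Iterable[str]) -> dict[str, str]:
    """SHA-256 per file, for determinism checks and run manifests."""
    out: dict[str, str] = {}
    for p in sorted(paths):
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            h.update(fh.read())
        out[p] = h.hexdigest()
    return out
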