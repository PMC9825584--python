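"""MinHash genome sketching and representative selection.

To sample a large pool of assemblies down to one genome per near-identical
group, genomes are sketched with a bottom-s MinHash over canonical k-mers
(the Mash approach), pairwise identity is estimated from the sketch Jaccard
via d = -(1/k) ln(2j / (1 + j)), genomes are clustered at an identity
threshold (default >96%), and each cluster is represented by its most
complete, most annotated member.

The k-mer hash is a seeded splitmix64-style mix of the 2-bit-packed
canonical k-mer; any stable 64-bit hash would do, and the seed travels with
the sketch so sketches are only compared when they are comparable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core import OrthokitError

_MASK64 = (1 << 64) - 1
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT_CODE = {0: 3, 1: 2, 2: 1, 3: 0}


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def hash_kmer(packed: int, seed: int) -> int:
    """64-bit hash of a 2-bit-packed canonical k-mer."""
    return _splitmix64(packed ^ _splitmix64(seed & _MASK64))


@dataclass(frozen=True)
class MinHashSketch:
    """Bottom-s MinHash sketch: the s smallest canonical-k-mer hashes."""

    genome_id: str
    k: int
    s: int
    seed: int
    hashes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.hashes) > self.s:
            raise ValueError("sketch larger than s")
        if any(b <= a for a, b in zip(self.hashes, self.hashes[1:])):
            raise ValueError("sketch hashes must be strictly increasing")


@dataclass(frozen=True)
class GenomeRecord:
    """Assembly metadata used for representative selection.

    ``completeness_pct`` is a BUSCO-style completeness percentage supplied as
    input (not computed here); ``annotation_score`` counts annotation records.
    """

    genome_id: str
    fasta_path: str = ""
    annotation_score: int = 0
    completeness_pct: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness_pct <= 100.0:
            raise ValueError("completeness_pct must be in [0, 100]")
        if self.annotation_score < 0:
            raise ValueError("annotation_score must be >= 0")


def canonical_kmers(sequence: str, k: int) -> Iterable[int]:
    """2-bit-packed canonical k-mers (min of k-mer and reverse complement).

    K-mers containing any non-ACGT character are skipped.
    """
    seq = sequence.upper()
    fwd = 0
    rev = 0
    valid = 0  # run length of valid bases ending here
    shift = 2 * (k - 1)
    mask = (1 << (2 * k)) - 1
    for ch in seq:
        code = _BASE_CODE.get(ch)
        if code is None:
            valid = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | (_COMPLEMENT_CODE[code] << shift)
        valid += 1
        if valid >= k:
            yield min(fwd, rev)


def sketch(
    sequences: Iterable[str],
    genome_id: str,
    k: int = 21,
    s: int = 1000,
    seed: int = 42,
) -> MinHashSketch:
    """Bottom-s sketch of a genome (one or more nucleotide sequences)."""
    seqs = list(sequences)
    total = sum(len(x) for x in seqs)
    if total < k:
        raise OrthokitError(
            f"genome {genome_id!r}: total sequence length {total} < k = {k}"
        )
    hashes: set[int] = set()
    for seq in seqs:
        for packed in canonical_kmers(seq, k):
            hashes.add(hash_kmer(packed, seed))
    bottom = sorted(hashes)[:s]
    return MinHashSketch(genome_id=genome_id, k=k, s=s, seed=seed, hashes=tuple(bottom))


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> tuple[float, float, float]:
    """(jaccard_estimate, mash_distance, identity_pct) between two sketches.

    The Jaccard index is estimated from the s smallest hashes of the merged
    union; the distance is d = -(1/k) ln(2j / (1+j)), capped at 1.0 when
    j = 0; identity_pct = 100 (1 - d).
    """
    if a.k != b.k:
        raise OrthokitError(f"sketch k mismatch: {a.k} != {b.k}")
    if a.seed != b.seed:
        raise OrthokitError("sketches were built with different hash seeds")
    set_a, set_b = set(a.hashes), set(b.hashes)
    s = min(a.s, b.s)
    merged = sorted(set_a | set_b)[:s]
    if not merged:
        raise OrthokitError("empty sketches")
    shared = sum(1 for h in merged if h in set_a and h in set_b)
    j = shared / len(merged)
    if j <= 0.0:
        return 0.0, 1.0, 0.0
    d = -(1.0 / a.k) * math.log(2.0 * j / (1.0 + j))
    d = min(d, 1.0)
    return j, d, 100.0 * (1.0 - d)


@dataclass
class GenomeCluster:
    """A group of near-identical genomes; id = smallest member genome_id."""

    cluster_id: str
    members: list[str]
    representative: str | None = None


def cluster_genomes(
    sketches: Sequence[MinHashSketch],
    identity_threshold_pct: float = 96.0,
    linkage: str = "single",
) -> list[GenomeCluster]:
    """Cluster genomes whose pairwise identity exceeds the threshold.

    Single linkage (default) takes connected components of the
    above-threshold graph; complete linkage only forms clusters in which
    *every* pair is above threshold (greedy, deterministic).
    """
    if not sketches:
        raise OrthokitError("cluster_genomes: no sketches")
    if linkage not in ("single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    ids = [sk.genome_id for sk in sketches]
    if len(set(ids)) != len(ids):
        raise OrthokitError("duplicate genome ids among sketches")
    identity: dict[tuple[str, str], float] = {}
    for a, b in combinations(sorted(sketches, key=lambda s: s.genome_id), 2):
        _, _, ident = mash_distance(a, b)
        identity[(a.genome_id, b.genome_id)] = ident

    def above(x: str, y: str) -> bool:
        key = (x, y) if x < y else (y, x)
        return identity[key] > identity_threshold_pct

    groups: list[list[str]]
    if linkage == "single":
        graph = nx.Graph()
        graph.add_nodes_from(ids)
        graph.add_edges_from(k for k, v in identity.items() if v > identity_threshold_pct)
        groups = [sorted(c) for c in nx.connected_components(graph)]
    else:
        groups = []
        for gid in sorted(ids):
            placed = False
            for grp in groups:
                if all(above(gid, other) for other in grp):
                    grp.append(gid)
                    placed = True
                    break
            if not placed:
                groups.append([gid])
    groups.sort(key=lambda g: g[0])
    return [GenomeCluster(cluster_id=g[0], members=g) for g in groups]


def select_representative(
    cluster: GenomeCluster,
    records: Mapping[str, GenomeRecord],
    priority: str = "completeness",
) -> str:
    """Pick the cluster representative: most complete, then most annotated.

    ``priority="annotation"`` swaps the first two keys.  Final tie-break is
    the lexicographically smallest genome id.
    """
    for gid in cluster.members:
        if gid not in records:
            raise OrthokitError(f"no metadata record for genome {gid!r}")

    def key(gid: str):
        r = records[gid]
        first, second = r.completeness_pct, r.annotation_score
        if priority == "annotation":
            first, second = second, first
        return (-first, -second, gid)

    return min(cluster.members, key=key)


def write_sketch(sk: MinHashSketch, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"genome_id": sk.genome_id, "k": sk.k, "s": sk.s, "seed": sk.seed,
             "hashes": list(sk.hashes)},
            fh,
        )
        fh.write("\n")


def read_sketch(path: str) -> MinHashSketch:
    with open(path) as fh:
        d = json.load(fh)
    return MinHashSketch(
        genome_id=d["genome_id"], k=d["k"], s=d["s"], seed=d["seed"],
        hashes=tuple(d["hashes"]),
    )
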