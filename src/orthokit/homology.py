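"""Cross-species pairwise similarity: the homolog-identification stage.

Candidate orthologs come from pairwise protein similarity.  The built-in
scorer is Smith–Waterman local alignment with affine gaps (BLOSUM62 by
default), preceded by an exact k-mer prefilter so that all-vs-all runs stay
tractable; alternatively, hits computed by an external search tool can be
imported from 12-column BLAST tabular files.

Scores are raw substitution-matrix scores.  They are only ever compared
within one hit table, so the units need only be internally consistent;
imported bit scores are used as-is.  ``X`` residues score 0 against
everything (neutral handling of masked positions).  A gap of length k costs
``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .core import AA_ALPHABET, OrthokitError, Proteome, species_of_map


class InputError(OrthokitError):
    """Bad sequence or file content."""


class FormatError(OrthokitError):
    """A tabular file does not match the expected layout."""


@dataclass(frozen=True)
class AlignParams:
    """Scoring and prefilter parameters for the built-in aligner.

    ``gap_open``/``gap_extend`` are positive penalties; ``kmer_size`` and
    ``min_shared_kmers`` control the exact-k-mer prefilter (a pair is aligned
    only if the sequences share at least ``min_shared_kmers`` distinct
    k-mers); ``min_score`` is the lowest alignment score recorded as a hit.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    kmer_size: int = 4
    min_shared_kmers: int = 2
    min_score: float = 30.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.kmer_size < 2:
            raise ValueError("kmer_size must be >= 2")


@dataclass(frozen=True)
class Hit:
    """A directed similarity hit between two distinct genes."""

    query_gene_id: str
    target_gene_id: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("hit score must be >= 0")
        if self.query_gene_id == self.target_gene_id:
            raise ValueError(f"self-hit for {self.query_gene_id!r}")


class HitTable:
    """Directed pairwise scores keyed by (query, target), one entry per pair.

    Also carries the gene -> species map so downstream stages can group hits
    by species pair without re-reading the proteomes.
    """

    def __init__(self, species_of: Mapping[str, str]):
        self._scores: dict[tuple[str, str], float] = {}
        self.species_of = dict(species_of)

    def add(self, query: str, target: str, score: float) -> None:
        if query == target:
            raise ValueError(f"self-hit for {query!r}")
        if score < 0:
            raise ValueError("hit score must be >= 0")
        key = (query, target)
        prev = self._scores.get(key)
        if prev is None or score > prev:
            self._scores[key] = score

    def get(self, query: str, target: str) -> float | None:
        return self._scores.get((query, target))

    def symmetric_score(self, a: str, b: str) -> float | None:
        """Best available score between two genes in either direction."""
        s1, s2 = self._scores.get((a, b)), self._scores.get((b, a))
        if s1 is None:
            return s2
        return s1 if s2 is None else max(s1, s2)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def items(self) -> Iterator[tuple[str, str, float]]:
        for (q, t), s in self._scores.items():
            yield q, t, s

    def sorted_items(self) -> list[tuple[str, str, float]]:
        return sorted((q, t, s) for (q, t), s in self._scores.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HitTable):
            return NotImplemented
        return self._scores == other._scores


@lru_cache(maxsize=8)
def _matrix(name: str) -> substitution_matrices.Array:
    mat = substitution_matrices.load(name)
    mat = mat.copy()
    if "X" in mat.alphabet:
        for aa in mat.alphabet:
            mat["X", aa] = 0.0
            mat[aa, "X"] = 0.0
    return mat


@lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix(params.matrix)
    # first gap position costs open+extend so a length-k gap costs open + k*extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_sequence(seq: str, which: str) -> None:
    if not seq:
        raise InputError(f"{which} sequence is empty")
    for i, c in enumerate(seq):
        if c not in AA_ALPHABET:
            raise InputError(f"{which} sequence: illegal residue {c!r} at position {i}")


def score_pair(seq_a: str, seq_b: str, params: AlignParams = AlignParams()) -> float:
    """Maximum Smith–Waterman local alignment score of two protein sequences.

    Symmetric and deterministic; floors at 0 (the empty local alignment).
    """
    _check_sequence(seq_a, "first")
    _check_sequence(seq_b, "second")
    return max(0.0, float(_aligner(params).score(seq_a, seq_b)))


def kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def shares_kmers(seq_a: str, seq_b: str, params: AlignParams) -> bool:
    shared = kmer_set(seq_a, params.kmer_size) & kmer_set(seq_b, params.kmer_size)
    return len(shared) >= params.min_shared_kmers


def all_vs_all(
    proteomes: Iterable[Proteome],
    params: AlignParams = AlignParams(),
    cross_species_only: bool = False,
) -> HitTable:
    """Score every gene pair passing the k-mer prefilter; record hits both ways.

    With ``cross_species_only=False`` (default) within-species pairs are also
    scored — the in-paralog attachment rule needs them.  Output is invariant
    to the order in which proteomes are supplied.
    """
    proteomes = sorted(proteomes, key=lambda p: p.species_id)
    if len(proteomes) < 2:
        raise InputError("all_vs_all needs at least 2 proteomes")
    table = HitTable(species_of_map(proteomes))
    genes = sorted(
        (g for p in proteomes for g in p), key=lambda g: g.gene_id
    )
    kmers = {g.gene_id: kmer_set(g.sequence, params.kmer_size) for g in genes}
    seqs = {g.gene_id: g.sequence for g in genes}
    species = {g.gene_id: g.species_id for g in genes}

    # inverted index: k-mer -> gene ids, then count distinct shared k-mers per pair
    index: dict[str, list[str]] = {}
    for g in genes:
        for km in kmers[g.gene_id]:
            index.setdefault(km, []).append(g.gene_id)
    shared_counts: dict[tuple[str, str], int] = {}
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for i, a in enumerate(bucket):
            for b in bucket[i + 1 :]:
                pair = (a, b) if a < b else (b, a)
                shared_counts[pair] = shared_counts.get(pair, 0) + 1

    for (a, b), n_shared in sorted(shared_counts.items()):
        if n_shared < params.min_shared_kmers:
            continue
        if cross_species_only and species[a] == species[b]:
            continue
        s = score_pair(seqs[a], seqs[b], params)
        if s >= params.min_score:
            table.add(a, b, s)
            table.add(b, a, s)
    return table


BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def import_hits(
    path: str,
    proteomes: Iterable[Proteome] | Mapping[str, str],
    strict: bool = True,
) -> HitTable:
    """Load 12-column BLAST tabular hits; bit score (column 12) is the score.

    The best-scoring row is kept per ordered (query, target) pair.  Gene ids
    not present in the supplied proteomes raise :class:`InputError` in strict
    mode and are skipped otherwise.  Self-hit rows are ignored.
    """
    if isinstance(proteomes, Mapping):
        species_of = dict(proteomes)
    else:
        species_of = species_of_map(proteomes)
    table = HitTable(species_of)
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(row)}"
                )
            q, t = row[0], row[1]
            try:
                score = float(row[11])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: bit score {row[11]!r} is not a number"
                ) from None
            for gid in (q, t):
                if gid not in species_of:
                    if strict:
                        raise InputError(
                            f"{path}: line {lineno}: unknown gene id {gid!r}"
                        )
                    break
            else:
                if q != t:
                    table.add(q, t, score)
    return table


def export_hits(table: HitTable, path: str) -> None:
    """Write a hit table as 12-column BLAST tabular (bit score = score).

    Alignment-detail columns are not tracked by :class:`HitTable` and are
    written as zeros; a roundtrip through :func:`import_hits` restores the
    table exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for q, t, s in table.sorted_items():
            writer.writerow([q, t, 0.0, 0, 0, 0, 0, 0, 0, 0, 0.0, f"{s:g}"])
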