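"""Map genes of a novel proteome onto precomputed orthologous groups.

Mapping links a newly sequenced genome to existing OGs (and thereby to their
annotations) without re-running ab-initio delineation, so lower-quality
inputs cannot skew the precomputed orthology.  Each novel gene is scored
against OG member sequences with the same local-alignment scorer used for
delineation; it is assigned to the OG of its best-scoring member (the
*anchor*) only if the score reaches a fraction (default 0.5) of that OG's
reference score — the median pairwise member-member score, which makes the
acceptance rule scale-free with respect to sequence length.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .brh import OrthologousGroup
from .core import OrthokitError, Proteome
from .homology import AlignParams, score_pair, shares_kmers

MAX_REFERENCE_PAIRS = 50


@dataclass(frozen=True)
class MappingResult:
    """Placement of one novel gene (og_id is "unassigned" when rejected)."""

    gene_id: str
    og_id: str
    best_anchor: str | None
    score: float
    acceptance_ratio: float

    @property
    def assigned(self) -> bool:
        return self.og_id != "unassigned"


def og_reference_score(
    og: OrthologousGroup,
    sequences: Mapping[str, str],
    params: AlignParams = AlignParams(),
    subsample_seed: int = 0,
) -> float:
    """Median pairwise member-member alignment score of an OG.

    With more than ``MAX_REFERENCE_PAIRS`` member pairs, a seeded random
    subsample of that many pairs is used, so the value is reproducible.
    """
    members = og.sorted_members()
    if len(members) < 2:
        raise OrthokitError(f"OG {og.og_id}: reference score needs >= 2 members")
    pairs = list(combinations(members, 2))
    if len(pairs) > MAX_REFERENCE_PAIRS:
        rng = np.random.default_rng(subsample_seed)
        idx = rng.choice(len(pairs), size=MAX_REFERENCE_PAIRS, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    scores = [score_pair(sequences[a], sequences[b], params) for a, b in pairs]
    return float(statistics.median(scores))


def map_genes(
    novel: Proteome,
    ogs: Sequence[OrthologousGroup],
    sequences: Mapping[str, str],
    species_of: Mapping[str, str],
    params: AlignParams = AlignParams(),
    accept_ratio: float = 0.5,
    subsample_seed: int = 0,
) -> list[MappingResult]:
    """Place each gene of ``novel`` into at most one precomputed OG.

    The novel species must not be among the OG member species.  A gene is
    scored against every OG member passing the k-mer prefilter; it is
    assigned to its best anchor's OG iff score >= accept_ratio x the OG's
    reference score.  Ties on score go to the lexicographically smallest
    anchor.  Precomputed OGs are never altered.
    """
    if not ogs:
        raise OrthokitError("map_genes: empty OG set")
    og_species = {species_of[g] for og in ogs for g in og.members}
    if novel.species_id in og_species:
        raise OrthokitError(
            f"novel species {novel.species_id!r} is already among the OG members"
        )
    og_of_gene = {g: og for og in ogs for g in og.members}
    ref_scores = {
        og.og_id: og_reference_score(og, sequences, params, subsample_seed)
        for og in ogs
    }
    anchors = sorted(og_of_gene)
    results: list[MappingResult] = []
    for gene in sorted(novel, key=lambda g: g.gene_id):
        best: tuple[float, str] | None = None
        for anchor in anchors:
            if not shares_kmers(gene.sequence, sequences[anchor], params):
                continue
            s = score_pair(gene.sequence, sequences[anchor], params)
            if best is None or s > best[0]:
                best = (s, anchor)
        if best is None:
            results.append(MappingResult(gene.gene_id, "unassigned", None, 0.0, 0.0))
            continue
        score, anchor = best
        og = og_of_gene[anchor]
        ref = ref_scores[og.og_id]
        ratio = score / ref if ref > 0 else float("inf")
        if ratio >= accept_ratio:
            results.append(MappingResult(gene.gene_id, og.og_id, anchor, score, ratio))
        else:
            results.append(
                MappingResult(gene.gene_id, "unassigned", anchor, score, ratio)
            )
    return results


def write_mapping(results: Iterable[MappingResult], path: str) -> None:
    """Mapping TSV: gene_id, og_id|unassigned, anchor, score, ratio."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "og_id", "anchor", "score", "acceptance_ratio"])
        for r in sorted(results, key=lambda r: r.gene_id):
            writer.writerow(
                [r.gene_id, r.og_id, r.best_anchor or "-", f"{r.score:g}",
                 f"{r.acceptance_ratio:.6g}"]
            )
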