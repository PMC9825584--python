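"""Per-OG evolutionary annotations: universality, duplicability, phyloprofiles.

*Universality* is the fraction of the level's species in which an OG has at
least one member; *duplicability* is the fraction of present species that
carry more than one copy.  Together with the single-copy fraction they drive
the classic phyloprofile filters, e.g. "present in >90% of species and
single-copy in >90% of species" for building species-tree marker sets.

The duplicability denominator is the number of species *present* (not all
level species): it measures the propensity to duplicate where the gene
exists.  Thresholds are strict (">"), so a value exactly at the threshold is
excluded.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .brh import OrthologousGroup
from .core import Level, OrthokitError


@dataclass(frozen=True)
class PhyloProfile:
    """Presence/copy-number summary of one OG across its level's species."""

    og_id: str
    n_level_species: int
    n_present: int
    n_single_copy: int
    n_multi_copy: int

    @property
    def universality(self) -> float:
        return self.n_present / self.n_level_species

    @property
    def duplicability(self) -> float:
        return self.n_multi_copy / self.n_present if self.n_present else 0.0

    @property
    def single_copy_fraction(self) -> float:
        return self.n_single_copy / self.n_level_species


def compute_profile(
    og: OrthologousGroup, level: Level, species_of: Mapping[str, str]
) -> PhyloProfile:
    """Count per-species multiplicities of an OG's members at its level."""
    if not og.members:
        raise OrthokitError(f"OG {og.og_id}: no members")
    copies = Counter(species_of[g] for g in og.members)
    outside = set(copies) - level.species_set
    if outside:
        raise OrthokitError(
            f"OG {og.og_id}: member species {sorted(outside)} outside level "
            f"{level.label!r}"
        )
    n_single = sum(1 for c in copies.values() if c == 1)
    n_multi = sum(1 for c in copies.values() if c >= 2)
    return PhyloProfile(
        og_id=og.og_id,
        n_level_species=len(level.species_set),
        n_present=len(copies),
        n_single_copy=n_single,
        n_multi_copy=n_multi,
    )


def filter_ogs(
    profiles: Iterable[PhyloProfile],
    min_presence_pct: float = 0.0,
    min_single_copy_pct: float = 0.0,
) -> list[str]:
    """OG ids passing both strict-">" phyloprofile filters.

    A threshold of 0 disables the corresponding filter.
    """
    for pct in (min_presence_pct, min_single_copy_pct):
        if not 0.0 <= pct <= 100.0:
            raise ValueError("thresholds must be percentages in [0, 100]")
    selected = [
        p.og_id
        for p in profiles
        if (min_presence_pct == 0 or p.universality * 100.0 > min_presence_pct)
        and (min_single_copy_pct == 0 or p.single_copy_fraction * 100.0 > min_single_copy_pct)
    ]
    return sorted(selected)


def export_single_copy_fasta(
    selected: Sequence[OrthologousGroup],
    sequences: Mapping[str, str],
    species_of: Mapping[str, str],
    directory: str,
) -> dict[str, list[str]]:
    """Write one FASTA per selected OG for marker-gene use.

    Headers are ``gene_id species_id og_id``.  If a species slipped through a
    relaxed filter with several copies, only its longest member is exported
    and a warning is recorded.  Returns {og_id: warnings}.
    """
    import os

    if not selected:
        raise OrthokitError("export_single_copy_fasta: empty selection")
    os.makedirs(directory, exist_ok=True)
    warnings: dict[str, list[str]] = {}
    for og in selected:
        warnings[og.og_id] = []
        by_species: dict[str, list[str]] = {}
        for g in og.sorted_members():
            by_species.setdefault(species_of[g], []).append(g)
        records: list[tuple[str, str]] = []
        for sp in sorted(by_species):
            genes = by_species[sp]
            if len(genes) > 1:
                # longest member wins; ties to smallest id
                pick = sorted(genes, key=lambda g: (-len(sequences[g]), g))[0]
                warnings[og.og_id].append(
                    f"species {sp}: {len(genes)} copies, exported longest ({pick})"
                )
                genes = [pick]
            records.extend((g, sp) for g in genes)
        path = os.path.join(directory, f"{og.og_id}.fasta")
        with open(path, "w") as fh:
            for g, sp in records:
                fh.write(f">{g} {sp} {og.og_id}\n{sequences[g]}\n")
    return warnings


PROFILE_COLUMNS = [
    "og_id", "n_level_species", "n_present", "n_single_copy", "n_multi_copy",
    "universality", "duplicability", "single_copy_fraction",
]


def write_profiles(profiles: Iterable[PhyloProfile], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROFILE_COLUMNS)
        for p in sorted(profiles, key=lambda p: p.og_id):
            writer.writerow(
                [p.og_id, p.n_level_species, p.n_present, p.n_single_copy,
                 p.n_multi_copy, f"{p.universality:.6g}", f"{p.duplicability:.6g}",
                 f"{p.single_copy_fraction:.6g}"]
            )
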