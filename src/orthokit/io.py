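"""Shared file formats: FASTA, species lists, metadata tables, run manifests.

All intermediate artifacts are plain FASTA/TSV/JSON so every pipeline stage
can be inspected and re-run independently.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from datetime import datetime, timezone
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .core import Gene, OrthokitError, Proteome


def read_fasta(path: str) -> list[tuple[str, str]]:
    """(id, sequence) records; the id is the first whitespace-delimited token.

    Duplicate ids and empty files are errors; CRLF input is accepted.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise OrthokitError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise OrthokitError(f"{path}: empty or not FASTA")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_proteome(path: str, species_id: str) -> Proteome:
    genes = [Gene(rid, species_id, seq) for rid, seq in read_fasta(path)]
    return Proteome(species_id, genes)


def read_species_list(path: str) -> list[tuple[str, str]]:
    """Species list TSV: (species_id, fasta_path) rows; paths relative to the file."""
    base = os.path.dirname(os.path.abspath(path))
    out: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise OrthokitError(f"{path}: line {lineno}: need species_id and path")
            sp, fasta = row[0], row[1]
            if not os.path.isabs(fasta):
                fasta = os.path.join(base, fasta)
            out.append((sp, fasta))
    return out


def load_proteomes(species_list_path: str) -> list[Proteome]:
    return [
        read_proteome(fasta, sp) for sp, fasta in read_species_list(species_list_path)
    ]


def read_genome_metadata(path: str) -> dict[str, dict[str, float]]:
    """Metadata TSV: genome_id, annotation_score, completeness_pct."""
    out: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and not _is_number(row[1] if len(row) > 1 else ""):
                continue  # header
            if len(row) < 3:
                raise OrthokitError(f"{path}: line {lineno}: need 3 columns")
            out[row[0]] = {
                "annotation_score": float(row[1]),
                "completeness_pct": float(row[2]),
            }
    return out


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_manifest(
    out_dir: str,
    config: Mapping[str, object],
    input_paths: Iterable[str],
    seed: int | None = None,
) -> str:
    """Run manifest: version, config, input checksums, seed, timestamp."""
    checksums = {}
    for p in sorted(set(input_paths)):
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            h.update(fh.read())
        checksums[os.path.basename(p)] = h.hexdigest()
    manifest = {
        "orthokit_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": dict(config),
        "input_sha256": checksums,
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
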