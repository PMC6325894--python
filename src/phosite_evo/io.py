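"""Readers and writers for the package's file formats.

Proteomes are FASTA with description lines of the form
``>protein_id gene=<gene_id> species=<label>``. Site tables, ortholog maps
and variant tables are UTF-8, LF-terminated TSV with ``.`` marking absent
fields. Alignments are aligned FASTA with row ids ``<species>|<protein_id>``.
All coordinates are 1-based.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .integrate import ProteinRecord, PTMSiteRecord, SiteCatalog

SITE_COLUMNS = ["species", "protein_id", "position", "residue", "ptm_type",
                "source", "source_score", "peptide", "peptide_offset"]
MISSING = "."


def read_proteome_fasta(path) -> list:
    """Read one species' proteome FASTA into ProteinRecords."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = species = None
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene_id = token[5:]
            elif token.startswith("species="):
                species = token[8:]
        if species is None:
            raise ValueError(f"{path}: record {rec.id} lacks species= tag")
        records.append(ProteinRecord(protein_id=rec.id, species=species,
                                     sequence=str(rec.seq).upper(),
                                     gene_id=gene_id))
    return records


def write_proteome_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqs = []
    for r in records:
        desc = (f"gene={r.gene_id} " if r.gene_id else "") + f"species={r.species}"
        seqs.append(SeqRecord(Seq(r.sequence), id=r.protein_id, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


def _opt_float(value: str) -> Optional[float]:
    return None if value == MISSING else float(value)


def _opt_str(value: str) -> Optional[str]:
    return None if value == MISSING else value


def read_site_table(path) -> SiteCatalog:
    """Read a PTM site TSV into a SiteCatalog."""
    catalog = SiteCatalog()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SITE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                offset = row["peptide_offset"]
                catalog.add(PTMSiteRecord(
                    species=row["species"],
                    protein_id=row["protein_id"],
                    position=int(row["position"]),
                    residue=row["residue"],
                    ptm_type=row["ptm_type"],
                    source=row["source"],
                    source_score=_opt_float(row["source_score"]),
                    peptide=_opt_str(row["peptide"]),
                    peptide_offset=None if offset == MISSING else int(offset),
                    ambiguous=row.get("ambiguous", "false") == "true",
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from exc
    return catalog


def write_site_table(catalog: SiteCatalog, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_COLUMNS + ["ambiguous"])
        recs = sorted(catalog.records,
                      key=lambda r: (r.species, r.protein_id, r.position,
                                     r.ptm_type, r.source))
        for r in recs:
            writer.writerow([
                r.species, r.protein_id, r.position, r.residue, r.ptm_type,
                r.source,
                MISSING if r.source_score is None else repr(r.source_score),
                r.peptide or MISSING,
                MISSING if r.peptide_offset is None else r.peptide_offset,
                "true" if r.ambiguous else "false",
            ])


def read_ortholog_map(path, min_score: int = 3) -> dict:
    """Read a group_id/species/protein_id/ortholog_score TSV.

    Rows with ortholog_score below ``min_score`` are dropped, mirroring the
    DIOPT "score of 3 or higher" input filter. Returns
    ``{group_id: [(species, protein_id, score), ...]}``.
    """
    groups: dict = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            try:
                score = int(row["ortholog_score"])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from exc
            if score < min_score:
                continue
            groups.setdefault(row["group_id"], []).append(
                (row["species"], row["protein_id"], score))
    return groups


def write_ortholog_map(groups: dict, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group_id", "species", "protein_id", "ortholog_score"])
        for gid in sorted(groups):
            for species, pid, score in groups[gid]:
                writer.writerow([gid, species, pid, score])


def read_alignment_fasta(path) -> dict:
    """Read an aligned FASTA; returns {(species, protein_id): gapped_row}."""
    rows = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"{path}: row id {rec.id!r} is not species|protein_id")
        species, pid = rec.id.split("|", 1)
        rows[(species, pid)] = str(rec.seq).upper()
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    return rows


def write_alignment_fasta(rows: dict, path) -> None:
    seqs = [SeqRecord(Seq(row), id=f"{species}|{pid}", description="")
            for (species, pid), row in rows.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_variant_table(path) -> list:
    """Read a protein_id/position/disease_label TSV into VariantRecords."""
    from .disease_proximity import VariantRecord

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(VariantRecord(protein_id=row["protein_id"],
                                         position=int(row["position"]),
                                         label=row["disease_label"]))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from exc
    return out


def write_variant_table(variants: Iterable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "position", "disease_label"])
        for v in variants:
            writer.writerow([v.protein_id, v.position, v.label])
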