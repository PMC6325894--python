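"""Multi-source PTM catalog integration.

Consolidates redundant proteomes, remaps peptide-anchored sites onto the
non-redundant protein collection, merges site catalogs from multiple
sources, and tabulates cross-source overlap. Positions are 1-based.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .constants import ACCEPTORS


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence from one species' proteome release."""

    protein_id: str
    species: str
    sequence: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.protein_id}")
        if "-" in self.sequence:
            raise ValueError(f"gap character in sequence of {self.protein_id}")


@dataclass
class NonRedundantProteome:
    """Distinct sequences plus a map from every original id to its representative.

    The representative of a set of identical sequences is the
    lexicographically smallest protein id, which makes consolidation
    deterministic.
    """

    species: str
    sequences: dict  # representative protein_id -> sequence
    id_map: dict  # original protein_id -> representative protein_id
    gene_map: dict = field(default_factory=dict)  # representative -> gene_id

    def sequence_of(self, protein_id: str) -> str:
        return self.sequences[self.id_map.get(protein_id, protein_id)]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class PTMSiteRecord:
    """One observed or predicted modification at a 1-based residue position."""

    species: str
    protein_id: str
    position: int
    residue: str
    ptm_type: str
    source: str
    source_score: Optional[float] = None
    peptide: Optional[str] = None
    peptide_offset: Optional[int] = None
    ambiguous: bool = False

    @property
    def key(self) -> tuple:
        return (self.species, self.protein_id, self.position, self.ptm_type)

    def validate(self, sequence: str) -> None:
        if not 1 <= self.position <= len(sequence):
            raise ValueError(
                f"position {self.position} outside {self.protein_id} "
                f"(length {len(sequence)})"
            )
        if sequence[self.position - 1] != self.residue:
            raise ValueError(
                f"residue mismatch at {self.protein_id}:{self.position}: "
                f"record says {self.residue}, sequence has "
                f"{sequence[self.position - 1]}"
            )
        if self.peptide is not None and self.peptide_offset is not None:
            if not 1 <= self.peptide_offset <= len(self.peptide):
                raise ValueError("peptide_offset outside peptide")
            if self.peptide[self.peptide_offset - 1] != self.residue:
                raise ValueError("peptide residue disagrees with site residue")


class SiteCatalog:
    """A set of PTM site records keyed by (species, protein, position, ptm_type).

    A key may carry several sources; duplicate (key, source) pairs collapse
    to one record (first wins).
    """

    def __init__(self, records: Iterable[PTMSiteRecord] = ()):  # noqa: D107
        self._by_key: dict = defaultdict(dict)  # key -> {source: record}
        for rec in records:
            self.add(rec)

    def add(self, rec: PTMSiteRecord) -> None:
        existing = self._by_key[rec.key]
        for other in existing.values():
            if other.residue != rec.residue:
                raise ValueError(
                    f"residue disagreement at key {rec.key}: "
                    f"{other.residue} vs {rec.residue}"
                )
        existing.setdefault(rec.source, rec)

    @property
    def records(self) -> list:
        return [r for srcs in self._by_key.values() for r in srcs.values()]

    @property
    def keys(self) -> set:
        return set(self._by_key)

    @property
    def sources(self) -> list:
        return sorted({r.source for r in self.records})

    def sources_of(self, key: tuple) -> set:
        return set(self._by_key.get(key, {}))

    def records_at(self, key: tuple) -> list:
        return list(self._by_key.get(key, {}).values())

    def observed(self, species: str, protein_id: str, position: int,
                 ptm_type: str = "phospho") -> bool:
        return (species, protein_id, position, ptm_type) in self._by_key

    def subset(self, species: Optional[str] = None,
               source: Optional[str] = None,
               ptm_type: Optional[str] = None,
               include_ambiguous: bool = True) -> "SiteCatalog":
        recs = self.records
        if species is not None:
            recs = [r for r in recs if r.species == species]
        if source is not None:
            recs = [r for r in recs if r.source == source]
        if ptm_type is not None:
            recs = [r for r in recs if r.ptm_type == ptm_type]
        if not include_ambiguous:
            recs = [r for r in recs if not r.ambiguous]
        return SiteCatalog(recs)

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self.records)


def consolidate_proteome(records: Sequence[ProteinRecord]) -> NonRedundantProteome:
    """Collapse identical sequences into one representative per sequence.

    The representative is the lexicographically smallest protein id among
    ids sharing the sequence. Conflicting duplicate ids (same id, different
    sequences) raise a ``ValueError`` naming the id.
    """
    if not records:
        return NonRedundantProteome(species="", sequences={}, id_map={})
    species = {r.species for r in records}
    if len(species) > 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    seen: dict = {}
    for rec in records:
        if rec.protein_id in seen and seen[rec.protein_id].sequence != rec.sequence:
            raise ValueError(
                f"conflicting sequences for duplicate id {rec.protein_id}"
            )
        seen.setdefault(rec.protein_id, rec)
    by_seq: dict = defaultdict(list)
    for rec in seen.values():
        by_seq[rec.sequence].append(rec)
    sequences, id_map, gene_map = {}, {}, {}
    for seq, recs in by_seq.items():
        rep = min(r.protein_id for r in recs)
        sequences[rep] = seq
        for r in recs:
            id_map[r.protein_id] = rep
            if r.gene_id is not None and r.protein_id == rep:
                gene_map[rep] = r.gene_id
    return NonRedundantProteome(species=species.pop(), sequences=sequences,
                                id_map=id_map, gene_map=gene_map)


def remap_peptide_site(peptide: str, peptide_offset: int,
                       proteome: NonRedundantProteome) -> list:
    """Locate a peptide-anchored site on the non-redundant proteome.

    Returns every ``(protein_id, position, ambiguous)`` such that the
    peptide occurs as an exact substring; ``position`` is the 1-based
    protein coordinate of the modified residue. ``ambiguous`` is True when
    the peptide maps to more than one location (all are returned). An
    unmapped peptide yields an empty list.
    """
    if not peptide:
        raise ValueError("empty peptide")
    if not 1 <= peptide_offset <= len(peptide):
        raise ValueError("peptide_offset outside peptide")
    hits = []
    for pid in sorted(proteome.sequences):
        seq = proteome.sequences[pid]
        start = seq.find(peptide)
        while start != -1:
            hits.append((pid, start + peptide_offset))  # 1-based
            start = seq.find(peptide, start + 1)
    ambiguous = len(hits) > 1
    return [(pid, pos, ambiguous) for pid, pos in hits]


def remap_catalog(catalog: SiteCatalog,
                  proteome: NonRedundantProteome) -> tuple:
    """Remap every peptide-bearing record onto the proteome.

    Records without a peptide are kept if their (id-mapped) coordinates
    validate against the proteome, else dropped. Returns
    ``(remapped_catalog, n_unmapped)``.
    """
    out, unmapped = [], 0
    for rec in catalog:
        if rec.peptide is None or rec.peptide_offset is None:
            pid = proteome.id_map.get(rec.protein_id)
            if pid is None:
                unmapped += 1
                continue
            seq = proteome.sequences[pid]
            if (1 <= rec.position <= len(seq)
                    and seq[rec.position - 1] == rec.residue):
                out.append(replace(rec, protein_id=pid))
            else:
                unmapped += 1
            continue
        hits = remap_peptide_site(rec.peptide, rec.peptide_offset, proteome)
        if not hits:
            unmapped += 1
            continue
        for pid, pos, ambiguous in hits:
            out.append(replace(rec, protein_id=pid, position=pos,
                               ambiguous=ambiguous))
    return SiteCatalog(out), unmapped


def merge_catalogs(catalogs: Sequence[SiteCatalog]) -> SiteCatalog:
    """Union several catalogs; shared keys accumulate sources.

    Order-independent: any permutation of the inputs yields an identical
    catalog. A residue disagreement at a shared key raises an error naming
    the key.
    """
    merged = SiteCatalog()
    for cat in catalogs:
        for rec in cat:
            merged.add(rec)
    return merged


def overlap_table(catalog: SiteCatalog, ptm_type: str = "phospho") -> pd.DataFrame:
    """Cross-source site overlap counts.

    One row per source with the number of that source's site keys supported
    by at least one / at least two *other* sources, plus an ``All`` row
    counting distinct keys supported by >= 2 and >= 3 sources overall.
    Fractions accompany each count.
    """
    keys = [k for k in catalog.keys if k[3] == ptm_type]
    if not keys:
        raise ValueError("catalog has no sites of the requested ptm_type")
    n_sources_at = {k: len(catalog.sources_of(k)) for k in keys}
    rows = []
    for src in catalog.sources:
        src_keys = [k for k in keys if src in catalog.sources_of(k)]
        n = len(src_keys)
        ge1 = sum(1 for k in src_keys if n_sources_at[k] >= 2)
        ge2 = sum(1 for k in src_keys if n_sources_at[k] >= 3)
        rows.append({
            "source": src, "n_sites": n,
            "n_overlap_ge1_other": ge1,
            "frac_overlap_ge1_other": ge1 / n if n else 0.0,
            "n_overlap_ge2_other": ge2,
            "frac_overlap_ge2_other": ge2 / n if n else 0.0,
        })
    n_all = len(keys)
    ge2_all = sum(1 for k in keys if n_sources_at[k] >= 2)
    ge3_all = sum(1 for k in keys if n_sources_at[k] >= 3)
    rows.append({
        "source": "All", "n_sites": n_all,
        "n_overlap_ge1_other": ge2_all,
        "frac_overlap_ge1_other": ge2_all / n_all,
        "n_overlap_ge2_other": ge3_all,
        "frac_overlap_ge2_other": ge3_all / n_all,
    })
    return pd.DataFrame(rows)


def acceptor_positions(sequence: str, classes: frozenset = ACCEPTORS) -> list:
    """1-based positions of phospho-acceptor residues in a sequence."""
    return [i + 1 for i, aa in enumerate(sequence) if aa in classes]
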