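"""Mapping PTM sites onto ortholog multiple sequence alignments.

An :class:`OrthologGroup` holds one representative protein per species plus
their gapped multiple alignment. Sites from a catalog are projected onto
alignment columns; columns carrying an observed phosphosite in at least one
species become :class:`AlignedSite` objects, and the cross-species status of
the acceptor residue at such a column is classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from .constants import ACCEPTORS, GAP
from .integrate import SiteCatalog

ACCEPTOR_CLASSIFICATIONS = (
    "identical_acceptor_observed_both",
    "identical_acceptor",
    "acceptor_class_changed",
    "acceptor_lost",
    "gap",
)


@dataclass
class OrthologGroup:
    """One ortholog family: members, gapped alignment, column/position maps."""

    group_id: str
    members: list  # [(species, protein_id), ...] one per species
    alignment: dict  # (species, protein_id) -> gapped row

    _pos2col: dict = field(init=False, repr=False)
    _col2pos: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError(f"group {self.group_id}: unequal row lengths")
        species_seen = [sp for sp, _ in self.members]
        if len(species_seen) != len(set(species_seen)):
            raise ValueError(f"group {self.group_id}: species appears twice")
        self._pos2col, self._col2pos = {}, {}
        for member, row in self.alignment.items():
            p2c, c2p = {}, {}
            pos = 0
            for col, aa in enumerate(row, start=1):
                if aa != GAP:
                    pos += 1
                    p2c[pos] = col
                    c2p[col] = pos
            self._pos2col[member] = p2c
            self._col2pos[member] = c2p

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.alignment.values())))

    def species_of(self) -> list:
        return [sp for sp, _ in self.members]

    def member_of(self, species: str) -> tuple:
        for m in self.members:
            if m[0] == species:
                return m
        raise KeyError(f"group {self.group_id}: no member for {species}")

    def ungapped(self, member) -> str:
        return self.alignment[member].replace(GAP, "")

    def position_to_column(self, member, position: int) -> int:
        """Alignment column (1-based) of an ungapped 1-based position."""
        p2c = self._pos2col[member]
        if position not in p2c:
            raise ValueError(
                f"position {position} outside ungapped length of {member}")
        return p2c[position]

    def column_to_position(self, member, column: int) -> Optional[int]:
        """Ungapped position at a column, or None if the member has a gap."""
        if not 1 <= column <= self.n_columns:
            raise ValueError(f"column {column} outside alignment")
        return self._col2pos[member].get(column)

    def residue_at(self, member, column: int) -> str:
        return self.alignment[member][column - 1]


@dataclass
class AlignedSite:
    """One alignment column carrying an observed phosphosite somewhere."""

    group_id: str
    column: int
    ptm_type: str
    residues: dict  # species -> residue (or '-')
    positions: dict  # species -> ungapped position or None
    observed: dict  # species -> bool
    propensity: dict = field(default_factory=dict)  # species -> score or absent

    @property
    def observed_species(self) -> list:
        return sorted(sp for sp, obs in self.observed.items() if obs)


def select_representative(records, gene_id: str):
    """Pick one representative isoform per gene: longest, ties by smallest id."""
    candidates = [r for r in records if r.gene_id == gene_id]
    if not candidates:
        raise ValueError(f"no isoform for gene {gene_id}")
    return max(candidates, key=lambda r: (len(r.sequence),
                                          [-ord(c) for c in r.protein_id]))


def build_group(group_id: str, alignment_rows: dict) -> OrthologGroup:
    """Assemble an OrthologGroup from aligned FASTA rows keyed by (species, id)."""
    members = sorted(alignment_rows)
    return OrthologGroup(group_id=group_id, members=members,
                         alignment=dict(alignment_rows))


def index_catalog(catalog: SiteCatalog) -> dict:
    """Index records by (species, protein_id) for fast per-group lookup."""
    index: dict = {}
    for rec in catalog:
        index.setdefault((rec.species, rec.protein_id), []).append(rec)
    return index


def select_aligned_acceptor_sites(group: OrthologGroup, catalog,
                                  ptm_type: str = "phospho",
                                  include_ambiguous: bool = False) -> list:
    """Columns where >= 1 member carries an observed site of ``ptm_type``.

    ``catalog`` is a SiteCatalog or a prebuilt :func:`index_catalog` dict,
    already remapped to the group's proteome. Ambiguous (multi-mapping)
    records are excluded by default.
    """
    if isinstance(catalog, SiteCatalog):
        catalog = index_catalog(catalog)
    observed_cols: dict = {}
    for species, pid in group.members:
        for rec in catalog.get((species, pid), ()):
            if rec.ptm_type != ptm_type:
                continue
            if rec.ambiguous and not include_ambiguous:
                continue
            ungapped = group.ungapped((species, pid))
            if not 1 <= rec.position <= len(ungapped):
                continue
            col = group.position_to_column((species, pid), rec.position)
            observed_cols.setdefault(col, set()).add(species)
    sites = []
    for col in sorted(observed_cols):
        residues, positions, observed = {}, {}, {}
        for member in group.members:
            species = member[0]
            residues[species] = group.residue_at(member, col)
            positions[species] = group.column_to_position(member, col)
            observed[species] = species in observed_cols[col]
        sites.append(AlignedSite(group_id=group.group_id, column=col,
                                 ptm_type=ptm_type, residues=residues,
                                 positions=positions, observed=observed))
    return sites


def classify_aligned_site(site: AlignedSite, reference_species: str,
                          target_species: str,
                          acceptor_class: str = "strict") -> str:
    """Cross-species status of the acceptor residue at an aligned site.

    With the default ``strict`` policy only S<->T substitutions count as an
    acceptor-class change; a Y at the reference replaced by S/T (or vice
    versa) is scored as ``acceptor_lost`` because tyrosine kinases are
    mechanistically distinct. ``acceptor_class="broad"`` treats any
    {S,T,Y} -> {S,T,Y} substitution as ``acceptor_class_changed``.
    """
    if acceptor_class not in ("strict", "broad"):
        raise ValueError(f"unknown acceptor_class policy {acceptor_class!r}")
    ref = site.residues[reference_species]
    if ref not in ACCEPTORS:
        raise ValueError(
            f"reference residue {ref!r} at column {site.column} is not an acceptor")
    tgt = site.residues[target_species]
    if tgt == GAP:
        return "gap"
    if tgt == ref:
        if site.observed.get(reference_species) and site.observed.get(target_species):
            return "identical_acceptor_observed_both"
        return "identical_acceptor"
    if tgt not in ACCEPTORS:
        return "acceptor_lost"
    if acceptor_class == "broad":
        return "acceptor_class_changed"
    # strict: S<->T only; crossing the ST/Y divide loses the acceptor
    if ref in ("S", "T") and tgt in ("S", "T"):
        return "acceptor_class_changed"
    return "acceptor_lost"
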