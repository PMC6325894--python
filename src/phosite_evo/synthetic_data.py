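"""Synthetic multi-species ortholog families with planted phosphosite truth.

The generator emulates the statistical structure the downstream analyses
assume: six species on a fixed ladder phylogeny, ancestral proteins with
planted functional (evolutionarily protected) and neutral phosphosites,
kinase-motif sequence signal around true sites, incomplete per-species MS
detection, and disease variants enriched near conserved sites. Every stage
records enough ground truth for exact recovery oracles.

Evolution is gap-free by default (the truth alignment is the identity map,
so column maps are trivial and oracles exact). Substitutions are drawn per
site per branch; a substitution always changes the residue (the new letter
is drawn from the background excluding the current one), so the realized
per-branch substitution fraction matches the configured probability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .alignment_sites import OrthologGroup
from .constants import ACCEPTORS, AMINO_ACIDS, DEFAULT_FLANK, acceptor_class
from .conservation import extract_window, window_identity
from .integrate import ProteinRecord, PTMSiteRecord, SiteCatalog
from .propensity import KinaseMotifPSSM, default_bank

SPECIES = ("mel", "sim", "yak", "ana", "pse", "vir")

#: ladder topology: (child, branch_key) pairs per internal node
TREE_TOPOLOGY = {
    "root": [("n1", "b_n1"), ("vir", "b_vir")],
    "n1": [("n2", "b_n2"), ("pse", "b_pse")],
    "n2": [("n3", "b_n3"), ("ana", "b_ana")],
    "n3": [("n4", "b_n4"), ("yak", "b_yak")],
    "n4": [("mel", "b_mel"), ("sim", "b_sim")],
}

# The root sits proximal to the reference (mel) lineage: detection,
# propensity training and window scoring all read the reference sequences,
# so the planted motif signal must survive there; divergence is carried by
# the non-reference branches. Pairwise reference-vs-ortholog divergence
# still increases down the ladder.
DEFAULT_BRANCH_PROBS = {
    "b_mel": 0.02, "b_sim": 0.33, "b_n4": 0.02,
    "b_yak": 0.48, "b_n3": 0.03,
    "b_ana": 0.60, "b_n2": 0.03,
    "b_pse": 0.73, "b_n1": 0.03,
    "b_vir": 0.87,
}

# rounded Swiss-Prot-like amino-acid background
DEFAULT_BACKGROUND = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.040, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.054, "V": 0.069, "W": 0.011, "Y": 0.029,
}

DEFAULT_SOURCE_SENSITIVITIES = {
    "mel": {"this_study": 0.55, "lit_embryo": 0.50,
            "cell_line": 0.45, "curated": 0.20},
    "sim": {"embryo_ms": 0.50},
    "yak": {"embryo_ms": 0.45},
    "ana": {"embryo_ms": 0.40},
    "pse": {"embryo_ms": 0.35},
    "vir": {"embryo_ms": 0.30},
}


@dataclass
class SimulationConfig:
    """All generator parameters; fully serializes the run (seed included)."""

    seed: int
    n_groups: int = 60
    species: tuple = SPECIES
    reference_species: str = "mel"
    length_range: tuple = (200, 800)
    branch_probs: dict = field(default_factory=lambda: dict(DEFAULT_BRANCH_PROBS))
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    functional_sites_per_protein: float = 3.0
    neutral_site_fraction: float = 0.15
    functional_conservation_boost: float = 0.15
    motif_strength: float = 2.5
    flank: int = DEFAULT_FLANK
    source_sensitivities: dict = field(
        default_factory=lambda: {sp: dict(d) for sp, d
                                 in DEFAULT_SOURCE_SENSITIVITIES.items()})
    variant_rate: float = 0.01
    variant_enrichment: float = 2.0
    variant_distance: int = 10
    retention: dict = field(default_factory=lambda: {sp: 1.0 for sp in SPECIES})
    phospho_retention_boost: float = 1.0
    false_positive_rate: float = 0.0
    #: robustness mode: per-site deletion-event probability on the terminal
    #: branch of each non-reference species (geometric lengths); the truth
    #: alignment records the gaps. 0 keeps evolution substitution-only.
    indel_rate: float = 0.0
    indel_mean_length: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        probs = list(self.branch_probs.values()) + list(self.retention.values())
        probs += [self.neutral_site_fraction, self.functional_conservation_boost,
                  self.variant_rate, self.false_positive_rate, self.indel_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-6:
            self.background = {aa: p / total for aa, p in self.background.items()}

    def combined_sensitivity(self, species: str) -> float:
        miss = 1.0
        for s in self.source_sensitivities[species].values():
            miss *= 1.0 - s
        return 1.0 - miss

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        for key in ("species", "length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class GroupTruth:
    """Ground truth for one ortholog family (gap-free coordinates)."""

    group_id: str
    length: int
    functional_sites: list  # positions (1-based, shared across species)
    neutral_sites: list
    site_class: dict  # position -> "ST" | "Y" (ancestral class)
    true_phospho: dict  # species -> set of positions
    conserved_functional: list = field(default_factory=list)
    identity: dict = field(default_factory=dict)  # (pos, species) -> window id


@dataclass
class SimulationTruth:
    config: SimulationConfig
    groups: dict = field(default_factory=dict)  # group_id -> GroupTruth
    detection: dict = field(default_factory=dict)  # species -> source -> set
    variants: list = field(default_factory=list)
    variant_stats: dict = field(default_factory=dict)

    def all_sites(self) -> list:
        """Every true site as (group_id, position)."""
        out = []
        for gid, gt in self.groups.items():
            out.extend((gid, p) for p in gt.functional_sites)
            out.extend((gid, p) for p in gt.neutral_sites)
        return out


def _sample_background(rng, background: dict, size: int) -> np.ndarray:
    letters = np.array(list(AMINO_ACIDS))
    probs = np.array([background[aa] for aa in AMINO_ACIDS])
    return rng.choice(len(letters), size=size, p=probs)


def _substitute(rng, seq_idx: np.ndarray, probs: np.ndarray,
                background_probs: np.ndarray) -> np.ndarray:
    """Per-site substitution; the new residue is never the current one."""
    hit = rng.random(seq_idx.size) < probs
    n = int(hit.sum())
    if n == 0:
        return seq_idx.copy()
    out = seq_idx.copy()
    current = seq_idx[hit]
    P = np.tile(background_probs, (n, 1))
    P[np.arange(n), current] = 0.0
    P /= P.sum(axis=1, keepdims=True)
    cdf = np.cumsum(P, axis=1)
    u = rng.random(n)
    out[hit] = (u[:, None] > cdf).sum(axis=1)
    return out


def _tilted_window(rng, background: dict, pssm: KinaseMotifPSSM,
                   strength: float, flank: int) -> np.ndarray:
    """Sample flank residues from background tilted by the motif log-odds."""
    bg = np.array([background[aa] for aa in AMINO_ACIDS])
    out = np.empty(2 * flank + 1, dtype=int)
    for off in range(-flank, flank + 1):
        if off == 0:
            continue
        logits = np.log(bg) + strength * pssm.weights[off + flank]
        p = np.exp(logits - logits.max())
        p /= p.sum()
        out[off + flank] = rng.choice(len(AMINO_ACIDS), p=p)
    return out


def simulate_families(config: SimulationConfig):
    """Generate proteomes, gap-free truth alignments, ortholog map and truth.

    Returns ``(proteomes, groups, ortholog_map, truth)`` where ``proteomes``
    maps species to lists of ProteinRecord, ``groups`` maps group_id to
    OrthologGroup, and ``ortholog_map`` maps group_id to
    ``[(species, protein_id, score), ...]``.
    """
    rng = np.random.default_rng([config.seed, 1])
    bank = default_bank()
    bank_by_class = {"ST": [p for p in bank if p.acceptor_class == "ST"],
                     "Y": [p for p in bank if p.acceptor_class == "Y"]}
    bg_probs = np.array([config.background[aa] for aa in AMINO_ACIDS])
    flank = config.flank
    letters = np.array(list(AMINO_ACIDS))
    acceptor_idx = {AMINO_ACIDS.index(a) for a in "STY"}

    proteomes: dict = {sp: [] for sp in config.species}
    groups: dict = {}
    ortholog_map: dict = {}
    truth = SimulationTruth(config=config)

    for g in range(config.n_groups):
        gid = f"G{g + 1:04d}"
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        ancestor = _sample_background(rng, config.background, L)

        # choose functional sites among interior acceptor positions
        interior = [i for i in range(flank, L - flank)
                    if int(ancestor[i]) in acceptor_idx]
        n_func = min(len(interior), rng.poisson(config.functional_sites_per_protein))
        func_pos0 = sorted(rng.choice(len(interior), size=n_func,
                                      replace=False)) if n_func else []
        functional = [interior[i] for i in func_pos0]

        site_class: dict = {}
        func_set = set(functional)

        def plant(center: int, cls: str, protect: set) -> None:
            pssm = bank_by_class[cls][int(rng.integers(len(bank_by_class[cls])))]
            tilted = _tilted_window(rng, config.background, pssm,
                                    config.motif_strength, flank)
            for off in range(-flank, flank + 1):
                j = center + off
                if off != 0 and 0 <= j < L and j not in protect:
                    ancestor[j] = tilted[off + flank]

        for i in functional:
            cls = acceptor_class(AMINO_ACIDS[ancestor[i]])
            site_class[i + 1] = cls
            plant(i, cls, func_set)

        # neutral true sites among the remaining acceptors (post-tilt residues)
        neutral = []
        for i in range(L):
            if int(ancestor[i]) in acceptor_idx and i not in func_set:
                if rng.random() < config.neutral_site_fraction:
                    neutral.append(i)
                    site_class[i + 1] = acceptor_class(AMINO_ACIDS[ancestor[i]])
        protected_centers = func_set | set(neutral)
        for i in neutral:
            plant(i, site_class[i + 1], protected_centers)

        # evolutionary protection of functional windows
        factor = np.ones(L)
        for i in functional:
            lo, hi = max(0, i - flank), min(L, i + flank + 1)
            factor[lo:hi] = config.functional_conservation_boost

        # evolve down the fixed tree
        leaves: dict = {}

        def descend(node: str, seq_idx: np.ndarray) -> None:
            for child, branch_key in TREE_TOPOLOGY.get(node, ()):  # noqa: B023
                p = config.branch_probs[branch_key] * factor
                child_seq = _substitute(rng, seq_idx, p, bg_probs)
                if child in TREE_TOPOLOGY:
                    descend(child, child_seq)
                else:
                    leaves[child] = child_seq

        descend("root", ancestor)

        # optional robustness mode: deletions on non-reference terminal
        # branches; functional protection also suppresses deletion starts
        ref = config.reference_species
        deleted = {sp: None for sp in config.species}
        if config.indel_rate > 0.0:
            p_geo = 1.0 / max(config.indel_mean_length, 1.0)
            for sp in config.species:
                if sp == ref:
                    continue
                mask = np.zeros(L, dtype=bool)
                starts = np.flatnonzero(
                    rng.random(L) < config.indel_rate * factor)
                for s in starts:
                    length = int(rng.geometric(p_geo))
                    mask[s:s + length] = True
                deleted[sp] = mask

        gt = GroupTruth(group_id=gid, length=L,
                        functional_sites=[i + 1 for i in functional],
                        neutral_sites=[i + 1 for i in neutral],
                        site_class=site_class,
                        true_phospho={sp: set() for sp in config.species})
        all_sites = gt.functional_sites + gt.neutral_sites
        for sp in config.species:
            seq = leaves[sp]
            for pos in all_sites:
                if deleted[sp] is not None and deleted[sp][pos - 1]:
                    continue
                aa = AMINO_ACIDS[seq[pos - 1]]
                if aa in ACCEPTORS and acceptor_class(aa) == gt.site_class[pos]:
                    gt.true_phospho[sp].add(pos)

        # per-site realized identity (reference vs each ortholog) and the
        # realized conserved flag for functional sites; positions are in
        # alignment/reference coordinates (the reference is never deleted)
        rows, ungapped, local_pos = {}, {}, {}
        for sp in config.species:
            chars = letters[leaves[sp]]
            if deleted[sp] is None:
                rows[sp] = "".join(chars)
                ungapped[sp] = rows[sp]
                local_pos[sp] = None  # identity mapping
            else:
                keep = ~deleted[sp]
                rows[sp] = "".join("-" if d else c
                                   for c, d in zip(chars, deleted[sp]))
                ungapped[sp] = "".join(chars[keep])
                local_pos[sp] = np.cumsum(keep)
        for pos in all_sites:
            ref_w = extract_window(ungapped[ref], pos, flank)
            vals = []
            for sp in config.species:
                if sp == ref:
                    continue
                if deleted[sp] is not None and deleted[sp][pos - 1]:
                    ident = 0.0  # gap at the acceptor column
                else:
                    p_sp = (pos if local_pos[sp] is None
                            else int(local_pos[sp][pos - 1]))
                    ident = window_identity(
                        ref_w, extract_window(ungapped[sp], p_sp, flank))
                gt.identity[(pos, sp)] = ident
                vals.append(ident)
            if pos in gt.functional_sites and vals \
                    and sum(vals) / len(vals) > 0.5:
                gt.conserved_functional.append(pos)

        # ortholog retention (reference always present)
        is_phospho_protein = bool(gt.true_phospho[ref])
        members = []
        for sp in config.species:
            if sp != ref:
                p = config.retention.get(sp, 1.0)
                if is_phospho_protein and config.phospho_retention_boost != 1.0:
                    odds = (p / (1.0 - p) if p < 1.0 else np.inf)
                    odds *= config.phospho_retention_boost
                    p = 1.0 if np.isinf(odds) else odds / (1.0 + odds)
                if rng.random() >= p:
                    continue
            pid = f"{sp}_{gid}"
            members.append((sp, pid))
            proteomes[sp].append(ProteinRecord(protein_id=pid, species=sp,
                                               sequence=ungapped[sp],
                                               gene_id=gid))
        alignment = {(sp, pid): rows[sp] for sp, pid in members}
        groups[gid] = OrthologGroup(group_id=gid, members=members,
                                    alignment=alignment)
        ortholog_map[gid] = [(sp, pid, 15) for sp, pid in members]
        truth.groups[gid] = gt

    return proteomes, groups, ortholog_map, truth


def simulate_detection(truth: SimulationTruth, config: SimulationConfig,
                       groups: dict) -> SiteCatalog:
    """Detection-limited site catalogs across species and sources.

    Every true site is detected independently with its source's
    sensitivity; detected records carry a true 7-25-mer peptide subsequence
    covering the site so remapping is exercised end to end. With the
    default ``false_positive_rate = 0`` detection implies true status.
    """
    rng = np.random.default_rng([config.seed, 2])
    catalog = SiteCatalog()
    truth.detection = {sp: {src: set() for src in config.source_sensitivities[sp]}
                       for sp in config.species}
    for gid in sorted(truth.groups):
        gt = truth.groups[gid]
        group = groups[gid]
        present = {sp: pid for sp, pid in group.members}
        for sp in config.species:
            if sp not in present:
                continue
            member = (sp, present[sp])
            seq = group.ungapped(member)
            # truth positions are alignment columns; records carry the
            # species-local coordinate (identical in gap-free mode)
            candidates = [(col, group.column_to_position(member, col))
                          for col in sorted(gt.true_phospho[sp])]
            for src, s in sorted(config.source_sensitivities[sp].items()):
                for col, pos in candidates:
                    if pos is None or rng.random() >= s:
                        continue
                    rec = _make_record(rng, sp, present[sp], pos, seq, src)
                    catalog.add(rec)
                    truth.detection[sp][src].add((gid, col))
                if config.false_positive_rate > 0.0:
                    true_local = {p for _, p in candidates}
                    accs = [i + 1 for i, aa in enumerate(seq)
                            if aa in ACCEPTORS and i + 1 not in true_local]
                    for pos in accs:
                        if rng.random() < config.false_positive_rate * s:
                            catalog.add(_make_record(rng, sp, present[sp],
                                                     pos, seq, src))
    return catalog


def _make_record(rng, species: str, pid: str, pos: int, seq: str,
                 source: str) -> PTMSiteRecord:
    pep_len = int(rng.integers(7, 26))
    lo = max(0, pos - pep_len)
    hi = min(len(seq) - pep_len, pos - 1)
    start = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
    pep_len = min(pep_len, len(seq) - start)
    peptide = seq[start:start + pep_len]
    return PTMSiteRecord(species=species, protein_id=pid, position=pos,
                         residue=seq[pos - 1], ptm_type="phospho",
                         source=source,
                         source_score=float(np.round(rng.random(), 4)),
                         peptide=peptide, peptide_offset=pos - start)


def simulate_variants(truth: SimulationTruth, config: SimulationConfig
                      ) -> list:
    """Place disease variants on the reference species' proteins.

    Per-residue placement probability is ``variant_rate``, multiplied by
    ``variant_enrichment`` within ``variant_distance`` residues of a
    conserved functional site. Realized near/far rates are recorded in
    ``truth.variant_stats``.
    """
    from .disease_proximity import VariantRecord

    if config.variant_enrichment < 1.0:
        raise ValueError("variant enrichment factor must be >= 1")
    rng = np.random.default_rng([config.seed, 3])
    ref = config.reference_species
    variants = []
    n_near = n_far = hits_near = hits_far = 0
    for gid in sorted(truth.groups):
        gt = truth.groups[gid]
        pid = f"{ref}_{gid}"
        near = np.zeros(gt.length, dtype=bool)
        for pos in gt.conserved_functional:
            lo = max(0, pos - 1 - config.variant_distance)
            hi = min(gt.length, pos + config.variant_distance)
            near[lo:hi] = True
        p = np.where(near, min(1.0, config.variant_rate * config.variant_enrichment),
                     config.variant_rate)
        hit = rng.random(gt.length) < p
        n_near += int(near.sum())
        n_far += int((~near).sum())
        hits_near += int(hit[near].sum())
        hits_far += int(hit[~near].sum())
        for i in np.flatnonzero(hit):
            variants.append(VariantRecord(protein_id=pid, position=int(i) + 1,
                                          label="synthetic_disease"))
    truth.variants = [(v.protein_id, v.position) for v in variants]
    truth.variant_stats = {
        "rate_near": hits_near / n_near if n_near else float("nan"),
        "rate_far": hits_far / n_far if n_far else float("nan"),
        "n_near": n_near, "n_far": n_far,
    }
    return variants
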