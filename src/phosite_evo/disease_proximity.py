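"""Proximity of conserved phosphosites to disease-associated variants.

A site is *proximal* when a variant lies on the same protein within 10
residues (inclusive; a variant at the site itself is distance 0). Fractions
proximal are stratified by window-identity cutoff and by acceptor status,
and enrichment of the high-identity stratum over the low-identity baseline
is tested with the two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

from .evostats import TwoByTwoTable, fisher_exact_two_sided

DEFAULT_DISTANCE = 10


@dataclass(frozen=True)
class VariantRecord:
    """A disease-associated substitution at a 1-based protein position."""

    protein_id: str
    position: int
    label: str = "disease"


@dataclass
class ProximityResult:
    """Proximal-site summary for one identity cutoff (and stratum)."""

    identity_cutoff: float
    stratum: str  # "all", "acceptor_conserved" or "acceptor_lost"
    n_sites: int
    n_proximal: int
    fraction: float
    table: Optional[TwoByTwoTable] = None  # stratum vs below-cutoff baseline
    odds_ratio: Optional[float] = None
    p_value: Optional[float] = None


def proximal_sites(site_positions: Sequence[tuple],
                   variants: Sequence[VariantRecord],
                   distance: int = DEFAULT_DISTANCE) -> list:
    """Per-site flags: is any variant within ``distance`` on the same protein?

    ``site_positions`` is a sequence of (protein_id, position). Sites on
    proteins with no annotated variant get False — they stay in
    denominators, since absence of nearby variants is informative.
    """
    by_protein: Dict[str, list] = {}
    for v in variants:
        by_protein.setdefault(v.protein_id, []).append(v.position)
    for positions in by_protein.values():
        positions.sort()
    flags = []
    for pid, pos in site_positions:
        positions = by_protein.get(pid, ())
        # sorted list is short per protein; linear scan with early exit
        hit = any(abs(vp - pos) <= distance for vp in positions)
        flags.append(hit)
    return flags


def enrichment_test(high_flags: Sequence[bool],
                    baseline_flags: Sequence[bool]) -> tuple:
    """Fisher test of proximal fraction: high-identity stratum vs baseline.

    The two strata are disjoint by construction (>= cutoff vs < cutoff).
    Returns (table, odds_ratio, p_value).
    """
    a = sum(high_flags)
    b = len(high_flags) - a
    c = sum(baseline_flags)
    d = len(baseline_flags) - c
    table = TwoByTwoTable(a, b, c, d)
    odds, p = fisher_exact_two_sided(table)
    return table, odds, p


def proximity_by_identity(sites: Sequence[dict],
                          variants: Sequence[VariantRecord],
                          cutoffs: Sequence[float] = (0.2, 0.5, 0.8, 1.0),
                          distance: int = DEFAULT_DISTANCE,
                          drop_variantless_proteins: bool = False) -> list:
    """Proximal fractions per identity cutoff, split by acceptor status.

    Each site dict needs ``protein_id``, ``position``, ``identity`` (its
    similarity score against the variant-bearing species) and
    ``acceptor_conserved`` (bool). For every cutoff, fractions are reported
    for all sites at identity >= cutoff and separately for the
    acceptor-conserved and acceptor-lost strata; empty strata are skipped.
    Each result at cutoff > min(cutoffs) carries an enrichment test against
    the below-cutoff baseline of the same stratum.
    """
    if drop_variantless_proteins:
        with_variants = {v.protein_id for v in variants}
        sites = [s for s in sites if s["protein_id"] in with_variants]
    flags = proximal_sites([(s["protein_id"], s["position"]) for s in sites],
                           variants, distance)
    results = []
    for cutoff in cutoffs:
        for stratum in ("all", "acceptor_conserved", "acceptor_lost"):
            def in_stratum(s):
                if stratum == "all":
                    return True
                want = stratum == "acceptor_conserved"
                return s["acceptor_conserved"] == want

            high = [f for s, f in zip(sites, flags)
                    if in_stratum(s) and s["identity"] >= cutoff - 1e-12]
            if not high:
                continue
            low = [f for s, f in zip(sites, flags)
                   if in_stratum(s) and s["identity"] < cutoff - 1e-12]
            res = ProximityResult(identity_cutoff=cutoff, stratum=stratum,
                                  n_sites=len(high), n_proximal=sum(high),
                                  fraction=sum(high) / len(high))
            if low:
                res.table, res.odds_ratio, res.p_value = enrichment_test(high, low)
            results.append(res)
    return results
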