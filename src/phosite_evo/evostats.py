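"""Conservation enrichment statistics.

Protein-level ("do phosphoproteins retain orthologs more often?") and
site-level ("are phosphorylated residues more conserved than other
acceptors on the same proteins?") comparisons, each summarized by a 2x2
table and a two-sided Fisher exact test.

The Fisher p-value follows the probability-mass rule: the sum of
hypergeometric probabilities of every table (with the observed margins)
whose probability does not exceed that of the observed table. It is
computed in exact integer arithmetic — numerators C(r1, a)·C(r2, c) share
the denominator C(n, a+c), so tables are compared as integers and the
division to a float happens once at the end. This avoids the tie-breaking
ambiguity of floating-point pmf comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts with rows = group and columns = outcome."""

    a: int  # group 1, outcome +
    b: int  # group 1, outcome -
    c: int  # group 2, outcome +
    d: int  # group 2, outcome -

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


def fisher_exact_two_sided(table: TwoByTwoTable) -> tuple:
    """Two-sided Fisher exact test, probability-mass rule, exact arithmetic.

    Returns ``(odds_ratio, p_value)`` with odds_ratio = ad/bc (+inf when
    bc = 0 and ad > 0). A zero margin makes every table with those margins
    identical, so p = 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.n
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return table.odds_ratio, 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = [math.comb(r1, k) * math.comb(r2, c1 - k)
                  for k in range(lo, hi + 1)]
    observed = numerators[a - lo]
    p_num = sum(v for v in numerators if v <= observed)
    return table.odds_ratio, p_num / math.comb(n, c1)


@dataclass
class ConservationComparison:
    """A phospho-vs-control conservation contrast for one target species."""

    target_species: str
    table: TwoByTwoTable
    phospho_proportion: float
    control_proportion: float
    odds_ratio: float
    p_value: float


def _compare(outcome_phospho: Sequence[bool], outcome_control: Sequence[bool],
             target_species: str) -> ConservationComparison:
    a = sum(outcome_phospho)
    b = len(outcome_phospho) - a
    c = sum(outcome_control)
    d = len(outcome_control) - c
    table = TwoByTwoTable(a, b, c, d)
    odds, p = fisher_exact_two_sided(table)
    return ConservationComparison(
        target_species=target_species, table=table,
        phospho_proportion=a / len(outcome_phospho),
        control_proportion=c / len(outcome_control),
        odds_ratio=odds, p_value=p)


def ortholog_conservation_comparison(phospho_proteins: set,
                                     control_proteins: set,
                                     ortholog_map: Dict[str, set],
                                     target_species: str
                                     ) -> ConservationComparison:
    """Fraction of proteins with an ortholog in the target species, by group.

    ``ortholog_map`` maps reference protein_id -> set of species with a
    retained ortholog at or above the map's score threshold. The phospho
    and control sets must be disjoint (control = proteins with no detected
    site of the tested PTM type).
    """
    if not phospho_proteins or not control_proteins:
        raise ValueError("empty protein group")
    overlap = phospho_proteins & control_proteins
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:3]}...")
    out_p = [target_species in ortholog_map.get(p, set())
             for p in sorted(phospho_proteins)]
    out_c = [target_species in ortholog_map.get(p, set())
             for p in sorted(control_proteins)]
    return _compare(out_p, out_c, target_species)


def default_site_identity_rule(acceptor_conserved: bool,
                               window_identity_value: Optional[float]) -> bool:
    """A site counts as conserved in the target when the aligned residue is
    still an acceptor and the window identity is >= 0.5."""
    return (acceptor_conserved and window_identity_value is not None
            and window_identity_value >= 0.5)


def site_conservation_comparison(phospho_outcomes: Sequence[bool],
                                 control_outcomes: Sequence[bool],
                                 target_species: str) -> ConservationComparison:
    """Site-level contrast from precomputed per-site conserved flags.

    Callers evaluate the identity rule (default
    :func:`default_site_identity_rule`) per site against the target species;
    control acceptors are drawn from the same proteins as the phosphosites.
    """
    if not phospho_outcomes or not control_outcomes:
        raise ValueError("empty site set")
    return _compare(list(phospho_outcomes), list(control_outcomes),
                    target_species)


def adjust_p_values(comparisons: Sequence["ConservationComparison"],
                    method: str = "fdr_bh") -> list:
    """Optional multiple-testing correction across target species.

    Off by default everywhere — per-species raw p-values are reported —
    but available for users testing many species. Returns adjusted
    p-values in input order.
    """
    from statsmodels.stats.multitest import multipletests

    if not comparisons:
        return []
    _, adjusted, _, _ = multipletests([c.p_value for c in comparisons],
                                      method=method)
    return list(adjusted)


def match_control_acceptors(phospho_residues: Sequence[str],
                            candidates: Sequence, residue_of, rng) -> list:
    """Sample a control set matching the S/T/Y composition of the phospho set.

    Draws, for each residue class, as many controls as the phospho set has
    sites of that class (capped by pool size), without replacement. Avoids
    residue-composition confounding; callers wanting unmatched controls
    simply use ``candidates`` directly.
    """
    from collections import Counter

    want = Counter(phospho_residues)
    by_res: dict = {}
    for cand in candidates:
        by_res.setdefault(residue_of(cand), []).append(cand)
    out = []
    for res, count in sorted(want.items()):
        pool = by_res.get(res, [])
        take = min(count, len(pool))
        if take:
            idx = rng.choice(len(pool), size=take, replace=False)
            out.extend(pool[i] for i in idx)
    return out
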