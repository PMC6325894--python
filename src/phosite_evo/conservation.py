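"""Window-based phosphosite conservation scoring.

Each site is represented by the 11-mer window of the phosphosite plus five
residues up- and downstream. The identity of two windows is the number of
identical positions divided by the nominal window length (11), so a single
mismatch scores 10/11 = 0.909..., displayed as 0.9 at one decimal. A site's
average similarity is the mean of the reference-vs-ortholog window
identities; sites with average similarity strictly above 0.5 are called
conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

from .alignment_sites import AlignedSite, OrthologGroup, classify_aligned_site
from .constants import DEFAULT_FLANK, GAP, UNKNOWN

CONSERVED_THRESHOLD = 0.5
DEFAULT_IDENTITY_CUTOFFS = (0.2, 0.5, 0.8, 1.0)


@dataclass(frozen=True)
class SiteWindow:
    """Residues around a site, clipped at protein termini."""

    center_position: int
    residues: str
    flank: int = DEFAULT_FLANK
    left_truncated: bool = False
    right_truncated: bool = False

    @property
    def nominal_length(self) -> int:
        return 2 * self.flank + 1

    @property
    def center_residue(self) -> str:
        # left clip removes (flank - (center_position - 1)) leading residues
        return self.residues[min(self.flank, self.center_position - 1)]


@dataclass
class SiteConservationResult:
    """Per-site cross-species similarity summary."""

    site: AlignedSite
    reference_species: str
    per_ortholog: dict  # species -> window identity in [0, 1]
    acceptor_class: dict  # species -> classification label
    average_similarity: Optional[float]

    @property
    def conserved(self) -> Optional[bool]:
        if self.average_similarity is None:
            return None
        return self.average_similarity > CONSERVED_THRESHOLD


def extract_window(sequence: str, position: int,
                   flank: int = DEFAULT_FLANK) -> SiteWindow:
    """The site residue plus ``flank`` residues each side, clipped at termini."""
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence "
                         f"(length {len(sequence)})")
    lo = max(0, position - 1 - flank)
    hi = min(len(sequence), position + flank)
    return SiteWindow(center_position=position,
                      residues=sequence[lo:hi], flank=flank,
                      left_truncated=position - 1 - flank < 0,
                      right_truncated=position + flank > len(sequence))


def _padded(window: SiteWindow) -> str:
    """Window as a fixed-length string, '-' padding truncated positions."""
    left_pad = window.flank - (window.center_position - 1) \
        if window.left_truncated else 0
    s = GAP * left_pad + window.residues
    return s + GAP * (window.nominal_length - len(s))


def window_identity(w1: SiteWindow, w2: SiteWindow) -> float:
    """Identical positions divided by the nominal window length.

    Comparison is anchored at the center. Positions missing from either
    window (terminus truncation) count as mismatches, as does the unknown
    residue X, which never matches anything.
    """
    if w1.flank != w2.flank:
        raise ValueError("windows have different flanks")
    a, b = _padded(w1), _padded(w2)
    n_ident = sum(1 for x, y in zip(a, b)
                  if x == y and x != GAP and x != UNKNOWN)
    return n_ident / w1.nominal_length


def average_similarity(reference_window: SiteWindow,
                       ortholog_windows: Dict[str, Optional[SiteWindow]]
                       ) -> Optional[float]:
    """Mean reference-vs-ortholog window identity.

    An ortholog with a gap at the acceptor column is passed as ``None`` and
    contributes similarity 0 (absence is the strongest non-conservation
    signal). Zero orthologs -> None; the site is then excluded from
    conserved summaries.
    """
    if not ortholog_windows:
        return None
    values = [0.0 if w is None else window_identity(reference_window, w)
              for w in ortholog_windows.values()]
    return sum(values) / len(values)


def all_pairs_average_similarity(windows: Dict[str, Optional[SiteWindow]]
                                 ) -> Optional[float]:
    """Mean identity over all unordered species pairs (alternative rule)."""
    keys = sorted(windows)
    if len(keys) < 2:
        return None
    vals = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            wa, wb = windows[a], windows[b]
            vals.append(0.0 if wa is None or wb is None
                        else window_identity(wa, wb))
    return sum(vals) / len(vals)


def score_site_conservation(group: OrthologGroup, site: AlignedSite,
                            reference_species: str, sequences: dict,
                            flank: int = DEFAULT_FLANK,
                            pairing: str = "reference",
                            acceptor_policy: str = "strict"
                            ) -> SiteConservationResult:
    """Window-compare one aligned site between the reference and each ortholog.

    ``sequences`` maps species -> ungapped sequence for this group.
    ``pairing="reference"`` (default) averages reference-vs-ortholog
    identities; ``pairing="all_pairs"`` averages all species pairs.
    """
    ref_pos = site.positions.get(reference_species)
    if ref_pos is None:
        raise ValueError(
            f"reference species has a gap at column {site.column}")
    ref_window = extract_window(sequences[reference_species], ref_pos, flank)
    per_ortholog, windows, classes = {}, {reference_species: ref_window}, {}
    for species, pos in site.positions.items():
        if species == reference_species:
            continue
        w = None if pos is None else extract_window(sequences[species], pos, flank)
        windows[species] = w
        per_ortholog[species] = (0.0 if w is None
                                 else window_identity(ref_window, w))
        classes[species] = classify_aligned_site(
            site, reference_species, species, acceptor_class=acceptor_policy)
    if pairing == "all_pairs":
        avg = all_pairs_average_similarity(windows)
    elif pairing == "reference":
        avg = (sum(per_ortholog.values()) / len(per_ortholog)
               if per_ortholog else None)
    else:
        raise ValueError(f"unknown pairing rule {pairing!r}")
    return SiteConservationResult(site=site,
                                  reference_species=reference_species,
                                  per_ortholog=per_ortholog,
                                  acceptor_class=classes,
                                  average_similarity=avg)


def bin_sites_by_identity(results: Sequence[SiteConservationResult],
                          cutoffs: Sequence[float] = DEFAULT_IDENTITY_CUTOFFS
                          ) -> dict:
    """Nested identity bins: a site joins every bin whose cutoff <= its score.

    Returns {cutoff: [results]}; counts are monotonically non-increasing
    with the cutoff. Sites without an average similarity are skipped.
    """
    if not results:
        raise ValueError("no conservation results to bin")
    bins: dict = {c: [] for c in cutoffs}
    for res in results:
        if res.average_similarity is None:
            continue
        for c in cutoffs:
            # tolerate float representation at the exact-cutoff boundary
            if res.average_similarity >= c - 1e-12:
                bins[c].append(res)
    return bins


def round_for_display(similarity: float, ndigits: int = 1) -> float:
    """One-decimal display rounding (10/11 prints as 0.9); comparisons stay unrounded."""
    return round(similarity, ndigits)
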