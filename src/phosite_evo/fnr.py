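"""False-negative-rate estimation from perfectly conserved benchmark sites.

A benchmark site is an aligned phosphosite whose 11-mer windows are 100%
identical across all species (no gaps) and which was observed in at least
two species. Such a site is almost certainly genuinely phosphorylated in
every species, so the fraction of benchmark sites a species' data misses
estimates that species' false-negative rate.

Because qualifying requires >= 2 observations, a species' own detections
contribute to the filter and the naive ratio slightly underestimates the
marginal miss probability; recovery tests compare against the conditional
expectation computed by enumeration, not against 1 - sensitivity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Sequence

from statsmodels.stats.proportion import proportion_confint

from .alignment_sites import AlignedSite, OrthologGroup
from .conservation import extract_window, window_identity
from .constants import DEFAULT_FLANK


@dataclass
class BenchmarkSite:
    """An aligned site with fully identical windows in all species."""

    site: AlignedSite
    observed: dict  # species -> bool


@dataclass
class FNREstimate:
    species: str
    n_benchmark: int
    n_missed: int
    fnr: float
    ci_low: float
    ci_high: float


def select_benchmark_sites(groups: Dict[str, OrthologGroup],
                           aligned_sites: Sequence[AlignedSite],
                           sequences: Dict[str, dict],
                           min_observed: int = 2,
                           flank: int = DEFAULT_FLANK) -> list:
    """Sites 100% identical (11-mer, no gaps) in all species, observed >= 2x.

    ``sequences[group_id][species]`` gives the ungapped sequence. All
    pairwise window identities must equal 1.0, which with the nominal-length
    denominator also excludes terminus-truncated windows.
    """
    out = []
    for site in aligned_sites:
        if sum(site.observed.values()) < min_observed:
            continue
        if any(pos is None for pos in site.positions.values()):
            continue  # a gap anywhere disqualifies the site
        seqs = sequences[site.group_id]
        windows = [extract_window(seqs[sp], pos, flank)
                   for sp, pos in sorted(site.positions.items())]
        identical = all(window_identity(a, b) == 1.0
                        for a, b in itertools.combinations(windows, 2))
        if identical:
            out.append(BenchmarkSite(site=site, observed=dict(site.observed)))
    return out


def estimate_fnr(benchmark_sites: Sequence[BenchmarkSite],
                 species: str, alpha: float = 0.05) -> FNREstimate:
    """Fraction of benchmark sites not covered by the species' data.

    Returns the exact ratio with a Wilson score confidence interval.
    """
    if not benchmark_sites:
        raise ValueError("empty benchmark set")
    n = len(benchmark_sites)
    missed = sum(1 for b in benchmark_sites if not b.observed.get(species, False))
    lo, hi = proportion_confint(missed, n, alpha=alpha, method="wilson")
    return FNREstimate(species=species, n_benchmark=n, n_missed=missed,
                       fnr=missed / n, ci_low=float(lo), ci_high=float(hi))


def conditional_fnr_oracle(sensitivities: Dict[str, float],
                           species: str, min_observed: int = 2) -> float:
    """Expected benchmark miss rate under independent per-species detection.

    Enumerates all detection patterns over the species set, conditions on
    at least ``min_observed`` detections, and returns
    P(species missed | pattern qualifies). This is the selection-bias-aware
    truth the estimator should recover.
    """
    names = sorted(sensitivities)
    p_qualify = 0.0
    p_missed_and_qualify = 0.0
    for pattern in itertools.product([0, 1], repeat=len(names)):
        if sum(pattern) < min_observed:
            continue
        p = 1.0
        for name, det in zip(names, pattern):
            s = sensitivities[name]
            p *= s if det else (1.0 - s)
        p_qualify += p
        if pattern[names.index(species)] == 0:
            p_missed_and_qualify += p
    if p_qualify == 0.0:
        raise ValueError("qualifying probability is zero")
    return p_missed_and_qualify / p_qualify
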