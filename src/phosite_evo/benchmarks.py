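"""Recovery benchmarks: end-to-end checks of the pipeline against
generator ground truth and independent oracles.

Each function simulates its own data at a documented problem size, runs
the relevant pipeline stages, and returns plain dictionaries of measured
quantities. The test suite asserts on these; the acceptance script reports
them. All randomness derives from the caller's seed.
"""

from __future__ import annotations

import dataclasses
import math
from fractions import Fraction
from typing import Dict, List, Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import roc_auc_score

from .alignment_sites import index_catalog, select_aligned_acceptor_sites
from .conservation import SiteWindow, extract_window, window_identity
from .disease_proximity import enrichment_test, proximal_sites
from .evostats import TwoByTwoTable, fisher_exact_two_sided
from .fnr import conditional_fnr_oracle, estimate_fnr, select_benchmark_sites
from .integrate import remap_peptide_site
from .pipeline import run_synthetic_pipeline
from .propensity import (assemble_training_sets, default_bank, feature_matrix,
                         train_propensity_model)
from .synthetic_data import (SimulationConfig, simulate_detection,
                             simulate_families, simulate_variants)


# ---------------------------------------------------------------- similarity

def worked_similarity_example() -> dict:
    """Two 11-mers differing at exactly one position: 10/11, shown as 0.9."""
    w1 = extract_window("ARNDCQEGHIL", 6)
    w2 = extract_window("ARNDCQEGHIV", 6)  # last residue differs
    value = window_identity(w1, w2)
    return {"raw": value, "displayed": round(value, 1)}


# -------------------------------------------------------------------- fisher

def hypergeometric_enumeration_p(a: int, b: int, c: int, d: int) -> Fraction:
    """Independent Fisher oracle: enumerate all tables with the observed
    margins, computing each probability as an exact Fraction of factorials,
    and sum those no more probable than the observed table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    c2 = n - c1
    if 0 in (r1, r2) or c1 in (0, n):
        return Fraction(1)

    def prob(a_):
        b_, c_ = r1 - a_, c1 - a_
        d_ = r2 - c_
        return Fraction(
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(c2),
            math.factorial(n) * math.factorial(a_) * math.factorial(b_)
            * math.factorial(c_) * math.factorial(d_))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {a_: prob(a_) for a_ in range(lo, hi + 1)}
    obs = probs[a]
    return sum((p for p in probs.values() if p <= obs), Fraction(0))


def fisher_enumeration_sweep(max_n: int = 48) -> dict:
    """Compare fisher_exact_two_sided with the enumeration oracle on every
    2x2 table with total count <= max_n. Oracle p-values are computed once
    per margin set via sorted exact prefix sums."""
    max_dp = 0.0
    n_tables = 0
    for n in range(1, max_n + 1):
        for r1 in range(n + 1):
            r2 = n - r1
            for c1 in range(n + 1):
                lo, hi = max(0, c1 - r2), min(r1, c1)
                if hi < lo:
                    continue
                # exact per-margin probabilities, sorted prefix sums
                fr = [Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                               math.comb(n, c1)) for k in range(lo, hi + 1)]
                order = sorted(range(len(fr)), key=lambda i: fr[i])
                prefix = []
                acc = Fraction(0)
                for i in order:
                    acc += fr[i]
                    prefix.append(acc)
                rank = {}
                for r_, i in enumerate(order):
                    rank[i] = r_
                # equal probabilities must share the highest prefix value
                for i in range(len(fr)):
                    r_ = rank[i]
                    while r_ + 1 < len(fr) and fr[order[r_ + 1]] == fr[i]:
                        r_ += 1
                    a = lo + i
                    table = TwoByTwoTable(a, r1 - a, c1 - a, r2 - (c1 - a))
                    _, p = fisher_exact_two_sided(table)
                    max_dp = max(max_dp, abs(p - float(prefix[r_])))
                    n_tables += 1
    return {"n_tables": n_tables, "max_abs_dp": max_dp}


# ----------------------------------------------------------------------- fnr

FNR_SENSITIVITIES = {"mel": 0.9, "sim": 0.6, "yak": 0.3,
                     "ana": 0.9, "pse": 0.6, "vir": 0.3}


def fnr_recovery(seed: int, n_seeds: int = 10, n_groups: int = 150) -> dict:
    """Estimate per-species FNR on perfectly conserved benchmark sites and
    compare with the enumeration-based conditional oracle.

    The scenario plants ~4 functional sites per protein with full
    evolutionary protection (boost 0) so every functional window is 100%
    identical, yielding >= 500 benchmark sites per dataset.
    """
    estimates: Dict[str, list] = {sp: [] for sp in FNR_SENSITIVITIES}
    n_benchmark = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed + k, n_groups=n_groups,
            functional_sites_per_protein=4.0,
            functional_conservation_boost=0.0,
            source_sensitivities={sp: {"ms": s}
                                  for sp, s in FNR_SENSITIVITIES.items()})
        _, groups, _, truth = simulate_families(cfg)
        catalog = simulate_detection(truth, cfg, groups)
        idx = index_catalog(catalog)
        aligned, seqs = [], {}
        for gid in sorted(groups):
            g = groups[gid]
            seqs[gid] = {sp: g.ungapped((sp, pid)) for sp, pid in g.members}
            aligned.extend(select_aligned_acceptor_sites(g, idx))
        bm = select_benchmark_sites(groups, aligned, seqs)
        n_benchmark.append(len(bm))
        for sp in FNR_SENSITIVITIES:
            estimates[sp].append(estimate_fnr(bm, sp).fnr)
    per_species = {}
    for sp, s in FNR_SENSITIVITIES.items():
        oracle = conditional_fnr_oracle(FNR_SENSITIVITIES, sp)
        mean_est = float(np.mean(estimates[sp]))
        per_species[sp] = {"sensitivity": s, "oracle": oracle,
                           "estimate": mean_est,
                           "abs_err": abs(mean_est - oracle)}
    by_level = {}
    for sp, d in per_species.items():
        by_level.setdefault(d["sensitivity"], []).append(d["estimate"])
    means = {s: float(np.mean(v)) for s, v in by_level.items()}
    monotone = means[0.3] > means[0.6] > means[0.9]
    return {"per_species": per_species,
            "max_abs_err": max(d["abs_err"] for d in per_species.values()),
            "fnr_by_sensitivity": means,
            "monotone_in_sensitivity": monotone,
            "n_benchmark": n_benchmark}


# ---------------------------------------------------------------- propensity

def _split(windows: Sequence[SiteWindow], rng, train_frac: float = 0.7):
    idx = rng.permutation(len(windows))
    k = int(train_frac * len(windows))
    return ([windows[i] for i in idx[:k]], [windows[i] for i in idx[k:]])


def propensity_recovery(seed: int, n_groups: int = 60,
                        n_shuffles: int = 20) -> dict:
    """Held-out AUC with the planted motif, shuffled-label null AUC, and
    decile calibration of the score against generator truth."""
    cfg = SimulationConfig(seed=seed, n_groups=n_groups)
    res = run_synthetic_pipeline(cfg, train_propensity=False)
    bank = default_bank()
    ref = cfg.reference_species
    pos_w, neg_w = assemble_training_sets(res.catalog, res.nr_proteomes[ref],
                                          "ST", seed=seed)
    rng = np.random.default_rng([seed, 10])
    pos_tr, pos_te = _split(pos_w, rng)
    neg_tr, neg_te = _split(neg_w, rng)
    model = train_propensity_model(pos_tr, neg_tr, bank, species=ref, seed=seed)
    X_te = feature_matrix(list(pos_te) + list(neg_te), bank)
    y_te = np.r_[np.ones(len(pos_te)), np.zeros(len(neg_te))]
    auc = float(roc_auc_score(y_te, model.margin(X_te)))

    # permutation null: retrain on shuffled labels
    train_windows = list(pos_tr) + list(neg_tr)
    y_tr = np.r_[np.ones(len(pos_tr)), -np.ones(len(neg_tr))]
    null_aucs = []
    for s in range(n_shuffles):
        perm = np.random.default_rng([seed, 20, s]).permutation(len(y_tr))
        yp = y_tr[perm]
        pw = [w for w, l in zip(train_windows, yp) if l > 0]
        nw = [w for w, l in zip(train_windows, yp) if l < 0]
        m = train_propensity_model(pw, nw, bank, species=ref, seed=seed)
        null_aucs.append(float(roc_auc_score(y_te, m.margin(X_te))))

    # decile calibration against generator truth over every ST acceptor
    windows, labels = [], []
    for gid, gt in res.truth.groups.items():
        seq = res.groups[gid].ungapped((ref, f"{ref}_{gid}"))
        true_st = {p for p in gt.true_phospho[ref] if seq[p - 1] in "ST"}
        for i, aa in enumerate(seq):
            if aa in "ST":
                windows.append(extract_window(seq, i + 1))
                labels.append((i + 1) in true_st)
    scores = model.calibrate(model.margin(feature_matrix(windows, bank)))
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(scores, kind="stable")
    deciles = np.array_split(order, 10)
    fracs = np.array([labels[d].mean() for d in deciles])
    iso = IsotonicRegression(increasing=True).fit_transform(
        np.arange(10), fracs)
    n_per = np.array([len(d) for d in deciles])
    pooled_se = float(np.sqrt(fracs.mean() * (1 - fracs.mean()) / n_per.mean()))
    max_iso_dev = float(np.max(np.abs(fracs - iso)))
    rho = float(spearmanr(np.arange(10), fracs).statistic)
    return {"auc": auc,
            "n_heldout": int(len(y_te)),
            "n_calibration": int(len(labels)),
            "null_auc_mean": float(np.mean(null_aucs)),
            "null_aucs": null_aucs,
            "decile_fractions": fracs.tolist(),
            "calibration_max_isotonic_dev": max_iso_dev,
            "calibration_noise_level": 2 * pooled_se,
            "calibration_spearman": rho,
            "calibration_monotone": bool(max_iso_dev <= 2 * pooled_se
                                         and rho > 0.8)}


# -------------------------------------------------------------- conservation

def conservation_recovery(seed: int, n_groups: int = 60) -> dict:
    """Conserved-call sensitivity/specificity vs planted truth, plus the
    nested identity-bin monotonicity of ortholog phosphorylation rates."""
    cfg = SimulationConfig(seed=seed, n_groups=n_groups)
    res = run_synthetic_pipeline(cfg, train_propensity=False)
    ref = cfg.reference_species
    tp = fp = fn = tn = 0
    pairs = []
    for r in res.conservation_results:
        gt = res.truth.groups[r.site.group_id]
        pos = r.site.positions[ref]
        is_func = pos in gt.functional_sites
        is_neut = pos in gt.neutral_sites
        for sp, ident in r.per_ortholog.items():
            pairs.append((ident, r.site.observed[sp]))
        if not (is_func or is_neut):
            continue
        if r.conserved:
            tp, fp = (tp + 1, fp) if is_func else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if is_func else (fn, tn + 1)
    pairs_arr = np.array(pairs, dtype=float)
    rates = []
    for c in (0.2, 0.5, 0.8, 1.0):
        sel = pairs_arr[:, 0] >= c - 1e-12
        rates.append(float(pairs_arr[sel, 1].mean()))
    return {"sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "n_functional": tp + fn, "n_neutral": tn + fp,
            "bin_rates": rates,
            "bins_monotone": all(rates[i] <= rates[i + 1] + 1e-12
                                 for i in range(len(rates) - 1))}


# ---------------------------------------------------------------- enrichment

def enrichment_power_and_type1(seed: int, n_sites: int = 2000,
                               n_power: int = 50, n_null: int = 200,
                               n_groups: int = 230) -> dict:
    """Power to detect 2x variant enrichment near conserved sites, and
    type-I error under uniform variant placement, on a fixed site scaffold
    with variants redrawn each replicate.

    Scaffold sites are spaced at least one full proximity window apart
    (2*distance + 1) so their proximal flags are independent under uniform
    placement — the condition under which the Fisher test's nominal level
    applies; overlapping windows would share variants and overdisperse the
    stratum counts.
    """
    base = SimulationConfig(seed=seed, n_groups=n_groups)
    _, _, _, truth = simulate_families(base)
    ref = base.reference_species
    spacing = 2 * base.variant_distance + 1
    sites = []
    for gid, gt in truth.groups.items():
        last = -spacing
        for pos in sorted(gt.functional_sites + gt.neutral_sites):
            if pos - last < spacing:
                continue
            last = pos
            idents = [gt.identity[(pos, sp)] for sp in base.species if sp != ref]
            sites.append((f"{ref}_{gid}", pos, float(np.mean(idents))))
    rng = np.random.default_rng([seed, 30])
    take = min(n_sites, len(sites))
    sites = [sites[i] for i in rng.choice(len(sites), size=take, replace=False)]
    coords = [(p, q) for p, q, _ in sites]
    high_mask = [ident >= 0.5 for _, _, ident in sites]

    def one_p(sub_seed: int, factor: float) -> float:
        cfg = dataclasses.replace(base, seed=sub_seed,
                                  variant_enrichment=factor)
        variants = simulate_variants(truth, cfg)
        flags = proximal_sites(coords, variants)
        hi = [f for f, h in zip(flags, high_mask) if h]
        lo = [f for f, h in zip(flags, high_mask) if not h]
        _, _, p = enrichment_test(hi, lo)
        return p

    power_ps = [one_p(seed + 1000 + k, 2.0) for k in range(n_power)]
    null_ps = [one_p(seed + 5000 + k, 1.0) for k in range(n_null)]
    return {"n_sites": take,
            "power": float(np.mean([p < 0.05 for p in power_ps])),
            "type1_error": float(np.mean([p < 0.05 for p in null_ps])),
            "n_power": n_power, "n_null": n_null}


# ------------------------------------------------------------------- remap

def remap_roundtrip(seed: int, n_peptides: int = 10000,
                    n_groups: int = 40) -> dict:
    """Sample peptides with known coordinates from a synthetic proteome,
    remap them, and re-extract: the peptide at the reported coordinates
    must reproduce the input exactly, and every unique match must equal
    the sampling truth."""
    from .integrate import NonRedundantProteome, consolidate_proteome

    cfg = SimulationConfig(seed=seed, n_groups=n_groups)
    proteomes, _, _, _ = simulate_families(cfg)
    ref = cfg.reference_species
    nr = consolidate_proteome(proteomes[ref])
    pids = sorted(nr.sequences)
    rng = np.random.default_rng([seed, 40])
    n_fail_roundtrip = n_fail_truth = n_unique = 0
    for _ in range(n_peptides):
        pid = pids[int(rng.integers(len(pids)))]
        seq = nr.sequences[pid]
        length = int(rng.integers(7, 26))
        start = int(rng.integers(0, len(seq) - length + 1))
        offset = int(rng.integers(1, length + 1))
        peptide = seq[start:start + length]
        hits = remap_peptide_site(peptide, offset, nr)
        true_pos = start + offset
        for hit_pid, pos, ambiguous in hits:
            s = nr.sequences[hit_pid]
            extracted = s[pos - offset: pos - offset + length]
            if extracted != peptide:
                n_fail_roundtrip += 1
        if len(hits) == 1:
            n_unique += 1
            hit_pid, pos, _ = hits[0]
            if (hit_pid, pos) != (pid, true_pos):
                n_fail_truth += 1
    return {"n_peptides": n_peptides, "n_unique": n_unique,
            "n_roundtrip_failures": n_fail_roundtrip,
            "n_truth_mismatches": n_fail_truth}
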