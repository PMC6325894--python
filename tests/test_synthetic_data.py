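"""Generator determinism, limits, and distributional recovery checks."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from phosite_evo.constants import AMINO_ACIDS
from phosite_evo.synthetic_data import (DEFAULT_BACKGROUND, SimulationConfig,
                                        _substitute, simulate_detection,
                                        simulate_families, simulate_variants)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_groups=3, motif_strength=1.5)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        loaded = SimulationConfig.from_yaml(path)
        assert loaded == cfg

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, functional_conservation_boost=1.5)

    def test_background_renormalized(self):
        bg = {aa: 1.0 for aa in AMINO_ACIDS}
        cfg = SimulationConfig(seed=1, background=bg)
        assert sum(cfg.background.values()) == pytest.approx(1.0)

    def test_combined_sensitivity(self):
        cfg = SimulationConfig(seed=1)
        # 1 - (1-.55)(1-.5)(1-.45)(1-.2) for the four reference sources
        assert cfg.combined_sensitivity("mel") == pytest.approx(0.901, abs=1e-3)


class TestDeterminism:
    def test_identical_config_gives_identical_outputs(self):
        cfg = SimulationConfig(seed=9, n_groups=4)
        out1 = simulate_families(cfg)
        out2 = simulate_families(cfg)
        for sp in cfg.species:
            assert [r.sequence for r in out1[0][sp]] == \
                [r.sequence for r in out2[0][sp]]
        t1, t2 = out1[3], out2[3]
        for gid in t1.groups:
            assert t1.groups[gid].functional_sites == \
                t2.groups[gid].functional_sites
            assert t1.groups[gid].true_phospho == t2.groups[gid].true_phospho


class TestEvolutionLimits:
    def test_zero_substitution_makes_all_species_identical(self):
        cfg = SimulationConfig(
            seed=3, n_groups=4,
            branch_probs={k: 0.0 for k in SimulationConfig(seed=0).branch_probs})
        proteomes, groups, _, truth = simulate_families(cfg)
        for gid, g in groups.items():
            rows = {g.ungapped(m) for m in g.members}
            assert len(rows) == 1
        for gt in truth.groups.values():
            for pos in gt.functional_sites:
                for sp in cfg.species:
                    if sp == cfg.reference_species:
                        continue
                    assert gt.identity[(pos, sp)] == 1.0

    def test_no_protection_equalizes_functional_and_neutral_identity(self):
        # boost = 1: windows around functional and neutral sites evolve at
        # the same rate, so their mean identities agree closely
        cfg = SimulationConfig(seed=13, n_groups=120,
                               functional_conservation_boost=1.0)
        _, _, _, truth = simulate_families(cfg)
        func, neut = [], []
        for gt in truth.groups.values():
            for pos in gt.functional_sites:
                func.extend(gt.identity[(pos, sp)] for sp in cfg.species
                            if sp != cfg.reference_species)
            for pos in gt.neutral_sites:
                neut.extend(gt.identity[(pos, sp)] for sp in cfg.species
                            if sp != cfg.reference_species)
        assert len(func) > 500 and len(neut) > 500
        assert abs(np.mean(func) - np.mean(neut)) < 0.02

    def test_substitution_fraction_matches_configured_probability(self):
        rng = np.random.default_rng(4)
        bg = np.array([DEFAULT_BACKGROUND[aa] for aa in AMINO_ACIDS])
        bg = bg / bg.sum()
        seq = rng.integers(0, 20, size=100_000)
        for p in (0.1, 0.5, 0.8):
            child = _substitute(rng, seq, np.full(seq.size, p), bg)
            frac = np.mean(child != seq)
            assert abs(frac - p) < 0.02

    def test_pairwise_divergence_follows_tree_paths(self):
        cfg = SimulationConfig(seed=21, n_groups=40)
        _, groups, _, truth = simulate_families(cfg)
        bp = cfg.branch_probs
        keep_mel = ((1 - bp["b_mel"]) * (1 - bp["b_n4"]) * (1 - bp["b_n3"])
                    * (1 - bp["b_n2"]) * (1 - bp["b_n1"]))
        # expected mel-vir identity at unprotected positions (coincidental
        # agreement of two independent substitutions adds only ~0.01)
        expected = keep_mel * (1 - bp["b_vir"])
        matches = total = 0
        for gid, g in groups.items():
            gt = truth.groups[gid]
            protected = set()
            for pos in gt.functional_sites:
                protected.update(range(pos - 1 - cfg.flank,
                                       pos + cfg.flank))
            a = g.ungapped(("mel", f"mel_{gid}"))
            b = g.ungapped(("vir", f"vir_{gid}"))
            for i, (x, y) in enumerate(zip(a, b)):
                if i not in protected:
                    matches += x == y
                    total += 1
        assert expected - 0.02 < matches / total < expected + 0.03


class TestDetection:
    def _families(self, seed=17, **kw):
        cfg = SimulationConfig(seed=seed, n_groups=25, **kw)
        proteomes, groups, omap, truth = simulate_families(cfg)
        return cfg, groups, truth

    def test_perfect_sensitivity_recovers_truth_exactly(self):
        cfg, groups, truth = self._families(
            source_sensitivities={sp: {"ms": 1.0}
                                  for sp in ("mel", "sim", "yak", "ana",
                                             "pse", "vir")})
        catalog = simulate_detection(truth, cfg, groups)
        for gid, gt in truth.groups.items():
            for sp in cfg.species:
                detected = {r.position for r in catalog.records
                            if r.species == sp and r.protein_id == f"{sp}_{gid}"}
                assert detected == gt.true_phospho[sp]

    def test_zero_sensitivity_gives_empty_catalog(self):
        cfg, groups, truth = self._families(
            source_sensitivities={sp: {"ms": 0.0}
                                  for sp in ("mel", "sim", "yak", "ana",
                                             "pse", "vir")})
        catalog = simulate_detection(truth, cfg, groups)
        assert len(catalog) == 0

    def test_detected_fraction_within_binomial_bounds(self):
        s = 0.37
        cfg, groups, truth = self._families(
            seed=23,
            source_sensitivities={sp: {"ms": s}
                                  for sp in ("mel", "sim", "yak", "ana",
                                             "pse", "vir")})
        catalog = simulate_detection(truth, cfg, groups)
        n_trials = sum(len(gt.true_phospho[sp])
                       for gt in truth.groups.values() for sp in cfg.species)
        n_det = len(catalog.records)
        lo, hi = stats.binom.interval(0.99, n_trials, s)
        assert lo <= n_det <= hi

    def test_detected_peptides_validate_and_remap(self):
        cfg, groups, truth = self._families(seed=29)
        catalog = simulate_detection(truth, cfg, groups)
        for rec in catalog.records[:200]:
            gid = rec.protein_id.split("_", 1)[1]
            seq = groups[gid].ungapped((rec.species, rec.protein_id))
            rec.validate(seq)


class TestVariants:
    def test_uniform_when_factor_one(self):
        cfg = SimulationConfig(seed=41, n_groups=60, variant_enrichment=1.0,
                               variant_rate=0.02)
        _, _, _, truth = simulate_families(cfg)
        variants = simulate_variants(truth, cfg)
        # pooled scaled positions should be uniform on (0, 1]
        scaled = []
        for pid, pos in truth.variants:
            gid = pid.split("_", 1)[1]
            scaled.append(pos / truth.groups[gid].length)
        assert len(scaled) > 300
        p = stats.kstest(scaled, "uniform").pvalue
        assert p > 0.01

    def test_factor_two_ratio_recovered(self):
        cfg = SimulationConfig(seed=43, n_groups=200, variant_rate=0.02,
                               variant_enrichment=2.0)
        _, _, _, truth = simulate_families(cfg)
        simulate_variants(truth, cfg)
        s = truth.variant_stats
        assert s["rate_far"] > 0
        assert 1.7 <= s["rate_near"] / s["rate_far"] <= 2.3

    def test_zero_rate_gives_empty_table(self):
        cfg = SimulationConfig(seed=47, n_groups=5, variant_rate=0.0,
                               variant_enrichment=1.0)
        _, _, _, truth = simulate_families(cfg)
        assert simulate_variants(truth, cfg) == []

    def test_sub_unit_enrichment_rejected(self):
        cfg = SimulationConfig(seed=47, n_groups=2)
        _, _, _, truth = simulate_families(cfg)
        bad = dataclasses.replace(cfg, variant_enrichment=0.5)
        with pytest.raises(ValueError):
            simulate_variants(truth, bad)


class TestIndelMode:
    def test_deletions_produce_consistent_gapped_truth(self):
        from phosite_evo.pipeline import run_synthetic_pipeline

        cfg = SimulationConfig(seed=2, n_groups=15, indel_rate=0.01)
        res = run_synthetic_pipeline(cfg, train_propensity=False)
        # gapped rows exist, reference row is gap-free, ungapping each row
        # reproduces the proteome sequence
        any_gap = False
        for gid, g in res.groups.items():
            for (sp, pid), row in g.alignment.items():
                if sp == cfg.reference_species:
                    assert "-" not in row
                any_gap = any_gap or "-" in row
                rec = [r for r in res.proteomes[sp]
                       if r.protein_id == pid][0]
                assert row.replace("-", "") == rec.sequence
        assert any_gap
        # deleted acceptors were classified as gaps somewhere
        labels = {c for r in res.conservation_results
                  for c in r.acceptor_class.values()}
        assert "gap" in labels
        # detection records still validate against species sequences
        for rec in res.catalog.records[:100]:
            gid = rec.protein_id.split("_", 1)[1]
            rec.validate(res.groups[gid].ungapped((rec.species,
                                                   rec.protein_id)))
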