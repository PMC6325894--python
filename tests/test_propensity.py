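"""PSSM feature scoring, training-set assembly, hinge trainer, prediction."""

import numpy as np
import pytest

from phosite_evo.conservation import extract_window
from phosite_evo.constants import AA_INDEX, AMINO_ACIDS
from phosite_evo.integrate import ProteinRecord, SiteCatalog, consolidate_proteome
from phosite_evo.propensity import (KinaseMotifPSSM, PropensityModel,
                                    assemble_training_sets, default_bank,
                                    feature_matrix, load_pssm_bank,
                                    predict_propensity, score_features,
                                    train_propensity_model, write_pssm_bank)
from helpers import make_site


def pssm(weights=None, cls="ST", name="k1"):
    w = np.zeros((11, 20)) if weights is None else weights
    return KinaseMotifPSSM(kinase=name, acceptor_class=cls, weights=w)


class TestScoreFeatures:
    def test_zero_pssm_scores_zero(self):
        w = extract_window("AAAAASAAAAA", 6)
        assert score_features(w, [pssm()]) == pytest.approx([0.0])

    def test_single_cell_matrix_hits_when_residue_present(self):
        weights = np.zeros((11, 20))
        weights[5 - 2, AA_INDEX["P"]] = 1.0  # offset -2
        w_hit = extract_window("AAAPASAAAAA", 6)  # P at offset -2
        w_miss = extract_window("AAAAASAAAAA", 6)
        assert score_features(w_hit, [pssm(weights)]) == pytest.approx([1.0])
        assert score_features(w_miss, [pssm(weights)]) == pytest.approx([0.0])

    def test_random_windows_match_double_loop_oracle(self, rng):
        bank = [pssm(rng.normal(size=(11, 20)), name=f"k{i}")
                for i in range(5)]
        for _ in range(20):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=11))
            seq = seq[:5] + "S" + seq[6:]
            w = extract_window(seq, 6)
            got = score_features(w, bank)
            for k, p in enumerate(bank):
                expected = 0.0
                for off in range(-5, 6):
                    aa = seq[5 + off]
                    expected += p.weights[off + 5, AA_INDEX[aa]]
                assert got[k] == pytest.approx(expected)

    def test_truncated_positions_score_zero_weight(self):
        weights = np.ones((11, 20))
        w = extract_window("SAAAAA", 1)  # left-truncated: 5 missing positions
        assert score_features(w, [pssm(weights)]) == pytest.approx([6.0])

    def test_acceptor_class_mismatch_rejected(self):
        w = extract_window("AAAAAYAAAAA", 6)
        with pytest.raises(ValueError, match="class"):
            score_features(w, [pssm(cls="ST")])

    def test_non_acceptor_center_rejected(self):
        w = extract_window("AAAAAGAAAAA", 6)
        with pytest.raises(ValueError):
            score_features(w, [pssm()])


def _toy_catalog_and_proteome(rng, n_proteins=6, length=80):
    records, sites = [], []
    for i in range(n_proteins):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        pid = f"P{i:02d}"
        records.append(ProteinRecord(pid, "mel", seq))
        for pos, aa in enumerate(seq, start=1):
            if aa in "ST" and rng.random() < 0.3:
                sites.append(make_site(protein_id=pid, position=pos,
                                       residue=aa))
    return SiteCatalog(sites), consolidate_proteome(records)


class TestAssemble:
    def test_positives_capped_at_availability(self, rng):
        catalog, nr = _toy_catalog_and_proteome(rng)
        pos, neg = assemble_training_sets(catalog, nr, "ST", n_samples=2000)
        n_detected = len([r for r in catalog if r.residue in "ST"])
        assert len(pos) == len({r.key for r in catalog})
        assert len(pos) <= 2000 and len(neg) <= 2000

    def test_same_seed_reproduces_sample(self, rng):
        catalog, nr = _toy_catalog_and_proteome(rng)
        a = assemble_training_sets(catalog, nr, "ST", n_samples=10, seed=7)
        b = assemble_training_sets(catalog, nr, "ST", n_samples=10, seed=7)
        assert [w.residues for w in a[0]] == [w.residues for w in b[0]]
        assert [w.residues for w in a[1]] == [w.residues for w in b[1]]

    def test_labels_match_catalog_membership(self, rng):
        catalog, nr = _toy_catalog_and_proteome(rng)
        pos, neg = assemble_training_sets(catalog, nr, "ST", n_samples=50,
                                          seed=1)
        detected = {(r.protein_id, r.position) for r in catalog}
        # brute-force: locate each window back in the proteome
        def locations(windows):
            out = []
            for w in windows:
                for pid, seq in nr.sequences.items():
                    for p in range(1, len(seq) + 1):
                        if (seq[p - 1] in "ST"
                                and extract_window(seq, p).residues == w.residues
                                and p == w.center_position):
                            out.append((pid, p))
            return out
        assert all(loc in detected for loc in locations(pos))
        assert all(loc not in detected for loc in locations(neg))

    def test_empty_class_rejected(self, rng):
        _, nr = _toy_catalog_and_proteome(rng)
        with pytest.raises(ValueError):
            assemble_training_sets(SiteCatalog(), nr, "ST")


class TestTrain:
    def _separable_sets(self):
        # positives have P at +1 (feature 1 fires), negatives never do
        pos = [extract_window("AAAAASPAAAA", 6) for _ in range(8)]
        neg = [extract_window("AAAAASGAAAA", 6) for _ in range(8)]
        weights = np.zeros((11, 20))
        weights[6, AA_INDEX["P"]] = 1.0
        bank = [pssm(), pssm(weights, name="k2")]
        return pos, neg, bank

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        pos, neg, bank = self._separable_sets()
        model = train_propensity_model(pos, neg, bank)
        X = feature_matrix(pos + neg, bank)
        pred = model.margin(X) > 0
        assert (pred == np.r_[np.ones(8), np.zeros(8)].astype(bool)).all()

    def test_training_is_bitwise_deterministic(self, rng):
        catalog, nr = _toy_catalog_and_proteome(rng)
        pos, neg = assemble_training_sets(catalog, nr, "ST", n_samples=40,
                                          seed=3)
        bank = default_bank()
        m1 = train_propensity_model(pos, neg, bank, seed=3)
        m2 = train_propensity_model(pos, neg, bank, seed=3)
        assert (m1.weights == m2.weights).all()
        assert m1.bias == m2.bias
        assert m1.calib_slope == m2.calib_slope

    def test_degenerate_identical_features_rejected(self):
        pos = [extract_window("AAAAASAAAAA", 6)] * 4
        neg = [extract_window("AAAAASAAAAA", 6)] * 4
        with pytest.raises(ValueError, match="degenerate|constant"):
            train_propensity_model(pos, neg, [pssm()])

    def test_planted_motif_feature_gets_largest_weight(self, rng):
        # positives generated from motif k2 (P at +1); other features noise
        bank = [pssm(rng.normal(scale=0.1, size=(11, 20)), name=f"n{i}")
                for i in range(4)]
        weights = np.zeros((11, 20))
        weights[6, AA_INDEX["P"]] = 2.0
        bank.append(pssm(weights, name="planted"))
        pos, neg = [], []
        for _ in range(60):
            s = "".join(rng.choice(list(AMINO_ACIDS), size=11))
            pos.append(extract_window(s[:5] + "SP" + s[7:], 6))
            neg.append(extract_window(s[:5] + "SG" + s[7:], 6))
        model = train_propensity_model(pos, neg, bank)
        assert int(np.argmax(np.abs(model.weights))) == 4


class TestPredict:
    def test_observed_sites_always_score_exactly_one(self, rng):
        catalog, nr = _toy_catalog_and_proteome(rng)
        pos, neg = assemble_training_sets(catalog, nr, "ST", n_samples=40,
                                          seed=5)
        bank = default_bank()
        model = train_propensity_model(pos, neg, bank, seed=5)
        assert predict_propensity(model, pos[0], bank, observed=True) == 1.0

    def test_scores_bounded_in_unit_interval(self, rng):
        pos, neg, bank = (TestTrain()._separable_sets())
        model = train_propensity_model(pos, neg, bank)
        for _ in range(200):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=11))
            seq = seq[:5] + "T" + seq[6:]
            score = predict_propensity(model, extract_window(seq, 6), bank)
            assert 0.0 <= score <= 1.0

    def test_strong_positive_scores_above_negative_exemplar(self):
        pos, neg, bank = (TestTrain()._separable_sets())
        model = train_propensity_model(pos, neg, bank)
        assert predict_propensity(model, pos[0], bank) > \
            predict_propensity(model, neg[0], bank)

    def test_class_mismatch_rejected(self):
        pos, neg, bank = (TestTrain()._separable_sets())
        model = train_propensity_model(pos, neg, bank)
        with pytest.raises(ValueError):
            predict_propensity(model, extract_window("AAAAAYAAAAA", 6), bank)


class TestSerialization:
    def test_model_json_roundtrip_is_prediction_stable(self, rng, tmp_path):
        pos, neg, bank = (TestTrain()._separable_sets())
        model = train_propensity_model(pos, neg, bank)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PropensityModel.from_json(path)
        X = feature_matrix(pos + neg, bank)
        assert model.margin(X) == pytest.approx(loaded.margin(X))
        assert model.calibrate(model.margin(X)) == \
            pytest.approx(loaded.calibrate(loaded.margin(X)))

    def test_bank_tsv_roundtrip(self, tmp_path):
        bank = default_bank()
        path = tmp_path / "bank.tsv"
        write_pssm_bank(bank, path)
        reloaded = load_pssm_bank(path)
        assert len(reloaded) == len(bank) == 40
        for a, b in zip(bank, reloaded):
            assert a.kinase == b.kinase
            assert a.acceptor_class == b.acceptor_class
            assert np.allclose(a.weights, b.weights)
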