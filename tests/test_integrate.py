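"""Proteome consolidation, peptide remapping, catalog merging, overlap."""

import random
import string

import pytest

from phosite_evo.integrate import (ProteinRecord, PTMSiteRecord, SiteCatalog,
                                   consolidate_proteome, merge_catalogs,
                                   overlap_table, remap_peptide_site)


class TestConsolidate:
    def test_exact_duplicates_collapse_to_one_representative(self, toy_proteins):
        nr = consolidate_proteome(toy_proteins)
        assert len(nr) == 2
        assert nr.id_map["P1"] == "P1"  # lexicographically smallest id wins
        assert nr.id_map["P2"] == "P1"
        assert nr.id_map["P3"] == "P3"

    def test_distinct_sequences_keep_identity_mapping(self):
        records = [ProteinRecord(f"Q{i}", "mel", seq)
                   for i, seq in enumerate(["MAS", "MTS", "MYS"])]
        nr = consolidate_proteome(records)
        assert len(nr) == 3
        assert all(nr.id_map[r.protein_id] == r.protein_id for r in records)

    def test_random_duplicates_match_brute_force_string_set(self, rng):
        pool = ["".join(rng.choice(list("ACDEFGH"), size=8)) for _ in range(12)]
        records = [ProteinRecord(f"R{i:02d}", "mel",
                                 pool[int(rng.integers(len(pool)))])
                   for i in range(50)]
        nr = consolidate_proteome(records)
        assert len(nr) == len({r.sequence for r in records})
        assert set(nr.id_map) == {r.protein_id for r in records}

    def test_conflicting_duplicate_id_raises_naming_the_id(self):
        records = [ProteinRecord("X1", "mel", "MAS"),
                   ProteinRecord("X1", "mel", "MTS")]
        with pytest.raises(ValueError, match="X1"):
            consolidate_proteome(records)

    def test_empty_input_gives_empty_proteome(self):
        assert len(consolidate_proteome([])) == 0

    def test_mixed_species_rejected(self):
        records = [ProteinRecord("A", "mel", "MAS"),
                   ProteinRecord("B", "sim", "MTS")]
        with pytest.raises(ValueError, match="species"):
            consolidate_proteome(records)


class TestRemap:
    def test_full_sequence_peptide_maps_to_offset(self, toy_proteins):
        nr = consolidate_proteome(toy_proteins)
        hits = remap_peptide_site("MSTAYKLSPQR", 3, nr)
        assert hits == [("P1", 3, False)]

    def test_absent_peptide_maps_nowhere(self, toy_proteins):
        nr = consolidate_proteome(toy_proteins)
        assert remap_peptide_site("WWWWWW", 1, nr) == []

    def test_multiple_matches_are_flagged_ambiguous(self):
        nr = consolidate_proteome([ProteinRecord("A", "mel", "ASPKKKASPK")])
        hits = remap_peptide_site("ASP", 2, nr)
        assert [(p, pos) for p, pos, _ in hits] == [("A", 2), ("A", 8)]
        assert all(amb for _, _, amb in hits)

    def test_sampled_peptides_recover_truth_vs_brute_force(self, rng):
        seqs = {f"S{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                            size=60)) for i in range(8)}
        nr = consolidate_proteome(
            [ProteinRecord(pid, "mel", s) for pid, s in seqs.items()])
        for _ in range(60):
            pid = f"S{int(rng.integers(8))}"
            start = int(rng.integers(0, 50))
            length = int(rng.integers(7, 11))
            offset = int(rng.integers(1, length + 1))
            peptide = seqs[pid][start:start + length]
            hits = remap_peptide_site(peptide, offset, nr)
            # independent brute-force scan of every substring position
            expected = sorted(
                (qid, i + offset)
                for qid, s in seqs.items()
                for i in range(len(s) - len(peptide) + 1)
                if s[i:i + len(peptide)] == peptide)
            assert sorted((p, q) for p, q, _ in hits) == expected
            assert (pid, start + offset) in {(p, q) for p, q, _ in hits}

    def test_roundtrip_reextraction_reproduces_peptide(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        nr = consolidate_proteome([ProteinRecord("T1", "mel", seq)])
        for _ in range(50):
            start = int(rng.integers(0, 180))
            length = int(rng.integers(7, 21))
            offset = int(rng.integers(1, length + 1))
            peptide = seq[start:start + length]
            for pid, pos, _ in remap_peptide_site(peptide, offset, nr):
                s = nr.sequences[pid]
                assert s[pos - offset:pos - offset + length] == peptide

    def test_bad_offset_rejected(self, toy_proteins):
        nr = consolidate_proteome(toy_proteins)
        with pytest.raises(ValueError):
            remap_peptide_site("MST", 4, nr)


def _catalog(recs):
    return SiteCatalog(recs)


class TestMerge:
    def test_disjoint_catalogs_sum(self, make_site_record):
        c1 = _catalog([make_site_record(position=2)])
        c2 = _catalog([make_site_record(position=8, residue="S",
                                        protein_id="P3", source="src_b")])
        assert len(merge_catalogs([c1, c2])) == 2

    def test_shared_key_unions_sources(self, make_site_record):
        c1 = _catalog([make_site_record(source="src_a")])
        c2 = _catalog([make_site_record(source="src_b")])
        merged = merge_catalogs([c1, c2])
        assert len(merged) == 1
        key = next(iter(merged.keys))
        assert merged.sources_of(key) == {"src_a", "src_b"}

    def test_random_merge_equals_set_union_and_is_order_independent(
            self, rng, make_site_record):
        catalogs = []
        for s in range(4):
            recs = [make_site_record(position=int(p), residue="S",
                                     protein_id="PP", source=f"src_{s}")
                    for p in rng.integers(1, 10, size=6)]
            catalogs.append(_catalog(recs))
        merged = merge_catalogs(catalogs)
        union = set().union(*(c.keys for c in catalogs))
        assert merged.keys == union
        shuffled = [catalogs[i] for i in rng.permutation(4)]
        remerged = merge_catalogs(shuffled)
        assert remerged.keys == merged.keys
        assert {k: remerged.sources_of(k) for k in remerged.keys} == \
               {k: merged.sources_of(k) for k in merged.keys}

    def test_residue_conflict_raises_naming_key(self, make_site_record):
        c1 = _catalog([make_site_record(residue="S")])
        c2 = _catalog([make_site_record(residue="T", source="src_b")])
        with pytest.raises(ValueError, match="P1"):
            merge_catalogs([c1, c2])


class TestOverlap:
    def test_single_source_has_zero_overlap(self, make_site_record):
        cat = _catalog([make_site_record(position=p) for p in (1, 2, 3)])
        table = overlap_table(cat)
        row = table[table.source == "src_a"].iloc[0]
        assert row.n_sites == 3
        assert row.n_overlap_ge1_other == 0
        assert row.n_overlap_ge2_other == 0

    def test_three_sources_sharing_one_key_hand_enumeration(self, make_site_record):
        recs = []
        for s in ("src_a", "src_b", "src_c"):
            recs.append(make_site_record(position=5, source=s))  # shared
            recs.append(make_site_record(position=ord(s[-1]), source=s))
        table = overlap_table(_catalog(recs)).set_index("source")
        for s in ("src_a", "src_b", "src_c"):
            assert table.loc[s, "n_sites"] == 2
            assert table.loc[s, "n_overlap_ge1_other"] == 1
            assert table.loc[s, "n_overlap_ge2_other"] == 1
        assert table.loc["All", "n_sites"] == 4
        assert table.loc["All", "n_overlap_ge1_other"] == 1  # >=2 sources
        assert table.loc["All", "n_overlap_ge2_other"] == 1  # >=3 sources

    def test_random_catalog_counts_match_per_key_tally(self, rng, make_site_record):
        recs = []
        for s in range(4):
            for p in rng.integers(1, 15, size=10):
                recs.append(make_site_record(position=int(p), protein_id="PP",
                                             source=f"src_{s}"))
        cat = _catalog(recs)
        table = overlap_table(cat).set_index("source")
        tally = {k: len(cat.sources_of(k)) for k in cat.keys}
        for s in cat.sources:
            mine = [k for k in cat.keys if s in cat.sources_of(k)]
            assert table.loc[s, "n_sites"] == len(mine)
            assert table.loc[s, "n_overlap_ge1_other"] == \
                sum(1 for k in mine if tally[k] >= 2)
            assert table.loc[s, "n_overlap_ge2_other"] == \
                sum(1 for k in mine if tally[k] >= 3)
        # monotone row structure
        for s in cat.sources:
            assert (table.loc[s, "n_overlap_ge2_other"]
                    <= table.loc[s, "n_overlap_ge1_other"]
                    <= table.loc[s, "n_sites"])


def test_site_record_validation_catches_mismatches(make_site_record):
    rec = make_site_record(position=2, residue="S")
    rec.validate("MSTAYKLSPQR")
    with pytest.raises(ValueError, match="mismatch"):
        make_site_record(position=3, residue="S").validate("MSTAYKLSPQR")
    with pytest.raises(ValueError, match="outside"):
        make_site_record(position=99).validate("MSTAYKLSPQR")
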