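import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from presnrna.structio import (
    DEFAULT_EXT_LEN, ConstraintSpec, ParseError, SecondaryStructure,
    SequenceRecord, VariantSet, extend_3prime, filter_variants, find_sm_site,
    read_dotbracket, read_fasta, write_dotbracket, write_fasta,
)


def _rec(species, vid, seq, rna="U2"):
    return SequenceRecord(id=vid, species=species, rna_name=rna, sequence=seq)


class TestFastaIO:
    def test_parse_groups_by_species_and_normalizes(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">hs|U2|v1\nACGTTT\n>mm|U2|v1\nacguuu\n")
        vs = read_fasta(p)
        assert vs.rna_name == "U2"
        assert vs.species == ["hs", "mm"]
        assert vs.per_species["hs"][0].sequence == "ACGUUU"
        assert vs.per_species["mm"][0].sequence == "ACGUUU"

    def test_malformed_header_raises(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">justonefield\nACGU\n")
        with pytest.raises(ParseError, match="justonefield"):
            read_fasta(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ParseError, match="no FASTA records"):
            read_fasta(p)

    def test_round_trip(self, tmp_path, small_family):
        p = tmp_path / "family.fa"
        write_fasta(small_family.variant_set, p)
        back = read_fasta(p)
        orig = {(r.species, r.id): r.sequence for r in small_family.variant_set.all_records()}
        got = {(r.species, r.id): r.sequence for r in back.all_records()}
        assert got == orig


class TestStructureTypes:
    @pytest.mark.parametrize("db,seq", [
        ("((...)", "GGAAAC"),   # unbalanced
        ("(..)", "GAAC"),       # hairpin loop < 3
        ("...)", "AAAC"),       # stray close
        ("(...))", "GAAACC"),   # unbalanced close
    ])
    def test_invalid_dotbrackets_rejected(self, db, seq):
        with pytest.raises(ValueError):
            SecondaryStructure(seq, db)

    def test_illegal_pair_rejected(self):
        with pytest.raises(ValueError, match="illegal base pair"):
            SecondaryStructure("GAAAG", "(...)")

    def test_pair_table(self):
        s = SecondaryStructure("GGAAACC", "((...))")
        assert s.pairs == [(0, 6), (1, 5)]
        assert s.pair_table == [6, 5, -1, -1, -1, 1, 0]

    def test_constraint_validation(self):
        c = ConstraintSpec("(.x.)")
        assert c.forced_pairs == [(0, 4)]
        assert c.blocked == {2}
        with pytest.raises(ValueError, match="not complementary"):
            c.validate_for("AAAAA")
        c.validate_for("GAAAC")

    def test_dotbracket_file_round_trip(self, tmp_path):
        structs = [SecondaryStructure("GGAAACC", "((...))", energy=-1.2),
                   SecondaryStructure("GGAAACC", ".(...).")]
        p = tmp_path / "s.db"
        write_dotbracket(structs, p)
        back = read_dotbracket(p)
        assert [(s.dotbracket, s.energy) for s in back] == \
            [("((...))", -1.2), (".(...).", None)]


class TestFilterVariants:
    def _base_set(self):
        full = "GGGGC" * 8 + "AUUUUUGA" + "CCCC"  # 52 nt with Sm site
        per = {"sp1": [], "sp2": []}
        for k in range(10):
            per["sp1" if k < 5 else "sp2"].append(_rec("sp1" if k < 5 else "sp2", f"v{k}", full))
        return per, full

    def test_counts_by_rule(self):
        per, full = self._base_set()
        short = full[: int(0.5 * len(full))].replace("AUUUUUG", "ACCCCCG")
        smless = full.replace("AUUUUUG", "ACCCCCG")
        per["sp1"] += [_rec("sp1", "frag1", short), _rec("sp1", "frag2", short),
                       _rec("sp1", "frag3", short)]
        per["sp2"] += [_rec("sp2", "nosm1", smless), _rec("sp2", "nosm2", smless)]
        vs = VariantSet(rna_name="U2", per_species=per)
        kept, report = filter_variants(vs)
        assert report.short == 3
        assert report.no_sm == 2
        assert report.n_retained == 10
        assert all(len(v) == 5 for v in kept.per_species.values())

    def test_identical_records_all_retained(self):
        per, _ = self._base_set()
        vs = VariantSet(rna_name="U2", per_species=per)
        kept, report = filter_variants(vs)
        assert report.n_retained == report.n_input == 10

    def test_idempotent(self, decoy_family):
        once, r1 = filter_variants(decoy_family.variant_set)
        twice, r2 = filter_variants(once)
        assert r2.short == r2.no_sm == 0
        assert {(r.species, r.id) for r in twice.all_records()} == \
            {(r.species, r.id) for r in once.all_records()}

    def test_u1_70k_motif_required(self):
        motif = "GGCAGAGG"
        with_motif = "G" * 10 + motif + "CCCC" + "AUUUUUG" + "AAA"
        without = "G" * 10 + "AAAAAAAA" + "CCCC" + "AUUUUUG" + "AAA"
        vs = VariantSet(rna_name="U1", per_species={
            "hs": [_rec("hs", "ok", with_motif, "U1"), _rec("hs", "no70k", without, "U1")],
        })
        kept, report = filter_variants(vs, require_u1_70k=True, u1_70k_pattern=motif)
        assert report.no_u1_70k == 1
        assert [r.id for r in kept.per_species["hs"]] == ["ok"]

    def test_species_left_empty_is_dropped(self):
        per, full = self._base_set()
        smless = full.replace("AUUUUUG", "ACCCCCG")
        per["sp3"] = [_rec("sp3", "bad", smless)]
        vs = VariantSet(rna_name="U2", per_species=per)
        kept, report = filter_variants(vs)
        assert "sp3" not in kept.per_species
        assert report.dropped_species == ["sp3"]


class TestExtend3Prime:
    def test_default_u2_extension_length(self):
        rec = _rec("hs", "v1", "G" * 40 + "AUUUUUGA")
        ext = extend_3prime(rec, "ACGU" * 10, DEFAULT_EXT_LEN["U2"])
        assert len(ext) == len(rec) + 21

    def test_zero_extension_is_identity(self):
        rec = _rec("hs", "v1", "GGAAACC")
        assert extend_3prime(rec, "AAAA", 0).sequence == "GGAAACC"

    def test_concatenation(self):
        rec = _rec("hs", "v1", "GG")
        assert extend_3prime(rec, "AUC", 3).sequence == "GGAUC"

    def test_short_context_raises(self):
        rec = _rec("hs", "v1", "GG")
        with pytest.raises(ValueError, match="shorter than"):
            extend_3prime(rec, "AU", 3)


class TestFindSmSite:
    def test_match_at_expected_offset(self):
        seq = "C" * 49 + "AUUUUUG" + "CC"
        assert find_sm_site(seq) == (49, 56)

    def test_absent(self):
        assert find_sm_site("ACGC" * 20) is None

    def test_three_prime_most_wins(self):
        seq = "C" * 10 + "AUUUUUG" + "C" * 63 + "AUUUUUG" + "CCC"
        assert find_sm_site(seq) == (80, 87)

    @settings(derandomize=True, max_examples=30)
    @given(pad=st.integers(min_value=0, max_value=25))
    def test_five_prime_pad_shifts_interval(self, pad):
        seq = "CCA" + "AUUUUUG" + "CAC"
        base = find_sm_site(seq)
        shifted = find_sm_site("C" * pad + seq)
        assert shifted == (base[0] + pad, base[1] + pad)
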