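import pytest

from presnrna.fold import mfe, subopt, template_constraint
from presnrna.refold import (
    SmSiteStaysPairedError, detect_nss, force_sm_single, min_block_open,
    pathway, single_pathway,
)
from presnrna.structio import SecondaryStructure, find_sm_site
from presnrna.synthetic import SimConfig, make_family


class TestDetectNSS:
    def test_hairpin_enclosing_sm_site(self):
        #        0123456789012345678
        seq = "GGGAUUUUUGAAACCC"
        s = SecondaryStructure(seq, "(((..........)))")
        sm = find_sm_site(seq)
        nss = detect_nss(s, sm)
        assert nss is not None
        assert nss.sm_overlap == sm[1] - sm[0]
        assert len(nss.helix_pairs) == 3

    def test_helix_free_window_returns_none(self):
        seq = "GGGAAACCC" + "A" * 15 + "AUUUUUG" + "A" * 12
        s = SecondaryStructure(seq, "(((...)))" + "." * (len(seq) - 9))
        sm = find_sm_site(seq)
        assert detect_nss(s, sm, window=5) is None

    def test_larger_overlap_wins(self):
        # helix A encloses the whole Sm site; helix B merely sits inside
        # the search window with zero overlap
        seq = "GGG" + "AAUUUUUGA" + "CCC" + "ACA" + "GGC" + "AAA" + "GCC"
        db = "(((.........)))" + "..." + "(((...)))"
        s = SecondaryStructure(seq, db)
        sm = find_sm_site(seq)
        assert sm == (4, 11)
        nss = detect_nss(s, sm, window=10)
        assert nss.helix_pairs[0] == (0, 14)
        assert nss.sm_overlap == 7


class TestMinBlockOpen:
    def test_already_open_site_returns_k0(self, template):
        seq, struct, sm = template
        # structure with the NSS absent: Sm site unpaired from the start
        pairs_outside = [(i, j) for i, j in
                         SecondaryStructure(seq, struct).pairs if j < sm[0]]
        from presnrna.structio import pairs_to_dotbracket
        open_struct = SecondaryStructure(seq, pairs_to_dotbracket(pairs_outside, len(seq)))
        nss = detect_nss(SecondaryStructure(seq, struct), sm)
        k, intermediate, _c, _e = min_block_open(open_struct, nss, sm)
        assert k == 0
        assert intermediate.dotbracket == open_struct.dotbracket

    def test_minimal_k_and_monotonicity(self, template):
        seq, struct, sm = template
        primary = SecondaryStructure(seq, struct)
        nss = detect_nss(primary, sm)
        k, intermediate, _c, _e = min_block_open(primary, nss, sm)
        assert k >= 1
        assert not intermediate.paired_positions(sm)
        nss_positions = {p for ij in nss.helix_pairs for p in ij}

        def top_with_blocks(kk):
            blocked = {p for ij in nss.helix_pairs[:kk] for p in ij}
            c = template_constraint(primary, blocked,
                                    unconstrained=nss_positions - blocked)
            return subopt(seq, c, max_structures=1, band=0.0)[0]

        # k-1 must leave at least one Sm position paired
        assert top_with_blocks(k - 1).paired_positions(sm)
        # blocking more pairs keeps the site open
        for kk in range(k + 1, min(k + 3, len(nss.helix_pairs)) + 1):
            assert not top_with_blocks(kk).paired_positions(sm)

    def test_unopenable_site_reports_residual(self):
        # Sm-like U-run locked into a GC-clamped helix that cannot melt and
        # whose root block alone cannot open the U-run (forced outer pairs)
        seq = "GGGGGAUUUUUGAAACAAAACGGGGCUUUCCCCC"
        # build a structure pairing the U-run against complementary A/G run
        s = mfe(seq)
        sm = find_sm_site(seq)
        nss = detect_nss(s, sm)
        if nss is None or not s.paired_positions(sm):
            pytest.skip("construction did not pair the Sm site")
        try:
            k, inter, _c, _e = min_block_open(s, nss, sm)
            assert not inter.paired_positions(sm)
        except SmSiteStaysPairedError as exc:
            assert exc.residual


class TestForceSmSingle:
    def test_already_satisfying_intermediate_unchanged(self, template):
        seq, struct, sm = template
        primary = SecondaryStructure(seq, struct)
        nss = detect_nss(primary, sm)
        _k, intermediate, _c, _e = min_block_open(primary, nss, sm)
        final, _c2, _e2 = force_sm_single(intermediate, sm, downstream_n=3)
        assert final.dotbracket == intermediate.dotbracket

    def test_constrained_positions_unpaired(self, template):
        seq, struct, sm = template
        primary = SecondaryStructure(seq, struct)
        final, c2, _e = force_sm_single(primary, sm, downstream_n=3)
        blocked = set(range(sm[0], min(len(seq), sm[1] + 3)))
        pt = final.pair_table
        assert all(pt[p] == -1 for p in blocked)

    def test_downstream_n_only_matters_when_downstream_paired(self, template):
        seq, struct, sm = template
        primary = SecondaryStructure(seq, struct)
        f0, _, _ = force_sm_single(primary, sm, downstream_n=0)
        f3, _, _ = force_sm_single(primary, sm, downstream_n=3)
        downstream = list(range(sm[1], min(len(seq), sm[1] + 3)))
        if not f0.paired_positions((downstream[0], downstream[-1] + 1)):
            assert f0.dotbracket == f3.dotbracket

    def test_negative_downstream_rejected(self, template):
        seq, struct, sm = template
        with pytest.raises(ValueError):
            force_sm_single(SecondaryStructure(seq, struct), sm, downstream_n=-1)


class TestPathway:
    def test_zero_divergence_family_shares_identical_stages(self):
        cfg = SimConfig.default(seed=2, n_species=3, divergence=0.0,
                                intra_divergence=0.0, decoy_fragment_rate=0.0,
                                decoy_smless_rate=0.0)
        fam = make_family(cfg)
        pc = pathway(fam.variant_set)
        assert not pc.failed_species
        inters = {r.intermediate.dotbracket for r in pc.per_species.values()}
        finals = {r.final.dotbracket for r in pc.per_species.values()}
        assert len(inters) == 1 and len(finals) == 1
        for r in pc.per_species.values():
            assert not r.intermediate.paired_positions(r.sm)
            assert not r.final.paired_positions(r.sm)

    def test_consensus_sets_cover_all_species(self, small_family):
        pc = pathway(small_family.variant_set)
        assert pc.intermediate_set is not None and pc.final_set is not None
        assert set(pc.intermediate_set.per_species) == set(pc.per_species)
        assert set(pc.final_set.per_species) == set(pc.per_species)

    def test_open_primary_takes_k0_path(self, template):
        seq, struct, sm = template
        pairs_outside = [(i, j) for i, j in
                         SecondaryStructure(seq, struct).pairs if j < sm[0]]
        from presnrna.structio import pairs_to_dotbracket
        open_primary = SecondaryStructure(seq, pairs_to_dotbracket(pairs_outside, len(seq)))
        res, _e1, _e2 = single_pathway(open_primary, sm)
        assert res.k_blocked == 0
        assert res.intermediate.dotbracket == open_primary.dotbracket
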