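import itertools

import pytest

from oracles import brute_tree_distance, sequence_for

from presnrna.consensus import (
    CandidatePool, RepresentativeSet, best_representative, match_homologs,
    run_consensus, select_most_related_set,
)
from presnrna.structio import SecondaryStructure, SequenceRecord, VariantSet
from presnrna.synthetic import SimConfig, make_family
from presnrna.treedist import structure_distance


def struct(db, species="sp", vid="v1", rank=0, energy=None):
    return SecondaryStructure(sequence_for(db), db, energy=energy,
                              provenance=(species, vid, rank))


DBS = ["((...))....", ".(...).....", "...........", "..((...))..", "(((...))).."]


class TestBestRepresentative:
    def test_single_structure_is_its_own_representative(self):
        pool = {"v1": [struct(DBS[0])]}
        rep, score = best_representative(pool)
        assert rep.dotbracket == DBS[0]
        assert score == 0.0

    def test_argmin_matches_exhaustive_evaluation(self):
        pool = {
            "v1": [struct(DBS[0], vid="v1", rank=0), struct(DBS[1], vid="v1", rank=1)],
            "v2": [struct(DBS[3], vid="v2", rank=0), struct(DBS[4], vid="v2", rank=1)],
        }
        rep, score = best_representative(pool)
        # independent recomputation with the brute-force distance oracle
        cands = [s for v in pool.values() for s in v]
        def eq1(c):
            tot = 0.0
            for ens in pool.values():
                tot += min(brute_tree_distance(c.dotbracket, s.dotbracket) for s in ens)
            return tot / len(pool)
        best_score = min(eq1(c) for c in cands)
        assert score == pytest.approx(best_score)
        assert eq1(rep) == pytest.approx(best_score)

    def test_tie_broken_by_lower_energy(self):
        pool = {"v1": [struct(DBS[0], energy=-1.0, rank=0),
                       struct(DBS[0], energy=-2.0, rank=1)]}
        rep, _ = best_representative(pool)
        assert rep.energy == -2.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            best_representative({"v1": []})


class TestMatchHomologs:
    def _pool(self, mapping):
        pool = CandidatePool(rna_name="U2")
        for sp, dbs in mapping.items():
            pool.per_species[sp] = {
                "v1": [struct(db, species=sp, rank=r) for r, db in enumerate(dbs)]
            }
        return pool

    def test_identical_pools_match_at_distance_zero(self):
        pool = self._pool({"a": DBS[:3], "b": DBS[:3], "c": DBS[:3]})
        template = pool.per_species["a"]["v1"][0]
        matches = match_homologs(template, pool)
        assert set(matches) == {"a", "b", "c"}
        for sp in ("b", "c"):
            assert matches[sp].dotbracket == template.dotbracket

    def test_per_species_argmin_matches_brute_force(self):
        pool = self._pool({"a": [DBS[0]], "b": [DBS[1], DBS[2]], "c": [DBS[3], DBS[4]]})
        template = pool.per_species["a"]["v1"][0]
        matches = match_homologs(template, pool)
        for sp in ("b", "c"):
            expected = min(
                (brute_tree_distance(template.dotbracket, s.dotbracket), s.dotbracket)
                for s in pool.species_structures(sp)
            )
            assert brute_tree_distance(template.dotbracket, matches[sp].dotbracket) == \
                expected[0]

    def test_own_pool_never_searched(self):
        # species a's pool contains a closer structure than the template
        # itself maps to; the mapping for a must stay the template
        pool = self._pool({"a": [DBS[0], DBS[1]], "b": [DBS[2]]})
        template = pool.per_species["a"]["v1"][1]
        matches = match_homologs(template, pool)
        assert matches["a"] is template


class TestSelectMostRelated:
    def _set(self, score, template):
        return RepresentativeSet(per_species={}, mutual_score=score,
                                 conservation=0.0, template_species=template)

    def test_single_set_returned(self):
        s = self._set(5.0, "a")
        assert select_most_related_set([s]) is s

    def test_argmin_of_mutual_score(self):
        sets = [self._set(7.0, "a"), self._set(3.0, "b"), self._set(5.0, "c")]
        assert select_most_related_set(sets).template_species == "b"

    def test_tie_goes_to_lowest_template_index(self):
        sets = [self._set(3.0, "c"), self._set(3.0, "a"), self._set(3.0, "b")]
        assert select_most_related_set(sets).template_species == "a"


class TestRunConsensus:
    def test_zero_divergence_family_is_perfectly_conserved(self):
        cfg = SimConfig.default(seed=5, n_species=3, divergence=0.0,
                                intra_divergence=0.0, decoy_fragment_rate=0.0,
                                decoy_smless_rate=0.0)
        fam = make_family(cfg)
        rep = run_consensus(fam.variant_set)
        assert rep.conservation == 0.0
        dbs = {s.dotbracket for s in rep.per_species.values()}
        assert dbs == {cfg.template_struct}

    def test_single_species_rejected(self):
        cfg = SimConfig.default(seed=5, n_species=1, decoy_fragment_rate=0.0,
                                decoy_smless_rate=0.0)
        fam = make_family(cfg)
        with pytest.raises(ValueError, match="at least 2 species"):
            run_consensus(fam.variant_set)

    def test_two_species_reduces_to_cross_pool_minimum(self):
        cfg = SimConfig.default(seed=9, n_species=2, divergence=0.08,
                                decoy_fragment_rate=0.0, decoy_smless_rate=0.0)
        fam = make_family(cfg)
        chosen, pool = run_consensus(fam.variant_set, return_pool=True)
        reps = {sp: best_representative(pool.per_species[sp])[0] for sp in pool.species}
        expected = min(
            min(structure_distance(reps[sp], s)
                for s in pool.species_structures(other))
            for sp, other in itertools.permutations(pool.species, 2)
        )
        assert chosen.mutual_score == expected

    def test_planted_structure_recovered_at_low_divergence(self, small_family):
        rep = run_consensus(small_family.variant_set)
        hits = sum(
            1 for sp, s in rep.per_species.items()
            if structure_distance(s, small_family.ground_truth[sp]) == 0
        )
        assert hits > len(rep.per_species) / 2

    def test_mutual_score_recomputable_from_members(self, small_family):
        rep = run_consensus(small_family.variant_set)
        raw, norm = rep.recompute_scores()
        assert raw == pytest.approx(rep.mutual_score)
        assert norm == pytest.approx(rep.conservation)
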