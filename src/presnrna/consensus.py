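"""Cross-species consensus selection of representative structures.

For each species, the variants' suboptimal ensembles form a pool of up to
20 structures per variant.  The per-species *best representative* is the
pool structure minimizing the average, over variants, of the distance to
that variant's closest ensemble member.  Each species' representative
then anchors a homolog set (its best match in every other species' pool),
and the set with the smallest sum of pairwise tree edit distances is
selected as the cross-species consensus ("primary folded transcripts").

Selection stages use raw tree edit distances; normalization by sequence
length enters only the reported conservation statistics.  All tie-breaks
are deterministic (score, then energy, then dot-bracket, then species
order) so repeated runs are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from . import fold
from .structio import SecondaryStructure, VariantSet
from .treedist import DistanceCache, normalized_distance

__all__ = [
    "CandidatePool", "RepresentativeSet", "best_representative",
    "match_homologs", "select_most_related_set", "run_consensus",
    "consensus_over_pools",
]


@dataclass
class CandidatePool:
    """Per-species, per-variant suboptimal ensembles with provenance.

    ``per_species[species][variant_id]`` is the energy-sorted list of at
    most 20 structures; every structure's provenance is
    ``(species, variant_id, rank)``.
    """

    rna_name: str
    per_species: dict[str, dict[str, list[SecondaryStructure]]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted(self.per_species)

    @property
    def n(self) -> int:
        return len(self.per_species)

    def m_i(self, species: str) -> int:
        return len(self.per_species[species])

    def species_structures(self, species: str) -> list[SecondaryStructure]:
        out = []
        for vid in sorted(self.per_species[species]):
            out.extend(self.per_species[species][vid])
        return out

    @classmethod
    def from_variant_set(cls, vs: VariantSet,
                         backend: Optional[fold.FoldBackend] = None,
                         max_structures: int = fold.DEFAULT_MAX_STRUCTURES,
                         band: Optional[float] = fold.DEFAULT_BAND) -> "CandidatePool":
        backend = backend or fold.BuiltinBackend()
        pool = cls(rna_name=vs.rna_name)
        for sp in vs.species:
            pool.per_species[sp] = {}
            for rec in vs.per_species[sp]:
                structs = fold.subopt(rec.sequence, None, max_structures=max_structures,
                                      backend=backend, band=band)
                ranked = [
                    SecondaryStructure(s.sequence, s.dotbracket, energy=s.energy,
                                       provenance=(sp, rec.id, rank))
                    for rank, s in enumerate(structs)
                ]
                pool.per_species[sp][rec.id] = ranked
        return pool


@dataclass
class RepresentativeSet:
    """One structure per species plus its mutual-relatedness scores."""

    per_species: dict[str, SecondaryStructure]
    mutual_score: float          # sum of pairwise raw tree edit distances
    conservation: float          # mean pairwise normalized distance
    template_species: Optional[str] = None

    def recompute_scores(self, cache: Optional[DistanceCache] = None) -> tuple[float, float]:
        cache = cache or DistanceCache()
        sps = sorted(self.per_species)
        raw = 0.0
        norm = 0.0
        npairs = 0
        for a in range(len(sps)):
            for b in range(a + 1, len(sps)):
                sa, sb = self.per_species[sps[a]], self.per_species[sps[b]]
                d = cache.distance(sa, sb)
                raw += d
                norm += normalized_distance(d, len(sa), len(sb))
                npairs += 1
        return raw, (norm / npairs if npairs else 0.0)

    def to_json(self) -> str:
        payload = {
            "template_species": self.template_species,
            "mutual_score": self.mutual_score,
            "conservation": self.conservation,
            "members": {
                sp: {
                    "variant": s.provenance[1] if s.provenance else None,
                    "rank": s.provenance[2] if s.provenance else None,
                    "dotbracket": s.dotbracket,
                    "energy": s.energy,
                }
                for sp, s in sorted(self.per_species.items())
            },
        }
        return json.dumps(payload, indent=2)


def _struct_key(s: SecondaryStructure) -> tuple:
    return (s.energy if s.energy is not None else 0.0, s.dotbracket)


def best_representative(pool_i: dict[str, list[SecondaryStructure]],
                        cache: Optional[DistanceCache] = None,
                        denominator: Optional[int] = None) -> tuple[SecondaryStructure, float]:
    """Best representative structure of one species and its score.

    Every structure in the species pool is a candidate; its score is the
    average over the species' variants of the minimal distance to that
    variant's ensemble (the candidate's own variant contributes 0).
    ``denominator`` overrides the averaging denominator (e.g. the species
    count n instead of the variant count m_i); being constant across
    candidates it rescales scores without changing the argmin.
    Ties break by (score, energy, dot-bracket).
    """
    variant_ids = sorted(pool_i)
    if not variant_ids or all(not pool_i[v] for v in variant_ids):
        raise ValueError("empty candidate pool")
    denom = denominator if denominator is not None else len(variant_ids)
    cache = cache or DistanceCache()
    best = None
    for vid in variant_ids:
        for cand in pool_i[vid]:
            total = 0.0
            for other in variant_ids:
                ens = pool_i[other]
                if not ens:
                    continue
                total += min(cache.distance(cand, s) for s in ens)
            score = total / denom
            key = (score, *_struct_key(cand))
            if best is None or key < best[0]:
                best = (key, cand, score)
    return best[1], best[2]


def match_homologs(template: SecondaryStructure, pool: CandidatePool,
                   cache: Optional[DistanceCache] = None) -> dict[str, SecondaryStructure]:
    """Best match to ``template`` in every other species' pool.

    The template's own species maps to the template itself and its pool is
    never searched, so a template cannot trivially match itself.
    """
    if template.provenance is None:
        raise ValueError("template must carry provenance")
    own_species = template.provenance[0]
    cache = cache or DistanceCache()
    out = {own_species: template}
    for sp in pool.species:
        if sp == own_species:
            continue
        candidates = pool.species_structures(sp)
        if not candidates:
            import warnings
            warnings.warn(f"species {sp!r} has an empty pool; skipped", stacklevel=2)
            continue
        best = min(candidates, key=lambda s: (cache.distance(template, s), *_struct_key(s)))
        out[sp] = best
    return out


def _mutual_scores(members: dict[str, SecondaryStructure],
                   cache: DistanceCache) -> tuple[float, float]:
    sps = sorted(members)
    raw, norm, npairs = 0.0, 0.0, 0
    for a in range(len(sps)):
        for b in range(a + 1, len(sps)):
            sa, sb = members[sps[a]], members[sps[b]]
            d = cache.distance(sa, sb)
            raw += d
            norm += normalized_distance(d, len(sa), len(sb))
            npairs += 1
    return raw, (norm / npairs if npairs else 0.0)


def select_most_related_set(sets: list[RepresentativeSet]) -> RepresentativeSet:
    """The set with minimal mutual score; ties go to the lowest template
    species in sort order (then input order)."""
    if not sets:
        raise ValueError("no representative sets given")
    return min(
        enumerate(sets),
        key=lambda kv: (kv[1].mutual_score, kv[1].template_species or "", kv[0]),
    )[1]


def consensus_over_pools(templates: dict[str, SecondaryStructure],
                         pool: CandidatePool,
                         cache: Optional[DistanceCache] = None) -> RepresentativeSet:
    """Template-anchored homolog matching plus most-related-set selection.

    Shared by the primary consensus stage and by the folding-intermediate /
    final-structure stages, which re-run it on pools of constrained
    suboptimal structures.
    """
    cache = cache or DistanceCache()
    sets = []
    for sp in sorted(templates):
        members = match_homologs(templates[sp], pool, cache)
        raw, norm = _mutual_scores(members, cache)
        sets.append(RepresentativeSet(per_species=members, mutual_score=raw,
                                      conservation=norm, template_species=sp))
    return select_most_related_set(sets)


def run_consensus(vs: VariantSet,
                  backend: Optional[fold.FoldBackend] = None,
                  max_structures: int = fold.DEFAULT_MAX_STRUCTURES,
                  band: Optional[float] = fold.DEFAULT_BAND,
                  cache: Optional[DistanceCache] = None,
                  return_pool: bool = False):
    """Full consensus pipeline for one filtered variant set.

    Folds every variant (<= ``max_structures`` suboptimal structures
    each), picks one best representative per species, builds the n
    template-anchored homolog sets and returns the most mutually related
    one with its conservation score.
    """
    if vs.n_species < 2:
        raise ValueError("conservation requires at least 2 species")
    cache = cache or DistanceCache()
    pool = CandidatePool.from_variant_set(vs, backend=backend,
                                          max_structures=max_structures, band=band)
    templates = {}
    for sp in pool.species:
        rep, _score = best_representative(pool.per_species[sp], cache)
        templates[sp] = rep
    chosen = consensus_over_pools(templates, pool, cache)
    if return_pool:
        return chosen, pool
    return chosen
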