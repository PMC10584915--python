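"""Two-step constrained-refolding pathway that opens the Sm site.

In the precursor fold ("primary folded transcript") a compact helix — the
Near Sm-site Structure, NSS — forms around, and partly including, the
U-rich Sm site, sterically blocking Sm-ring assembly.  The modeled
opening pathway is:

1. *Folding intermediate*: block the minimal number of outermost NSS base
   pairs (both partners forbidden from pairing, mimicking helicase
   action), hold the remaining template pairs, and refold.  The smallest
   block count whose top-ranked refold leaves every Sm-site position
   unpaired defines the intermediate.
2. *Final structure*: additionally force the Sm motif plus a few
   downstream nucleotides single-stranded (mimicking the bound Sm ring)
   and take the constrained MFE.

Cross-species consensus is re-applied to the constrained ensembles at
each step, exactly as for the primary structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import fold
from .consensus import CandidatePool, RepresentativeSet, consensus_over_pools, run_consensus
from .structio import ConstraintSpec, SecondaryStructure, VariantSet, find_sm_site
from .treedist import DistanceCache

logger = logging.getLogger(__name__)

DEFAULT_NSS_WINDOW = 10
DEFAULT_SM_DOWNSTREAM = 3


class SmSiteStaysPairedError(RuntimeError):
    """No admissible block count renders the Sm site single-stranded."""

    def __init__(self, residual: list[int]):
        self.residual = residual
        super().__init__(
            "Sm site cannot be opened by blocking NSS pairs; still-paired "
            f"positions (1-based): {[p + 1 for p in residual]}"
        )


@dataclass(frozen=True)
class NSSRegion:
    """The helix forming the Near Sm-site Structure.

    ``helix_pairs`` runs from the root (outermost pair) to the loop;
    ``span`` is the enclosed sequence interval (0-based half-open);
    ``sm_overlap`` counts Sm-site nucleotides inside the paired-or-loop
    region.
    """

    helix_pairs: tuple[tuple[int, int], ...]
    span: tuple[int, int]
    sm_overlap: int

    def __post_init__(self):
        ii = [p[0] for p in self.helix_pairs]
        if ii != sorted(ii):
            raise ValueError("helix pairs must be ordered root to loop")
        if self.sm_overlap < 0:
            raise ValueError("sm_overlap must be >= 0")


@dataclass
class PathwayResult:
    primary: SecondaryStructure
    intermediate: SecondaryStructure
    final: SecondaryStructure
    k_blocked: int
    step1_constraint: ConstraintSpec
    step2_constraint: ConstraintSpec
    sm: tuple[int, int] = (0, 0)


def detect_nss(s: SecondaryStructure, sm: tuple[int, int],
               window: int = DEFAULT_NSS_WINDOW) -> Optional[NSSRegion]:
    """Find the helix around the Sm site.

    Candidate helices either have paired positions within ``sm`` extended
    by ``window`` nt on each side, or enclose Sm nucleotides in their
    loop.  Among candidates the one overlapping the most Sm nucleotides
    wins; ties go to the helix whose root is closest to the Sm 5' end.
    Returns None when the neighborhood is helix-free.
    """
    start, end = sm
    if not (0 <= start < end <= len(s)):
        raise ValueError("Sm interval outside sequence")
    lo, hi = max(0, start - window), min(len(s), end + window)
    best = None
    for run in fold.decompose_helices(s):
        positions = {p for ij in run for p in ij}
        root_i, root_j = run[0]
        enclosed = range(root_i, root_j + 1)
        in_window = any(lo <= p < hi for p in positions)
        loop_has_sm = any(start <= p < end for p in enclosed)
        if not (in_window or loop_has_sm):
            continue
        overlap = sum(1 for p in range(start, end) if root_i <= p <= root_j)
        key = (-overlap, abs(root_i - start))
        if best is None or key < best[0]:
            best = (key, NSSRegion(helix_pairs=run, span=(root_i, root_j + 1),
                                   sm_overlap=overlap))
    return best[1] if best else None


def min_block_open(primary: SecondaryStructure, nss: NSSRegion, sm: tuple[int, int],
                   backend: Optional[fold.FoldBackend] = None,
                   max_structures: int = fold.DEFAULT_MAX_STRUCTURES,
                   band: Optional[float] = fold.DEFAULT_BAND,
                   ) -> tuple[int, SecondaryStructure, ConstraintSpec, list[SecondaryStructure]]:
    """Minimal root-ward NSS block that opens the Sm site.

    Tries k = 0, 1, ... blocked pairs: both partners of each of the k
    outermost NSS pairs are set to 'x', template pairs *outside* the NSS
    are forced, and the remaining NSS pairs are left free — so a weak
    A-U/G-U stem deprived of its root stacking can (and typically does)
    melt spontaneously, unfolding parts that were never blocked.  Returns
    the first k whose top-ranked refolded structure has every Sm-site
    position unpaired, together with that structure, the constraint used,
    and the kept constrained ensemble (<= 20).  Blocking more pairs keeps
    the site open (the block is monotone).
    """
    if not nss.helix_pairs:
        raise ValueError("empty NSS region")
    top = None
    ensemble: list[SecondaryStructure] = []
    # the whole enclosed region (including bulged-off sub-stems) belongs
    # to the NSS and may melt; only structure outside the span is held
    nss_positions = set(range(*nss.span))
    for k in range(0, len(nss.helix_pairs) + 1):
        if k == 0:
            if not primary.paired_positions(sm):
                return 0, primary, ConstraintSpec.free(len(primary)), [primary]
            continue
        blocked = {p for ij in nss.helix_pairs[:k] for p in ij}
        constraint = fold.template_constraint(primary, blocked,
                                              unconstrained=nss_positions - blocked)
        ensemble = fold.subopt(primary.sequence, constraint, max_structures=max_structures,
                               backend=backend, band=band)
        if not ensemble:
            continue
        top = ensemble[0]
        if not top.paired_positions(sm):
            return k, top, constraint, ensemble
    # report which Sm positions remain paired at full blocking
    residual = top.paired_positions(sm) if top is not None else primary.paired_positions(sm)
    raise SmSiteStaysPairedError(residual)


def force_sm_single(intermediate: SecondaryStructure, sm: tuple[int, int],
                    downstream_n: int = DEFAULT_SM_DOWNSTREAM,
                    backend: Optional[fold.FoldBackend] = None,
                    max_structures: int = fold.DEFAULT_MAX_STRUCTURES,
                    band: Optional[float] = fold.DEFAULT_BAND,
                    ) -> tuple[SecondaryStructure, ConstraintSpec, list[SecondaryStructure]]:
    """Force the Sm motif plus ``downstream_n`` following nucleotides
    single-stranded (mimicking the bound Sm ring) and refold.

    Template pairs of the intermediate are retained where both partners
    stay unconstrained.  Returns the constrained MFE, the constraint and
    the kept ensemble.
    """
    if downstream_n < 0:
        raise ValueError("downstream_n must be >= 0")
    start, end = sm
    blocked = set(range(start, min(len(intermediate), end + downstream_n)))
    constraint = fold.template_constraint(intermediate, blocked)
    ensemble = fold.subopt(intermediate.sequence, constraint, max_structures=max_structures,
                           backend=backend, band=band)
    if not ensemble:
        raise ValueError("Sm-single-strand constraint unsatisfiable")
    return ensemble[0], constraint, ensemble


def single_pathway(primary: SecondaryStructure, sm: tuple[int, int],
                   window: int = DEFAULT_NSS_WINDOW,
                   downstream_n: int = DEFAULT_SM_DOWNSTREAM,
                   backend: Optional[fold.FoldBackend] = None,
                   max_structures: int = fold.DEFAULT_MAX_STRUCTURES,
                   band: Optional[float] = fold.DEFAULT_BAND,
                   ) -> tuple[PathwayResult, list[SecondaryStructure], list[SecondaryStructure]]:
    """Run both opening steps for one species.

    Returns the pathway result plus the constrained ensembles backing the
    intermediate and final consensus stages.  A primary fold whose Sm
    neighborhood is helix-free takes the k=0 path.
    """
    nss = detect_nss(primary, sm, window)
    if nss is None:
        k, intermediate, c1 = 0, primary, ConstraintSpec.free(len(primary))
        ens1 = [primary]
        if primary.paired_positions(sm):
            raise SmSiteStaysPairedError(primary.paired_positions(sm))
    else:
        k, intermediate, c1, ens1 = min_block_open(primary, nss, sm, backend=backend,
                                                   max_structures=max_structures, band=band)
    final, c2, ens2 = force_sm_single(intermediate, sm, downstream_n, backend=backend,
                                      max_structures=max_structures, band=band)
    result = PathwayResult(primary=primary, intermediate=intermediate, final=final,
                           k_blocked=k, step1_constraint=c1, step2_constraint=c2, sm=sm)
    assert not result.intermediate.paired_positions(sm), "intermediate leaves Sm site paired"
    assert not result.final.paired_positions(sm), "final leaves Sm site paired"
    return result, ens1, ens2


@dataclass
class PathwayConsensus:
    per_species: dict[str, PathwayResult]
    failed_species: dict[str, str]
    intermediate_set: Optional[RepresentativeSet]
    final_set: Optional[RepresentativeSet]


def _carry_provenance(structs, sp, vid):
    return [SecondaryStructure(s.sequence, s.dotbracket, energy=s.energy,
                               provenance=(sp, vid, rank))
            for rank, s in enumerate(structs)]


def pathway(vs: VariantSet,
            sm_pattern: Optional[str] = None,
            window: int = DEFAULT_NSS_WINDOW,
            downstream_n: int = DEFAULT_SM_DOWNSTREAM,
            backend: Optional[fold.FoldBackend] = None,
            max_structures: int = fold.DEFAULT_MAX_STRUCTURES,
            band: Optional[float] = fold.DEFAULT_BAND,
            primaries: Optional[RepresentativeSet] = None) -> PathwayConsensus:
    """Per-species two-step pathway plus cross-species consensus.

    Runs the primary consensus first (or reuses ``primaries``), opens the
    NSS species by species, then re-applies template matching and
    most-related-set selection to the constrained ensembles of the
    intermediates and finals.  Species whose Sm site cannot be opened are
    reported and excluded from the consensus sets.
    """
    from .structio import DEFAULT_SM_PATTERN
    sm_pattern = sm_pattern or DEFAULT_SM_PATTERN
    cache = DistanceCache()
    if primaries is None:
        primaries = run_consensus(vs, backend=backend, max_structures=max_structures,
                                  band=band, cache=cache)
    results: dict[str, PathwayResult] = {}
    failed: dict[str, str] = {}
    pools1 = CandidatePool(rna_name=vs.rna_name)
    pools2 = CandidatePool(rna_name=vs.rna_name)
    for sp, primary in sorted(primaries.per_species.items()):
        sm = find_sm_site(primary.sequence, sm_pattern)
        if sm is None:
            failed[sp] = "no Sm site found"
            continue
        try:
            res, ens1, ens2 = single_pathway(primary, sm, window=window,
                                             downstream_n=downstream_n, backend=backend,
                                             max_structures=max_structures, band=band)
        except SmSiteStaysPairedError as exc:
            logger.warning("species %s excluded: %s", sp, exc)
            failed[sp] = str(exc)
            continue
        vid = primary.provenance[1] if primary.provenance else "rep"
        results[sp] = res
        pools1.per_species[sp] = {vid: _carry_provenance(ens1, sp, vid)}
        pools2.per_species[sp] = {vid: _carry_provenance(ens2, sp, vid)}

    inter_set = final_set = None
    if len(results) >= 2:
        # intermediates/finals are by construction the rank-0 members of
        # their constrained ensembles
        def _rank0(pools, sp):
            species_pool = pools.per_species[sp]
            vid = next(iter(species_pool))
            return species_pool[vid][0]

        templates1 = {sp: _rank0(pools1, sp) for sp in results}
        templates2 = {sp: _rank0(pools2, sp) for sp in results}
        inter_set = consensus_over_pools(templates1, pools1, cache)
        final_set = consensus_over_pools(templates2, pools2, cache)
    return PathwayConsensus(per_species=results, failed_species=failed,
                            intermediate_set=inter_set, final_set=final_set)
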