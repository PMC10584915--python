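"""Ground-truth synthetic pre-snRNA families.

Real pre-snRNA variant sets comprise, per species, several genomic gene
copies of one snRNA: a conserved single-stranded U-rich Sm site near the
3' end, helices diverging under compensatory (covariation-preserving)
substitutions, a 3' extension, and contaminating gene fragments and
Sm-less copies.  This module builds families with a *planted* secondary
structure — a stable G-C flanking hairpin plus a marginally stable
A-U/G-U helix (the Near Sm-site Structure) drawing the 3' portion of the
Sm site into its stem — verified at generation to be the built-in-model
MFE, then evolves homologs from it.  Every pipeline stage can therefore
be scored against known ground truth without any database access.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import fold
from .structio import (
    SecondaryStructure, SequenceRecord, VariantSet, find_sm_site,
    pairs_to_dotbracket, parse_dotbracket, LEGAL_PAIRS,
)

SM_SEQUENCE = "AUUUUUG"

#: legal pair choices for compensatory substitution
_PAIR_CHOICES = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
#: A-U/G-U-type pairs for the NSS stem, (5' base, 3' base); Watson-Crick
#: A-U dominates with occasional wobble, as in U-rich snRNA stems — weak
#: enough to rank least stable, cohesive enough to survive compensatory
#: divergence
_WEAK_PAIR_CHOICES = [("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]
_WEAK_PAIR_WEIGHTS = [0.4, 0.4, 0.1, 0.1]
#: partners that keep a fixed 3' base legally paired
_PARTNER_OF = {"A": ["U"], "C": ["G"], "G": ["C", "U"], "U": ["A", "G"]}


def _ac_fill(rng: np.random.Generator, n: int) -> str:
    """A/C filler: A and C cannot pair with each other, so filler regions
    never nucleate helices."""
    return "".join(rng.choice(["A", "C"], size=n))


def make_nss_template(stem_len: int = 8, loop_len: int = 4, sm_overlap: int = 3,
                      gc_flanks: bool = True, seed: int = 0,
                      ext_len: int = 6, max_attempts: int = 60,
                      ) -> tuple[str, str, tuple[int, int]]:
    """Build a sequence with a planted NSS and return (seq, struct, sm).

    The Sm site AUUUUUG is placed so that its 3' ``sm_overlap``
    nucleotides pair into an A-U/G-U stem of ``stem_len`` pairs (the
    NSS), with the rest of the motif in the NSS loop; a G-C hairpin
    upstream provides a stable structural anchor.  The returned structure
    is verified to be the built-in-model MFE of the sequence (random
    fillers are redrawn until it is).
    """
    if stem_len < 2:
        raise ValueError("stem_len must be >= 2")
    if not (0 <= sm_overlap <= min(stem_len, len(SM_SEQUENCE) - 1)):
        raise ValueError("sm_overlap must leave at least one Sm nucleotide in the loop")
    loop_needed = len(SM_SEQUENCE) - sm_overlap
    loop_total = max(loop_len, loop_needed, 3)
    rng = np.random.default_rng(seed)

    for _attempt in range(max_attempts):
        parts: list[str] = []
        pairs: list[tuple[int, int]] = []
        pos = 0

        def emit(s: str) -> int:
            nonlocal pos
            parts.append(s)
            start = pos
            pos += len(s)
            return start

        emit(_ac_fill(rng, 3))  # 5' leader
        if gc_flanks:
            g_len = 6
            arm5 = "".join(rng.choice(["G", "C"], size=g_len))
            arm3 = "".join({"G": "C", "C": "G"}[c] for c in reversed(arm5))
            a5 = emit(arm5)
            emit(_ac_fill(rng, 4))  # hairpin loop
            a3 = emit(arm3)
            for t in range(g_len):
                pairs.append((a5 + t, a3 + g_len - 1 - t))
            emit(_ac_fill(rng, 4))  # linker

        # NSS: 5' arm, loop (pad + Sm 5' part), 3' arm (Sm 3' part first).
        # The root pair is a G-C clamp pinning the helix register, as in
        # natural weak stems; the body is heterogeneous A-U with occasional
        # wobble, so the helix stays clearly the least stable one.
        arm3_bases = []
        arm5_bases = [""] * stem_len
        for idx in range(stem_len):
            if idx < sm_overlap:
                b3 = SM_SEQUENCE[len(SM_SEQUENCE) - sm_overlap + idx]
                b5 = str(rng.choice(_PARTNER_OF[b3]))
            elif idx == stem_len - 1:
                b5, b3 = ("G", "C") if rng.random() < 0.5 else ("C", "G")
            else:
                b5, b3 = _WEAK_PAIR_CHOICES[
                    rng.choice(len(_WEAK_PAIR_CHOICES), p=_WEAK_PAIR_WEIGHTS)]
            arm3_bases.append(b3)
            arm5_bases[stem_len - 1 - idx] = b5
        n5 = emit("".join(arm5_bases))
        pad = _ac_fill(rng, loop_total - loop_needed)
        emit(pad)
        sm_start = emit(SM_SEQUENCE[: len(SM_SEQUENCE) - sm_overlap])
        n3 = emit("".join(arm3_bases))
        for t in range(stem_len):
            pairs.append((n5 + t, n3 + stem_len - 1 - t))
        emit(_ac_fill(rng, ext_len))  # 3' extension stand-in

        seq = "".join(parts)
        struct = pairs_to_dotbracket(sorted(pairs), len(seq))
        sm = (sm_start, sm_start + len(SM_SEQUENCE))
        try:
            planted = SecondaryStructure(seq, struct)
        except ValueError:
            continue
        found = find_sm_site(seq)
        if found is None or found[0] != sm[0]:
            continue
        if fold.mfe(seq).dotbracket == struct:
            return seq, struct, sm
    raise RuntimeError(
        "could not construct a template whose planted structure is the MFE; "
        "try different stem/loop lengths"
    )


def mutate_homolog(seq: str, struct: str, divergence: float, compensatory_prob: float,
                   rng, sm: Optional[tuple[int, int]] = None) -> str:
    """Substitute each non-Sm position with probability ``divergence``.

    Substitutions at paired positions are compensated with probability
    ``compensatory_prob``: the new base is drawn so the pair stays legal,
    adjusting the partner when needed (never touching the Sm site — when
    the partner is inside the Sm interval the mutated side is drawn from
    the partners of the fixed Sm base).  No indels.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    bases = list(seq)
    pt = [-1] * len(seq)
    for i, j in parse_dotbracket(struct):
        pt[i] = j
        pt[j] = i
    sm_range = range(*sm) if sm else range(0)
    for i in range(len(bases)):
        if i in sm_range:
            continue
        if rng.random() >= divergence:
            continue
        j = pt[i]
        if j == -1:
            choices = [b for b in "ACGU" if b != bases[i]]
            bases[i] = str(rng.choice(choices))
        elif rng.random() < compensatory_prob:
            if sm and j in sm_range:
                options = [b for b in _PARTNER_OF[bases[j]] if b != bases[i]]
                if options:
                    bases[i] = str(rng.choice(options))
            else:
                options = [pq for pq in _PAIR_CHOICES if pq != (bases[i], bases[j])] \
                    if i < j else \
                    [pq for pq in _PAIR_CHOICES if pq != (bases[j], bases[i])]
                b5, b3 = options[rng.integers(len(options))]
                if i < j:
                    bases[i], bases[j] = b5, b3
                else:
                    bases[j], bases[i] = b5, b3
        else:
            choices = [b for b in "ACGU" if b != bases[i]]
            bases[i] = str(rng.choice(choices))
    return "".join(bases)


@dataclass
class SimConfig:
    """Study conditions for one simulated homolog family."""

    template_seq: str
    template_struct: str
    sm: tuple[int, int]
    n_species: int = 6
    variants_per_species: tuple[int, int] = (3, 3)
    divergence: float = 0.05            # interspecies substitution rate per site
    intra_divergence: float = 0.01      # gene-copy divergence within a species
    compensatory_prob: float = 0.9
    decoy_fragment_rate: float = 0.15   # truncated gene fragments per variant slot
    decoy_smless_rate: float = 0.10     # Sm-degenerate copies per variant slot
    fragment_fraction: float = 0.6      # decoy length as fraction of full length
    rna_name: str = "U2"
    seed: int = 0

    def __post_init__(self):
        for p in (self.divergence, self.intra_divergence, self.compensatory_prob,
                  self.decoy_fragment_rate, self.decoy_smless_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        SecondaryStructure(self.template_seq, self.template_struct)  # validates

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "SimConfig":
        seq, struct, sm = make_nss_template(seed=seed)
        return cls(template_seq=seq, template_struct=struct, sm=sm, seed=seed,
                   **overrides)


@dataclass
class SimulatedFamily:
    variant_set: VariantSet
    ground_truth: dict[str, SecondaryStructure]   # per-species planted structure
    sm: tuple[int, int]
    nss_pairs: tuple[tuple[int, int], ...]
    decoy_ids: dict[str, list[str]] = field(default_factory=dict)
    config: Optional[SimConfig] = None


def _nss_pairs_of(struct: str, sm: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    pairs = parse_dotbracket(struct)
    # NSS pairs: those whose enclosed span intersects the Sm interval
    out = [p for p in pairs if p[0] <= sm[1] - 1 and p[1] >= sm[0]]
    return tuple(sorted(out))


def _smless(rng: np.random.Generator, seq: str, sm: tuple[int, int]) -> str:
    """Degrade the Sm site (and any residual U-run motif) to A/C filler."""
    cand = list(seq)
    cand[sm[0]: sm[1]] = _ac_fill(rng, sm[1] - sm[0])
    for _ in range(20):
        m = find_sm_site("".join(cand))
        if m is None:
            return "".join(cand)
        cand[m[0]: m[1]] = _ac_fill(rng, m[1] - m[0])
    raise RuntimeError("could not scramble Sm site away")


def make_family(cfg: SimConfig, scramble_structure: bool = False) -> SimulatedFamily:
    """Generate one homolog family under the configured study conditions.

    Per species: a species-level homolog of the template, then
    ``variants_per_species`` gene copies at the (small) within-species
    divergence, plus decoy fragments and Sm-less copies at the configured
    rates.  With ``scramble_structure`` the non-Sm part of each species
    sequence is independently permuted first, destroying the shared
    planted structure while preserving composition — the negative control
    for conservation statistics.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    vs = VariantSet(rna_name=cfg.rna_name)
    truth: dict[str, SecondaryStructure] = {}
    decoys: dict[str, list[str]] = {}
    lo, hi = cfg.variants_per_species
    for s_idx in range(cfg.n_species):
        sp = f"sp{s_idx + 1:02d}"
        if scramble_structure:
            base_chars = np.array(list(cfg.template_seq))
            non_sm = np.array([k for k in range(len(base_chars))
                               if not cfg.sm[0] <= k < cfg.sm[1]])
            base_chars[non_sm] = base_chars[rng.permutation(non_sm)]
            species_base = "".join(base_chars)
        else:
            species_base = mutate_homolog(cfg.template_seq, cfg.template_struct,
                                          cfg.divergence, cfg.compensatory_prob,
                                          rng, cfg.sm)
        truth[sp] = _truth_structure(species_base, cfg)
        n_var = int(rng.integers(lo, hi + 1))
        records = []
        decoys[sp] = []
        for v in range(n_var):
            var_seq = mutate_homolog(species_base, cfg.template_struct,
                                     cfg.intra_divergence, cfg.compensatory_prob,
                                     rng, cfg.sm)
            records.append(SequenceRecord(id=f"v{v + 1}", species=sp,
                                          rna_name=cfg.rna_name, sequence=var_seq))
            if rng.random() < cfg.decoy_fragment_rate:
                frag_len = int(round(cfg.fragment_fraction * len(var_seq)))
                rid = f"fragment{v + 1}"
                records.append(SequenceRecord(id=rid, species=sp, rna_name=cfg.rna_name,
                                              sequence=var_seq[:frag_len]))
                decoys[sp].append(rid)
            if rng.random() < cfg.decoy_smless_rate:
                rid = f"smless{v + 1}"
                records.append(SequenceRecord(id=rid, species=sp, rna_name=cfg.rna_name,
                                              sequence=_smless(rng, var_seq, cfg.sm)))
                decoys[sp].append(rid)
        vs.per_species[sp] = records
    return SimulatedFamily(
        variant_set=vs, ground_truth=truth, sm=cfg.sm,
        nss_pairs=_nss_pairs_of(cfg.template_struct, cfg.sm),
        decoy_ids=decoys, config=cfg,
    )


def _truth_structure(species_seq: str, cfg: SimConfig) -> SecondaryStructure:
    """Planted topology on the species sequence; pairs broken by
    non-compensated substitutions are dropped from the truth."""
    kept = [(i, j) for i, j in parse_dotbracket(cfg.template_struct)
            if (species_seq[i], species_seq[j]) in LEGAL_PAIRS]
    return SecondaryStructure(species_seq,
                              pairs_to_dotbracket(kept, len(species_seq)))
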