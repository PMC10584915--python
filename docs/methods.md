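# Methods

This note documents the models, parameter choices and limitations of the
`presnrna` package in one place. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Folding engine

The built-in engine implements the standard loop-decomposition free
energy model in reduced form. A structure's energy is the sum over its
loops:

* **stacks** — a 6×6 table of stacking energies for the admissible pairs
  (A·U, C·G, G·C, G·U, U·A, U·G), Turner-like magnitudes for
  Watson–Crick-on-Watson–Crick steps (−0.9 to −3.4 kcal/mol) and weakly
  stabilizing wobble-on-wobble steps;
* **hairpin / bulge / internal loops** — length-indexed initiation
  penalties with Jacobson–Stockmayer logarithmic extrapolation
  (coefficient 1.08 kcal/mol) beyond the tabulated sizes; interior loops
  are capped at 30 unpaired nucleotides;
* **multiloops** — affine cost 3.4 + 0.4·branches kcal/mol, no
  per-unpaired-nucleotide term.

Omitted on purpose: sequence-dependent terminal mismatches and dangles,
special tetraloops, asymmetry penalties, lonely-pair prohibition and
pseudoknots. The model is intentionally small enough that exhaustive
enumeration with an independent loop-decomposition scorer can certify
the dynamic program exactly (the test suite does this for all random
sequences up to 14 nt); it is faithful enough that G-C helices are
strongly stable while A-U/G-U helices — the hallmark of the U-rich
region around the Sm site — are marginal.

Minimum hairpin size is 3; energies are handled internally as integer
hundredths of kcal/mol, so there is no floating-point tie ambiguity.

**MFE and suboptimal structures.** Matrices V (pair closed), M / M2
(multiloop regions with ≥1 / ≥2 branches) and W (exterior prefix) are
filled by an unambiguous grammar; suboptimal structures are enumerated
best-first from partial states whose bound (fixed energy + matrix values
of open targets) is the exact energy of their best completion. Each
structure is produced exactly once, in exact energy order; at equal
energy the final order is lexicographic in the dot-bracket string. The
default ensemble is at most 20 structures within 5 kcal/mol of the MFE —
the 20-structure cap is the binding parameter of the comparative
procedure, and the band default is a package choice exposed as
`--band`.

**Hard constraints.** 'x' forbids a position from pairing; matched
'(' ')' force a specific pair. Constraints enter the DP as admissibility
masks, so every enumerated structure satisfies them by construction; an
unsatisfiable constraint yields an empty list plus a warning.

**Backends.** The built-in engine is the default and the only one the
oracles certify. A `ViennaBackend` adapter (ViennaRNA python bindings,
Turner parameters) implements the same contract for users who want
production-grade thermodynamics; its availability is probed at call time
and its version logged.

## Tree edit distances

Structures map to rooted ordered trees ("full" representation: one `P`
node per pair, one `U` leaf per unpaired base, virtual root; a "coarse"
element-level representation is available for sensitivity checks).
Distances are Zhang–Shasha ordered tree edit distances with unit
insert/delete/relabel costs (relabel is free for equal labels). The DP
is verified against the exponential rightmost-root recursion for every
pair of dot-bracket shapes up to length 10. Conservation statistics
normalize d by the arithmetic mean of the two sequence lengths
(`--norm max|min` available); selection stages always use raw distances,
because within one RNA the lengths are nearly equal.

## Consensus selection

Per species i with m_i variants, every ensemble member is a candidate;
its score is the average over variants of the distance to the variant's
closest ensemble member (the candidate's own variant contributes 0). The
denominator is m_i; since any fixed denominator rescales all candidate
scores equally, the argmin — and hence the pipeline output — is
unaffected by the choice, and an override is exposed. Tie-breaks are
deterministic everywhere (score, then energy, then dot-bracket, then
species order), so reruns are byte-identical.

Cross-species: each species' representative anchors a set containing its
nearest structure from every other species' pool (the anchor's own pool
is never searched); the set minimizing the summed pairwise distance
wins. The same machinery is re-applied to the constrained ensembles of
the folding intermediates and final structures.

A property of this selection worth knowing: it favors the structural
*intersection* of the family. When every species' pool contains a
reduced version of a shared fold (likely for short toy sequences, where
20 structures nearly exhaust the ensemble), a single deviant species
pulls the consensus onto that reduced common denominator. At realistic
molecule sizes the top-20 ensembles are a vanishing fraction of the
structure space and this degeneracy is correspondingly rare.

## Sm-site opening pathway

* **Detection.** Helices are maximal runs of nested pairs in which
  single-nucleotide bulges do not interrupt the run (uridines bulging
  out of the NSS must not fragment it); candidates either have paired
  positions within the Sm interval ± 10 nt (`--nss-window`) or enclose
  Sm nucleotides in their loop; the candidate with maximal Sm overlap
  wins, ties going to the root closest to the Sm 5′ end.
* **Step 1 (folding intermediate).** For k = 0, 1, …: both partners of
  the k outermost NSS pairs are blocked ('x'), template pairs *outside*
  the NSS span are forced, and everything inside the span — including
  bulged-off sub-stems — is left free. The first k whose top-ranked
  refold leaves every Sm position unpaired is returned; minimality
  (k−1 fails) and monotonicity (larger k stays open) are asserted in the
  tests. Freeing the span, rather than forcing the unblocked NSS
  remainder, is what lets a weak stem deprived of its root stacking melt
  spontaneously — with the default synthetic templates this typically
  happens after one to four blocked pairs.
* **Step 2 (final structure).** The Sm motif plus 3 downstream
  nucleotides (`--sm-downstream`) are forced single-stranded, intermediate
  pairs are retained where legal, and the constrained MFE is returned.
* Species whose freed Sm site immediately re-pairs with partners outside
  the NSS take an explicit refusal path naming the still-paired
  positions and are excluded from the consensus sets.

## Conservation statistics

Clade similarity values are mean pairwise normalized distances; clades
are compared with the pooled-variance (equal-variance) two-sample
two-tailed t-test, df = n_a + n_b − 2 — the pooled form reproduces the
published clade-comparison p-values from the published table values to
four decimals, which a Welch test does not, and the implementation is
checked against an explicit pooled formula with the regularized
incomplete beta function at 1e-10 relative tolerance. Degenerate
zero-variance inputs: equal means give t = 0, p = 1; unequal means are
an error. Box-plot summaries use midpoint-interpolation quartiles and
1.5×IQR fences, with whiskers at the most extreme non-outlier points
(collapsing onto the quartiles when no point lies within the fences).

## SHAPE reactivities

High 2′-OH reactivity marks flexible, almost certainly unpaired
nucleotides: positions with reactivity ≥ 0.4 (`--shape-threshold`;
community convention) become 'x' constraints; missing values propagate
as unconstrained. Differential comparisons follow the windowed
convention of the established differential-SHAPE tools: 3-nt centered
smoothing of both the difference and the standard errors, a Z-factor
gate 1 − 1.96(σ_a + σ_b)/|Δ| > 0, an absolute standard score ≥ 1
against the transcript-wide difference distribution, and a region call
when ≥ 3 nucleotides in any 5-nt window pass both gates. Region calls
are symmetric in the two profiles.

## Synthetic data

The generator emulates per-species sets of snRNA gene copies:

* **Template** (`make_nss_template`): 5′ A/C leader, 6-bp G-C anchor
  hairpin, A/C linker, then the NSS — an 8-bp stem whose 3′ arm begins
  with the last 3 nucleotides of the AUUUUUG Sm site (so that a few Sm
  nucleotides are drawn into the stem, as observed in pre-snRNA folds),
  with a heterogeneous A-U-dominated body (~20% wobble) and a single
  G-C clamp at the root that pins the helix register, followed by an A/C
  3′ tail standing in for the precursor extension. A/C filler cannot
  base-pair with itself, so linkers never nucleate spurious helices. The
  planted structure is verified at generation to be the built-in-model
  MFE (fillers are redrawn until it is). Net stem stability ≈ −8
  kcal/mol versus ≈ −15 for the G-C anchor, so the NSS is always the
  least stable helix while surviving a realistic amount of divergence.
* **Divergence** (`mutate_homolog`): per-site substitution probability
  0.05 between species (snRNAs are highly conserved across Metazoa) and
  0.01 between gene copies within a species; substitutions at paired
  sites are compensated with probability 0.9 (the pair is re-drawn among
  legal pairs; when the partner lies in the untouchable Sm interval the
  mutated side is drawn from the Sm base's legal partners). The Sm site
  itself never mutates in non-decoy records, matching the assumption
  behind the Sm-site filter. No indels, so tree sizes stay comparable.
* **Decoys**: truncated fragments at 60% of full length (caught by the
  75%-of-average-length filter) at rate 0.15 per variant slot, and
  Sm-degenerate copies (the motif — and any residual U-run match —
  replaced by A/C filler) at rate 0.10.

What the generator does **not** emulate: phylogenetically structured
evolution (species are independent draws from the template), indels,
promoter/gene architecture, multiple competing NSS-like elements, or
molecules at natural snRNA length (~160–200 nt plus extension). Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under controlled divergence — not performance on database-scale inputs.

## Problem sizes

The shipped sweeps use templates of ~50 nt, 6 species × 3 variants,
20-seed recovery sweeps and 100-seed pathway/stability sweeps — sizes
chosen so the full suite and the acceptance script each complete in
minutes on one CPU while still exercising every stage end to end.

## Known limitations

* The reduced energy model is not Turner-2004-complete; absolute
  energies and ensembles differ from production engines (use the Vienna
  adapter when fidelity matters).
* Tree-edit conservation ignores phylogenetic relatedness; all species
  pairs weigh equally.
* The recovery sweep documents a scale artifact of min-sum consensus
  selection on short sequences (see "Consensus selection" above): at the
  default divergence a minority of seeds converge on the family's
  structural intersection rather than the full planted fold.
* The exact Sm-site and U1-70K motif definitions are configuration, not
  hard-coded truth (`--sm-pattern`; U1-70K patterns must be supplied per
  species).
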