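"""Sequence and structure I/O for pre-snRNA variant sets.

Spliceosomal snRNA genes occur in multiple copies per genome; many copies
are truncated fragments or have degenerate Sm sites.  This module reads
variant sets grouped by species from FASTA, applies the standard quality
filters (length fraction, Sm-site presence, optional U1-70K motif), builds
3'-extended precursor sequences from genomic context, and locates the
U-rich Sm site.

Coordinates are 0-based half-open internally; 1-based inclusive in files
and reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

RNA_ALPHABET = set("ACGU")

#: Watson-Crick plus wobble pairs admitted throughout the package.
LEGAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

#: Default 3' extension lengths (nt) per RNA, as found in human precursors.
DEFAULT_EXT_LEN = {"U1": 49, "U2": 21, "U4": 7, "U5": 48}

#: Default Sm-site motif: AUUUU core, greedy U-run, then G within 3 nt.
DEFAULT_SM_PATTERN = "AUUUU+.{0,2}G"

IUPAC_MAP = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


class ParseError(ValueError):
    pass


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U; reject anything outside {A,C,G,U}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ParseError(f"non-RNA characters after normalization: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    rna_name: str
    sequence: str
    source_coords: Optional[tuple] = None  # (contig, start, end, strand), 0-based half-open

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class VariantSet:
    rna_name: str
    per_species: dict[str, list[SequenceRecord]] = field(default_factory=dict)

    def __post_init__(self):
        for sp, recs in self.per_species.items():
            ids = [r.id for r in recs]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate record ids for species {sp!r}")
            for r in recs:
                if r.rna_name != self.rna_name:
                    raise ValueError(
                        f"record {r.id!r} has rna_name {r.rna_name!r}, expected {self.rna_name!r}"
                    )

    @property
    def species(self) -> list[str]:
        return sorted(self.per_species)

    @property
    def n_species(self) -> int:
        return len(self.per_species)

    def all_records(self) -> Iterable[SequenceRecord]:
        for sp in self.species:
            yield from self.per_species[sp]


# ---------------------------------------------------------------------------
# Secondary structures and constraints
# ---------------------------------------------------------------------------

def parse_dotbracket(dotbracket: str) -> list[tuple[int, int]]:
    """Return the (i, j) pair list (i < j) of a pseudoknot-free dot-bracket."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    db = ["."] * length
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence with one pseudoknot-free secondary structure.

    ``energy`` is the free energy in kcal/mol when known.  ``provenance``
    carries (species, variant id, rank in the suboptimal list) through the
    consensus stages.
    """

    sequence: str
    dotbracket: str
    energy: Optional[float] = None
    provenance: Optional[tuple] = None  # (species, variant_id, rank)

    min_hairpin = 3

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.dotbracket) != len(self.sequence):
            raise ValueError("dot-bracket length differs from sequence length")
        pairs = parse_dotbracket(self.dotbracket)  # validates nesting
        for i, j in pairs:
            if (self.sequence[i], self.sequence[j]) not in LEGAL_PAIRS:
                raise ValueError(
                    f"illegal base pair {self.sequence[i]}{i + 1}-{self.sequence[j]}{j + 1}"
                )
            if j - i - 1 < self.min_hairpin:
                raise ValueError(f"hairpin loop shorter than {self.min_hairpin} at pair ({i},{j})")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return parse_dotbracket(self.dotbracket)

    @property
    def pair_table(self) -> list[int]:
        """partner[i] = j if (i, j) or (j, i) paired, else -1."""
        pt = [-1] * len(self.sequence)
        for i, j in self.pairs:
            pt[i] = j
            pt[j] = i
        return pt

    def paired_positions(self, interval: tuple[int, int]) -> list[int]:
        """Positions inside [start, end) that are base-paired."""
        pt = self.pair_table
        return [k for k in range(*interval) if pt[k] != -1]

    def __len__(self) -> int:
        return len(self.sequence)


CONSTRAINT_CHARS = set(".x()")


@dataclass(frozen=True)
class ConstraintSpec:
    """Hard folding constraints: '.' free, 'x' forbidden from pairing,
    matched '(' / ')' a forced pair."""

    symbols: str

    def __post_init__(self):
        bad = set(self.symbols) - CONSTRAINT_CHARS
        if bad:
            raise ValueError(f"illegal constraint characters: {sorted(bad)}")
        parse_dotbracket(self.symbols.replace("x", "."))  # validates nesting

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def forced_pairs(self) -> list[tuple[int, int]]:
        return parse_dotbracket(self.symbols.replace("x", "."))

    @property
    def blocked(self) -> set[int]:
        return {i for i, c in enumerate(self.symbols) if c == "x"}

    def validate_for(self, sequence: str) -> None:
        if len(self.symbols) != len(sequence):
            raise ValueError("constraint length differs from sequence length")
        for i, j in self.forced_pairs:
            if (sequence[i], sequence[j]) not in LEGAL_PAIRS:
                raise ValueError(f"forced pair ({i + 1},{j + 1}) is not complementary")

    def satisfied_by(self, s: SecondaryStructure) -> bool:
        pt = s.pair_table
        for i, c in enumerate(self.symbols):
            if c == "x" and pt[i] != -1:
                return False
        forced = set(self.forced_pairs)
        return forced <= set(s.pairs)

    @classmethod
    def free(cls, length: int) -> "ConstraintSpec":
        return cls("." * length)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path, delimiter: str = "|") -> VariantSet:
    """Read a variant set from FASTA with ``species|rna|id`` headers.

    T is converted to U and lowercase uppercased.  All records must share
    one rna_name.
    """
    per_species: dict[str, list[SequenceRecord]] = {}
    rna_name = None
    n = 0
    for line_rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        fields = line_rec.id.split(delimiter)
        if len(fields) < 3:
            raise ParseError(
                f"malformed FASTA header {line_rec.id!r}: expected "
                f"'species{delimiter}rna{delimiter}id'"
            )
        species, rna, vid = fields[0], fields[1], delimiter.join(fields[2:])
        if rna_name is None:
            rna_name = rna
        elif rna != rna_name:
            raise ParseError(f"mixed rna names in one file: {rna_name!r} vs {rna!r}")
        rec = SequenceRecord(id=vid, species=species, rna_name=rna, sequence=str(line_rec.seq))
        per_species.setdefault(species, []).append(rec)
    if n == 0:
        raise ParseError(f"no FASTA records in {path}")
    return VariantSet(rna_name=rna_name, per_species=per_species)


def write_fasta(vs: VariantSet, path, delimiter: str = "|") -> None:
    recs = [
        _BioSeqRecord(Seq(r.sequence), id=delimiter.join([r.species, r.rna_name, r.id]),
                      description="")
        for r in vs.all_records()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_dotbracket(path) -> list[SecondaryStructure]:
    """Read a Vienna-style multi-record dot-bracket file.

    Each record: a ``>header`` line, a sequence line, and one or more
    structure lines with an optional trailing ``(-3.40)`` energy.
    """
    structures = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ParseError(f"expected '>' header at line {i + 1} of {path}")
        seq = lines[i + 1]
        i += 2
        while i < len(lines) and not lines[i].startswith(">"):
            m = re.match(r"^([.()]+)(?:\s+\(\s*(-?\d+\.?\d*)\))?\s*$", lines[i])
            if not m:
                raise ParseError(f"malformed structure line {i + 1} of {path}")
            energy = float(m.group(2)) if m.group(2) is not None else None
            structures.append(SecondaryStructure(seq, m.group(1), energy=energy))
            i += 1
    return structures


def write_dotbracket(structures: list[SecondaryStructure], path, names=None) -> None:
    with open(path, "w") as fh:
        for k, s in enumerate(structures):
            name = names[k] if names else f"structure_{k + 1}"
            fh.write(f">{name}\n{s.sequence}\n{s.dotbracket}")
            if s.energy is not None:
                fh.write(f" ({s.energy:.2f})")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    short: int = 0
    no_sm: int = 0
    no_u1_70k: int = 0
    dropped_species: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "short": self.short,
            "no_sm": self.no_sm,
            "no_u1_70k": self.no_u1_70k,
            "dropped_species": list(self.dropped_species),
        }


def iupac_to_regex(pattern: str) -> str:
    """Expand IUPAC ambiguity codes; regex metacharacters pass through."""
    out = []
    for c in pattern.upper():
        out.append(IUPAC_MAP.get(c, c))
    return "".join(out)


def find_sm_site(seq: str, pattern: str = DEFAULT_SM_PATTERN) -> Optional[tuple[int, int]]:
    """Locate the 3'-most Sm-site match; 0-based half-open interval or None.

    Sm sites sit near the snRNA 3' end, so when a degenerate motif matches
    more than once the 3'-most occurrence is the biologically meaningful
    one.
    """
    rx = re.compile(iupac_to_regex(pattern))
    best = None
    for m in rx.finditer(normalize_rna(seq)):
        best = (m.start(), m.end())
    return best


def filter_variants(
    vs: VariantSet,
    min_len_frac: float = 0.75,
    sm_pattern: str = DEFAULT_SM_PATTERN,
    require_u1_70k: bool = False,
    u1_70k_pattern: Optional[str] = None,
) -> tuple[VariantSet, FilterReport]:
    """Remove gene fragments and Sm-less variants.

    A record is dropped when shorter than ``min_len_frac`` of the average
    length of ALL input records of this RNA (pooled across species, before
    any removal), when it lacks a complete Sm site, or — with
    ``require_u1_70k`` — when it lacks the U1-70K binding motif.  Filtering
    is idempotent.
    """
    records = list(vs.all_records())
    if not records:
        raise ValueError("empty variant set")
    avg_len = sum(len(r) for r in records) / len(records)
    report = FilterReport(n_input=len(records))

    kept: dict[str, list[SequenceRecord]] = {}
    for sp in vs.species:
        kept_sp = []
        for rec in vs.per_species[sp]:
            if len(rec) < min_len_frac * avg_len:
                report.short += 1
                continue
            if find_sm_site(rec.sequence, sm_pattern) is None:
                report.no_sm += 1
                continue
            if require_u1_70k:
                if u1_70k_pattern is None:
                    raise ValueError("require_u1_70k set but no u1_70k_pattern given")
                if re.search(iupac_to_regex(u1_70k_pattern), rec.sequence) is None:
                    report.no_u1_70k += 1
                    continue
            kept_sp.append(rec)
        if kept_sp:
            kept[sp] = kept_sp
        else:
            report.dropped_species.append(sp)
    report.n_retained = sum(len(v) for v in kept.values())
    return VariantSet(rna_name=vs.rna_name, per_species=kept), report


def extend_3prime(rec: SequenceRecord, genomic_context: str, ext_len: int) -> SequenceRecord:
    """Append the first ``ext_len`` nt of the downstream genomic context.

    ``genomic_context`` must start at the nucleotide immediately 3' of the
    mature end and already be sense-strand.
    """
    if ext_len < 0:
        raise ValueError("ext_len must be >= 0")
    context = normalize_rna(genomic_context) if genomic_context else ""
    if len(context) < ext_len:
        raise ValueError(
            f"genomic context ({len(context)} nt) shorter than requested extension ({ext_len} nt)"
        )
    if ext_len == 0:
        return rec
    return replace(rec, sequence=rec.sequence + context[:ext_len])
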