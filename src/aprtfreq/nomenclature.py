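"""HGVS variant nomenclature for the *APRT* gene.

Parses, validates and round-trips the cDNA (``c.``) and protein (``p.``)
descriptions that occur in curated registries of pathogenic *APRT* alleles
(transcript NM_000485.2; a 543-nt coding sequence encoding a 180-residue
protein plus stop). This is deliberately not a full HGVS implementation:
only the constructs needed for this gene's published variant spectrum are
supported — substitutions (with intronic offsets), duplications, deletions
(single position or range), insertions and delins.

Parsed values format back to their source string byte-for-byte after
whitespace normalisation, so registries can be validated by round-trip.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "CDS_LENGTH",
    "PROTEIN_LENGTH",
    "HgvsParseError",
    "CodingRangeWarning",
    "EditType",
    "CdnaChange",
    "ProteinAltKind",
    "ProteinChange",
    "Consequence",
    "Region",
    "Variant",
    "parse_cdna",
    "parse_protein",
    "parse_region",
    "classify",
    "format_variant",
]

#: Coding-sequence length of NM_000485.2 (180 codons + stop).
CDS_LENGTH = 543
#: Protein positions run 1..180 plus the stop codon at 181.
PROTEIN_LENGTH = 181
#: The gene has five exons; region indices are restricted accordingly.
N_EXONS = 5

AMINO_ACIDS_3 = frozenset(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)


class HgvsParseError(ValueError):
    """Malformed HGVS description; carries the offending token."""

    def __init__(self, text: str, token: str, message: str):
        self.text = text
        self.token = token
        super().__init__(f"cannot parse {text!r}: {message} (offending token: {token!r})")


class CodingRangeWarning(UserWarning):
    """Position lies outside the 1..543 coding span (not fatal)."""


class EditType(str, Enum):
    SUBSTITUTION = "substitution"
    DUPLICATION = "duplication"
    DELETION = "deletion"
    INSERTION = "insertion"
    DELINS = "delins"


def _fmt_coord(pos: int, offset: int) -> str:
    if offset == 0:
        return str(pos)
    return f"{pos}{offset:+d}"


@dataclass(frozen=True)
class CdnaChange:
    """A parsed ``c.`` description.

    Coordinates are 1-based cDNA positions on NM_000485.2; ``start_offset``
    is the signed intronic offset (0 for exonic positions). Range edits
    (e.g. ``c.521_523del``) carry ``end_pos``/``end_offset``.
    """

    raw: str
    start_pos: int
    start_offset: int
    edit: EditType
    end_pos: Optional[int] = None
    end_offset: Optional[int] = None
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    inserted: Optional[str] = None  # dup/del annotated seq, or ins/delins payload

    def __post_init__(self) -> None:
        if self.start_pos < 1:
            raise HgvsParseError(self.raw, str(self.start_pos), "cDNA position must be >= 1")
        if self.end_pos is not None:
            if (self.end_pos, self.end_offset or 0) < (self.start_pos, self.start_offset):
                raise HgvsParseError(self.raw, f"{self.end_pos}", "range end precedes start")
        if self.edit is EditType.SUBSTITUTION:
            for b in (self.ref_base, self.alt_base):
                if b not in {"A", "C", "G", "T"}:
                    raise HgvsParseError(self.raw, str(b), "substitution bases must be single nucleotides")
            if self.ref_base == self.alt_base:
                raise HgvsParseError(self.raw, f"{self.ref_base}>{self.alt_base}", "ref and alt are identical")

    @property
    def is_intronic(self) -> bool:
        return self.start_offset != 0 or bool(self.end_offset)

    def span_length(self) -> Optional[int]:
        """Number of reference positions touched by a range edit (None if offsets make it undefined)."""
        if self.end_pos is None:
            return 1
        if self.start_offset or self.end_offset:
            return None
        return self.end_pos - self.start_pos + 1

    def format(self) -> str:
        coord = _fmt_coord(self.start_pos, self.start_offset)
        if self.end_pos is not None:
            coord += "_" + _fmt_coord(self.end_pos, self.end_offset or 0)
        if self.edit is EditType.SUBSTITUTION:
            tail = f"{self.ref_base}>{self.alt_base}"
        elif self.edit is EditType.DUPLICATION:
            tail = "dup" + (self.inserted or "")
        elif self.edit is EditType.DELETION:
            tail = "del" + (self.inserted or "")
        elif self.edit is EditType.INSERTION:
            tail = "ins" + (self.inserted or "")
        else:
            tail = "delins" + (self.inserted or "")
        return f"c.{coord}{tail}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


_COORD = r"(\d+)([+-]\d+)?"
_CDNA_RE = re.compile(
    rf"^c\.{_COORD}(?:_{_COORD})?"
    r"(?:(?P<sub>[ACGT]>[ACGT])"
    r"|(?P<delins>del[ACGT]*ins[ACGT]+)"
    r"|dup(?P<dup>[ACGT]*)"
    r"|del(?P<del>[ACGT]*)"
    r"|ins(?P<ins>[ACGT]+))$"
)


def parse_cdna(text: str) -> CdnaChange:
    """Parse an HGVS cDNA description such as ``c.194A>T`` or ``c.400+2dup``.

    Internal whitespace is stripped first (the literature prints both
    ``c.400+2dup`` and ``c.400 + 2dup``). Positions outside the 1..543
    coding span raise :class:`CodingRangeWarning` but still parse, since
    intronic offsets and the stop codon are legitimate.
    """
    norm = re.sub(r"\s+", "", text)
    if not norm.startswith("c."):
        raise HgvsParseError(text, norm[:2], "expected 'c.' prefix")
    m = _CDNA_RE.match(norm)
    if m is None:
        raise HgvsParseError(text, norm[2:], "unrecognised cDNA syntax")
    start_pos = int(m.group(1))
    start_offset = int(m.group(2) or 0)
    end_pos = int(m.group(3)) if m.group(3) else None
    end_offset = int(m.group(4)) if m.group(4) else (0 if end_pos is not None else None)

    if m.group("sub"):
        ref, alt = m.group("sub").split(">")
        change = CdnaChange(norm, start_pos, start_offset, EditType.SUBSTITUTION,
                            end_pos, end_offset, ref_base=ref, alt_base=alt)
    elif m.group("delins"):
        deleted, ins = m.group("delins")[3:].split("ins")
        change = CdnaChange(norm, start_pos, start_offset, EditType.DELINS,
                            end_pos, end_offset, inserted=ins)
    elif m.group("dup") is not None:
        change = CdnaChange(norm, start_pos, start_offset, EditType.DUPLICATION,
                            end_pos, end_offset, inserted=m.group("dup") or None)
    elif m.group("del") is not None:
        change = CdnaChange(norm, start_pos, start_offset, EditType.DELETION,
                            end_pos, end_offset, inserted=m.group("del") or None)
    else:
        change = CdnaChange(norm, start_pos, start_offset, EditType.INSERTION,
                            end_pos, end_offset, inserted=m.group("ins"))

    for pos in (start_pos, end_pos):
        if pos is not None and pos > CDS_LENGTH:
            warnings.warn(
                f"{norm}: position {pos} outside the 1..{CDS_LENGTH} coding span",
                CodingRangeWarning, stacklevel=2,
            )
    return change


class ProteinAltKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_DEL = "inframe_del"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ProteinChange:
    """A parsed ``p.(...)`` description (predicted consequence notation)."""

    raw: str
    ref_residue: str  # 3-letter code, or "*" for the stop codon
    position: int
    kind: ProteinAltKind
    alt_residue: Optional[str] = None  # new residue (missense / first changed of frameshift / stop-loss readthrough)
    stop_distance: Optional[int] = None  # frameshift: codons to the new stop; None = unknown

    def __post_init__(self) -> None:
        if not (1 <= self.position <= PROTEIN_LENGTH):
            raise HgvsParseError(self.raw, str(self.position),
                                 f"residue position must lie in 1..{PROTEIN_LENGTH}")

    def format(self) -> str:
        if self.kind is ProteinAltKind.START_LOSS:
            return "p.(Met1?)"
        if self.kind is ProteinAltKind.STOP_LOSS:
            return f"p.(*{self.position}{self.alt_residue}ext*?)"
        core = f"{self.ref_residue}{self.position}"
        if self.kind is ProteinAltKind.MISSENSE:
            core += self.alt_residue or ""
        elif self.kind is ProteinAltKind.NONSENSE:
            core += "*"
        elif self.kind is ProteinAltKind.FRAMESHIFT:
            stop = "?" if self.stop_distance is None else str(self.stop_distance)
            core += f"{self.alt_residue}fs*{stop}"
        elif self.kind is ProteinAltKind.INFRAME_DEL:
            core += "del"
        return f"p.({core})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


_AA = r"[A-Z][a-z]{2}"
_PROTEIN_PATTERNS = [
    (re.compile(r"^Met1\?$"), ProteinAltKind.START_LOSS),
    (re.compile(rf"^\*(\d+)({_AA})ext\*\?$"), ProteinAltKind.STOP_LOSS),
    (re.compile(rf"^({_AA})(\d+)({_AA})fs\*(\d+|\?)$"), ProteinAltKind.FRAMESHIFT),
    (re.compile(rf"^({_AA})(\d+)\*$"), ProteinAltKind.NONSENSE),
    (re.compile(rf"^({_AA})(\d+)del$"), ProteinAltKind.INFRAME_DEL),
    (re.compile(rf"^({_AA})(\d+)({_AA})$"), ProteinAltKind.MISSENSE),
]


def _check_aa(raw: str, code: str) -> str:
    if code not in AMINO_ACIDS_3:
        raise HgvsParseError(raw, code, "unknown 3-letter amino-acid code")
    return code


def parse_protein(text: str) -> ProteinChange:
    """Parse an HGVS protein description such as ``p.(Asp65Val)`` or ``p.(Ala108Glufs*3)``."""
    norm = re.sub(r"\s+", "", text)
    if not (norm.startswith("p.(") and norm.endswith(")")):
        raise HgvsParseError(text, norm[:3], "expected 'p.(' ... ')' wrapper")
    inner = norm[3:-1]
    for pattern, kind in _PROTEIN_PATTERNS:
        m = pattern.match(inner)
        if m is None:
            continue
        if kind is ProteinAltKind.START_LOSS:
            return ProteinChange(norm, "Met", 1, kind)
        if kind is ProteinAltKind.STOP_LOSS:
            return ProteinChange(norm, "*", int(m.group(1)), kind,
                                 alt_residue=_check_aa(norm, m.group(2)))
        ref = _check_aa(norm, m.group(1))
        pos = int(m.group(2))
        if kind is ProteinAltKind.FRAMESHIFT:
            stop = None if m.group(4) == "?" else int(m.group(4))
            return ProteinChange(norm, ref, pos, kind,
                                 alt_residue=_check_aa(norm, m.group(3)), stop_distance=stop)
        if kind is ProteinAltKind.MISSENSE:
            return ProteinChange(norm, ref, pos, kind, alt_residue=_check_aa(norm, m.group(3)))
        return ProteinChange(norm, ref, pos, kind)
    raise HgvsParseError(text, inner, "unrecognised protein syntax")


class Consequence(str, Enum):
    """Systematic molecular consequence, computed from the parsed change.

    Registries sometimes print looser labels ("Indel" for a splice-donor
    duplication, "Nonsense" for a start-loss); those are preserved verbatim
    on :class:`Variant` as ``printed_label`` while this enum carries the
    systematic class used by all logic.
    """

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"
    SPLICE_REGION = "splice_region"
    OTHER = "other"


def classify(cdna: CdnaChange, protein: Optional[ProteinChange] = None) -> Consequence:
    """Deterministic systematic consequence class.

    A change at the canonical splice dinucleotide (intronic offset of
    magnitude 1 or 2) is splice_region regardless of the annotated protein
    effect; deeper intronic changes (e.g. an offset of -3) are not. Protein
    tags decide the exonic classes; an in-frame deletion/duplication with no
    frameshift falls to inframe_indel. Anything unresolvable is ``other``.
    """
    offsets = [cdna.start_offset]
    if cdna.end_offset:
        offsets.append(cdna.end_offset)
    if any(1 <= abs(o) <= 2 for o in offsets if o):
        return Consequence.SPLICE_REGION
    if protein is not None:
        mapping = {
            ProteinAltKind.FRAMESHIFT: Consequence.FRAMESHIFT,
            ProteinAltKind.NONSENSE: Consequence.NONSENSE,
            ProteinAltKind.START_LOSS: Consequence.START_LOSS,
            ProteinAltKind.STOP_LOSS: Consequence.STOP_LOSS,
            ProteinAltKind.MISSENSE: Consequence.MISSENSE,
            ProteinAltKind.INFRAME_DEL: Consequence.INFRAME_INDEL,
        }
        if protein.kind in mapping:
            return mapping[protein.kind]
    if cdna.edit in (EditType.DELETION, EditType.DUPLICATION):
        span = cdna.span_length()
        if span is not None and span % 3 == 0:
            return Consequence.INFRAME_INDEL
    return Consequence.OTHER


_REGION_RE = re.compile(r"^(Exon|Intron)\s*(\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class Region:
    """Gene region: one of the five exons or four introns."""

    kind: str  # "exon" | "intron"
    index: int

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"region kind must be exon/intron, got {self.kind!r}")
        if not 1 <= self.index <= N_EXONS:
            raise ValueError(f"region index must lie in 1..{N_EXONS}, got {self.index}")

    def format(self) -> str:
        return f"{self.kind.capitalize()} {self.index}"


def parse_region(text: str) -> Region:
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise HgvsParseError(text, text, "expected 'Exon N' or 'Intron N'")
    return Region(m.group(1).lower(), int(m.group(2)))


@dataclass(frozen=True)
class Variant:
    """One pathogenic *APRT* allele as curated in a registry."""

    variant_id: str
    cdna: CdnaChange
    protein: Optional[ProteinChange]
    region: Region
    consequence: Consequence
    printed_label: str = ""
    build38_pos: Optional[str] = None  # opaque "16:<pos>" GRCh38 coordinate
    genomic_ref: Optional[str] = None  # explicit plus-strand alleles for VCF export;
    genomic_alt: Optional[str] = None  # never derived from the cDNA (reverse-strand gene)

    def __post_init__(self) -> None:
        # An intronic region label must coincide with a nonzero cDNA offset.
        if (self.region.kind == "intron") != self.cdna.is_intronic:
            raise ValueError(
                f"{self.variant_id}: region {self.region.format()!r} inconsistent "
                f"with cDNA offset {self.cdna.start_offset:+d}"
            )
        if self.build38_pos is not None and not re.match(r"^16:\d+$", self.build38_pos):
            raise ValueError(f"{self.variant_id}: build38_pos must look like '16:<int>'")


def format_variant(v: Variant) -> str:
    """Canonical display string: ``c.194A>T (p.(Asp65Val))``, or the cDNA alone."""
    if v.protein is None:
        return v.cdna.format()
    return f"{v.cdna.format()} ({v.protein.format()})"
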