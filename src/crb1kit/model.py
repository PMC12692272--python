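"""Gene model and variant nomenclature for the three CRB1 transcripts.

CRB1 (chromosome 1q31.3) is expressed in the human retina as three major
transcripts: the canonical 12-exon CRB1-A, the photoreceptor-enriched
CRB1-B, and the short secreted-like CRB1-C.  Exon numbering throughout this
package is the canonical CRB1-A numbering, 1..12, with exon 6 the single
exon shared by all three transcripts.

This module parses the restricted HGVS-like coding nomenclature used in
clinical variant tables (substitutions, deletions, duplications, delins),
assigns a consequence class, and maps an exon to the set of transcripts
that contain it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Union

EXON_MIN = 1
EXON_MAX = 12
#: splice-site consequence is restricted to canonical +1..+3 (and -1..-3) offsets
MAX_SPLICE_OFFSET = 3
#: number of missense predictors consulted (VEP ensemble)
N_DAMAGING_PREDICTORS = 15
#: number of splice-prediction tools (SSF, MaxEnt, NNSPLICE, GeneSplicer)
N_SPLICE_TOOLS = 4


class VariantParseError(ValueError):
    """Raised when a cDNA string cannot be parsed."""


class ClassificationError(ValueError):
    """Raised on contradictory or insufficient evidence for a consequence class."""


class UnsupportedVariantError(ValueError):
    """Raised for variants outside the supported nomenclature (e.g. deep-intronic)."""


class DomainError(ValueError):
    """Raised when a value falls outside its biological domain (e.g. exon 13)."""


class ConsequenceClass(str, Enum):
    TRUNCATING = "truncating"
    MISSENSE = "missense"
    IN_FRAME = "in_frame"
    SPLICE_SITE = "splice_site"


class EditKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    DELINS = "delins"


# ---------------------------------------------------------------------------
# coordinates and descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingCoord:
    """A coding (c.) coordinate: position plus optional intronic offset.

    ``offset`` follows HGVS convention: ``+n`` counts into the downstream
    intron from the last exonic base, ``-n`` into the upstream intron.
    """

    position: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset:
            return f"{self.position}{self.offset:+d}"
        return str(self.position)


@dataclass(frozen=True)
class VariantDescriptor:
    """Structured form of one HGVS-like coding variant description."""

    raw_cdna: str
    start: CodingCoord
    end: Optional[CodingCoord]
    edit_kind: EditKind
    ref: str = ""
    alt: str = ""
    length: int = 1

    @property
    def coding_position(self) -> Union[int, tuple[int, int]]:
        if self.end is not None and self.end.position != self.start.position:
            return (self.start.position, self.end.position)
        return self.start.position

    @property
    def intronic_offset(self) -> Optional[int]:
        """The signed intronic offset, or None for a purely exonic change."""
        if self.start.offset:
            return self.start.offset
        if self.end is not None and self.end.offset:
            return self.end.offset
        return None

    def format(self) -> str:
        """Serialize back to HGVS-like text; round-trips with the parser."""
        span = str(self.start)
        if self.end is not None:
            span += f"_{self.end}"
        if self.edit_kind is EditKind.SUBSTITUTION:
            return f"c.{span}{self.ref}>{self.alt}"
        if self.edit_kind is EditKind.DELETION:
            return f"c.{span}del{self.ref}"
        if self.edit_kind is EditKind.DUPLICATION:
            return f"c.{span}dup{self.ref}"
        return f"c.{span}delins{self.alt}"


_COORD = r"(\d+)([+-]\d+)?"
_SUB_RE = re.compile(rf"^c\.{_COORD}([ACGT])>([ACGT])$")
_INDEL_RE = re.compile(
    rf"^c\.{_COORD}(?:_{_COORD})?(del(?:ins)?|dup)([ACGT]*)$"
)


def _parse_coord(pos: str, off: Optional[str]) -> CodingCoord:
    return CodingCoord(int(pos), int(off) if off else 0)


def _span_length(start: CodingCoord, end: Optional[CodingCoord]) -> Optional[int]:
    if end is None:
        return 1
    if start.offset == 0 and end.offset == 0:
        return end.position - start.position + 1
    if start.position == end.position:
        return end.offset - start.offset + 1
    return None  # span crosses an exon/intron boundary: length from the sequence


def parse_cdna_variant(raw: str) -> VariantDescriptor:
    """Parse an HGVS-like coding variant string.

    Supports the substitution / deletion / duplication / delins forms found
    in clinical tables, including intronic offsets (``c.4005+1G>A``,
    ``c.3749+2_3749+3delTG``).

    Raises
    ------
    VariantParseError
        For an empty or malformed string, naming the offending token.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise VariantParseError("empty variant string")
    raw = raw.strip()
    if not raw.startswith("c."):
        raise VariantParseError(f"variant must use coding ('c.') nomenclature: {raw!r}")

    m = _SUB_RE.match(raw)
    if m:
        pos, off, ref, alt = m.groups()
        return VariantDescriptor(
            raw_cdna=raw,
            start=_parse_coord(pos, off),
            end=None,
            edit_kind=EditKind.SUBSTITUTION,
            ref=ref,
            alt=alt,
            length=1,
        )

    m = _INDEL_RE.match(raw)
    if m:
        pos1, off1, pos2, off2, op, seq = m.groups()
        start = _parse_coord(pos1, off1)
        end = _parse_coord(pos2, off2) if pos2 else None
        span = _span_length(start, end)
        if op == "delins":
            if not seq:
                raise VariantParseError(f"delins without inserted sequence: {raw!r}")
            return VariantDescriptor(
                raw_cdna=raw, start=start, end=end,
                edit_kind=EditKind.DELINS, alt=seq, length=len(seq),
            )
        kind = EditKind.DELETION if op == "del" else EditKind.DUPLICATION
        if seq and span is not None and len(seq) != span:
            raise VariantParseError(
                f"stated sequence {seq!r} ({len(seq)} nt) does not match the "
                f"coordinate span of {span} nt in {raw!r}"
            )
        length = span if span is not None else len(seq)
        if length is None or length <= 0:
            raise VariantParseError(f"cannot determine edit length of {raw!r}")
        return VariantDescriptor(
            raw_cdna=raw, start=start, end=end,
            edit_kind=kind, ref=seq, length=length,
        )

    raise VariantParseError(f"unrecognized variant nomenclature: {raw!r}")


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

_AA3 = r"(?:[A-Z][a-z]{2})"
_MISSENSE_RE = re.compile(rf"^p\.{_AA3}\d+{_AA3}$")
_NONSENSE_RE = re.compile(rf"^p\.{_AA3}\d+(Ter|\*)$")
_FRAMESHIFT_RE = re.compile(rf"^p\.{_AA3}\d+{_AA3}?fs(Ter\d*|\*\d*)?$")
_INFRAME_RE = re.compile(rf"^p\.{_AA3}\d+(_{_AA3}\d+)?(del|dup)(?:{_AA3})*$")
_SPLICE_NOTE_RE = re.compile(r"^\(\s*splice\s*\)\s*", re.IGNORECASE)


def normalize_protein_change(protein_change: Optional[str]) -> tuple[Optional[str], bool]:
    """Strip placeholder/annotation decoration from a protein-change string.

    Returns ``(p_string_or_None, had_splice_note)``; clinical tables mark
    missense changes with predicted splice impact as ``(Splice) p.Xxx###Yyy``.
    """
    if protein_change is None:
        return None, False
    text = str(protein_change).strip()
    had_note = False
    if _SPLICE_NOTE_RE.match(text):
        had_note = True
        text = _SPLICE_NOTE_RE.sub("", text).strip()
    if text in {"", "-", "--", "."}:
        return None, had_note
    return text, had_note


def classify_consequence(
    descriptor: Optional[VariantDescriptor],
    protein_change: Optional[str] = None,
) -> ConsequenceClass:
    """Assign a consequence class from the cDNA descriptor and/or protein change.

    Canonical splice-site offsets (|offset| <= 3) dominate any protein
    annotation; a missense protein change combined with an intronic offset
    is contradictory and raises.  Frameshift (``fsTer``) and nonsense
    (``Ter``) protein changes are truncating; in-frame del/dup (length
    divisible by 3) are ``in_frame``; single-residue substitutions are
    ``missense``.  A missense variant with ancillary splice predictions
    (e.g. ``(Splice) p.Cys948Tyr``) stays missense — the splice evidence is
    consumed by the scoring rules, not the class.
    """
    protein, _ = normalize_protein_change(protein_change)
    if descriptor is None and protein is None:
        raise ClassificationError("no evidence: neither descriptor nor protein change")

    offset = descriptor.intronic_offset if descriptor is not None else None
    if offset is not None:
        if abs(offset) > MAX_SPLICE_OFFSET:
            raise UnsupportedVariantError(
                f"intronic offset {offset:+d} is outside the supported canonical "
                f"splice region (+/-1..{MAX_SPLICE_OFFSET})"
            )
        if protein is not None and _MISSENSE_RE.match(protein):
            raise ClassificationError(
                f"contradictory evidence: intronic offset {offset:+d} with "
                f"missense protein change {protein!r}"
            )
        return ConsequenceClass.SPLICE_SITE

    if protein is not None:
        if _FRAMESHIFT_RE.match(protein) or _NONSENSE_RE.match(protein):
            return ConsequenceClass.TRUNCATING
        if _INFRAME_RE.match(protein):
            if descriptor is not None and descriptor.length % 3 != 0:
                raise ClassificationError(
                    f"in-frame protein change {protein!r} with a {descriptor.length}-nt "
                    f"edit (not a multiple of 3)"
                )
            return ConsequenceClass.IN_FRAME
        if _MISSENSE_RE.match(protein):
            return ConsequenceClass.MISSENSE
        raise ClassificationError(f"unrecognized protein change {protein!r}")

    # nomenclature-only classification
    if descriptor.edit_kind in (EditKind.DELETION, EditKind.DUPLICATION):
        if descriptor.length % 3 == 0:
            return ConsequenceClass.IN_FRAME
        return ConsequenceClass.TRUNCATING
    raise ClassificationError(
        f"cannot classify exonic substitution {descriptor.raw_cdna!r} without "
        f"a protein change"
    )


# ---------------------------------------------------------------------------
# isoform model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoformModel:
    """Exon membership of one CRB1 transcript (canonical exon numbering)."""

    isoform_id: str
    exons: frozenset[int]

    def __post_init__(self) -> None:
        if self.isoform_id not in {"A", "B", "C"}:
            raise DomainError(f"unknown isoform {self.isoform_id!r}")
        bad = [e for e in self.exons if not (EXON_MIN <= e <= EXON_MAX)]
        if bad:
            raise DomainError(f"exon numbers outside {EXON_MIN}..{EXON_MAX}: {bad}")

    def contains(self, exon: int) -> bool:
        return exon in self.exons


#: Default exon membership: A spans all 12 exons; B and C are the unique simple
#: contiguous split for which exon 6 is the only exon common to all three.
DEFAULT_ISOFORM_EXONS: Mapping[str, frozenset[int]] = {
    "A": frozenset(range(1, 13)),
    "B": frozenset(range(6, 13)),
    "C": frozenset(range(1, 7)),
}


def default_isoform_models() -> dict[str, IsoformModel]:
    return build_isoform_models(DEFAULT_ISOFORM_EXONS)


def build_isoform_models(exon_map: Mapping[str, Iterable[int]]) -> dict[str, IsoformModel]:
    """Build and validate the three-transcript model from an exon-membership map."""
    models = {
        iso: IsoformModel(iso, frozenset(int(e) for e in exons))
        for iso, exons in exon_map.items()
    }
    missing = {"A", "B", "C"} - set(models)
    if missing:
        raise DomainError(f"isoform model must cover A, B, C; missing {sorted(missing)}")
    for iso in ("B", "C"):
        if not models[iso].exons <= models["A"].exons:
            raise DomainError(f"isoform A must contain every exon of {iso}")
        if 6 not in models[iso].exons:
            raise DomainError(f"exon 6 must belong to all three isoforms (missing in {iso})")
    return models


def affected_isoforms(
    exon: int, models: Optional[Mapping[str, IsoformModel]] = None
) -> frozenset[str]:
    """Return the set of isoforms whose transcript contains ``exon``.

    With the default model this always includes A, reflecting that CRB1-A
    spans every exon.
    """
    if not (EXON_MIN <= exon <= EXON_MAX):
        raise DomainError(f"exon {exon} outside {EXON_MIN}..{EXON_MAX}")
    if models is None:
        models = default_isoform_models()
    return frozenset(iso for iso, m in models.items() if m.contains(exon))


# ---------------------------------------------------------------------------
# annotated variant records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpliceToken:
    """One splice-prediction token, e.g. ``2G`` = 2 tools predicting a gain."""

    count: int
    direction: str  # "gain" | "loss"

    def __post_init__(self) -> None:
        if not (0 <= self.count <= N_SPLICE_TOOLS):
            raise DomainError(
                f"splice token count {self.count} outside 0..{N_SPLICE_TOOLS}"
            )
        if self.direction not in {"gain", "loss"}:
            raise DomainError(f"splice direction must be gain/loss, got {self.direction!r}")

    def __str__(self) -> str:
        return f"{self.count}{'G' if self.direction == 'gain' else 'L'}"


_TOKEN_RE = re.compile(r"^(\d+)\s*([GL])$", re.IGNORECASE)
_MISSING_TOKENS = {"", "-", "--", ".", "nan", "none"}


def parse_splice_tokens(text: Optional[str]) -> tuple[SpliceToken, ...]:
    """Parse serialized splice tokens ('2G', '4L', '1G;2L', '--' for absent)."""
    if text is None or str(text).strip().lower() in _MISSING_TOKENS:
        return ()
    tokens = []
    for piece in re.split(r"[;,/\s]+", str(text).strip()):
        if not piece:
            continue
        m = _TOKEN_RE.match(piece)
        if m is None:
            raise VariantParseError(f"unrecognized splice token {piece!r}")
        tokens.append(
            SpliceToken(int(m.group(1)), "gain" if m.group(2).upper() == "G" else "loss")
        )
    return tuple(tokens)


def parse_damaging_count(text: Optional[str]) -> Optional[int]:
    """Parse a damaging-predictor count token ('14D', '6D'; '--' for absent)."""
    if text is None or str(text).strip().lower() in _MISSING_TOKENS:
        return None
    m = re.match(r"^(\d+)\s*D$", str(text).strip(), re.IGNORECASE)
    if m is None:
        raise VariantParseError(f"unrecognized damaging-count token {text!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class VariantRecord:
    """One annotated CRB1 variant as carried by a proband allele."""

    descriptor: VariantDescriptor
    exon: int
    consequence_class: ConsequenceClass
    protein_change: Optional[str] = None
    damaging_count: Optional[int] = None
    splice_tokens: tuple[SpliceToken, ...] = field(default_factory=tuple)
    novel: bool = False
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if not (EXON_MIN <= self.exon <= EXON_MAX):
            raise DomainError(f"exon {self.exon} outside {EXON_MIN}..{EXON_MAX}")
        if self.damaging_count is not None and self.damaging_count < 0:
            raise DomainError(f"negative damaging count {self.damaging_count}")
        if self.damaging_count is not None and self.damaging_count > N_DAMAGING_PREDICTORS:
            raise DomainError(
                f"damaging count {self.damaging_count} exceeds the "
                f"{N_DAMAGING_PREDICTORS} predictors consulted"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise DomainError(f"MAF {self.maf} outside [0, 1]")

    @property
    def cdna(self) -> str:
        return self.descriptor.raw_cdna

    def __str__(self) -> str:
        prot = f" ({self.protein_change})" if self.protein_change else ""
        return f"{self.cdna}{prot}"
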