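"""Transcript/CDS data model, HGVS-c parsing and normalization, translation, I/O.

Coordinates follow the HGVS coding-DNA ("c.") convention externally: 1-based,
c.1 is the first base of the start codon. All internal arithmetic is 0-based
half-open; the conversion happens only at the public boundaries of this module.

The supported variant grammar is deliberately small — single-run frameshift
deletions and the insertion dialect used for knock-in corrections, where
``c.NinsB`` means "the inserted base occupies position N of the edited
sequence". The equivalent anchor form ``c.(N-1)_Nins`` is carried alongside.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

_VALID_BASES = set("ACGTN")

__all__ = [
    "Transcript",
    "FrameshiftVariant",
    "HgvsParseError",
    "UnsupportedVariantError",
    "CoordinateError",
    "ReferenceMismatchError",
    "parse_hgvs_c",
    "normalize_3prime",
    "apply_variant",
    "translate",
    "read_transcript",
    "write_transcript",
]


class HgvsParseError(ValueError):
    """Variant text does not match the supported grammar."""


class UnsupportedVariantError(ValueError):
    """Grammatically valid but outside the supported variant space."""


class CoordinateError(ValueError):
    """A c. coordinate falls outside the CDS."""


class ReferenceMismatchError(ValueError):
    """Deleted bases do not match the reference sequence at that position."""


@dataclass(frozen=True)
class Transcript:
    """A coding sequence with optional genomic context.

    Parameters
    ----------
    id : str
        Transcript identifier.
    cds : str
        Coding sequence, A/C/G/T/N, from the first base of the start codon
        (c.1) through the stop codon.
    genomic_context : str, optional
        A contiguous genomic window containing the CDS as an exact substring
        (intronless model; a multi-exon transcript is represented as its
        spliced CDS plus one context window around the region of interest).
    cds_offset : int
        0-based offset of the CDS within ``genomic_context``.
    """

    id: str
    cds: str
    genomic_context: str | None = None
    cds_offset: int = 0

    def __post_init__(self) -> None:
        bad = set(self.cds) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid CDS characters: {sorted(bad)!r}")
        if self.genomic_context is not None:
            end = self.cds_offset + len(self.cds)
            if self.genomic_context[self.cds_offset:end] != self.cds:
                raise ValueError(
                    "genomic_context does not contain cds at the recorded offset"
                )

    def __len__(self) -> int:
        return len(self.cds)

    def c_to_index(self, pos_c: int) -> int:
        """Convert a 1-based c. position to a 0-based CDS index."""
        if not 1 <= pos_c <= len(self.cds):
            raise CoordinateError(
                f"c.{pos_c} outside CDS of length {len(self.cds)}"
            )
        return pos_c - 1

    def c_to_context_index(self, pos_c: int) -> int:
        """Convert a c. position to a 0-based index on the genomic context."""
        if self.genomic_context is None:
            raise ValueError("transcript has no genomic context")
        return self.cds_offset + self.c_to_index(pos_c)


@dataclass(frozen=True)
class FrameshiftVariant:
    """A small deletion or insertion on the c. axis.

    For insertions ``position`` is the c. position the inserted bases occupy
    after editing (dialect used in knock-in design reports, e.g. c.4464insG);
    ``anchor`` exposes the equivalent between-bases form ``c.(N-1)_Nins``.
    """

    kind: str  # "deletion" | "insertion"
    position: int  # 1-based c. coordinate
    bases: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.bases or set(self.bases) - set("ACGT"):
            raise ValueError(f"invalid variant bases {self.bases!r}")

    @property
    def anchor(self) -> tuple[int, int] | None:
        """Flanking positions (N-1, N) for an insertion; None for deletions."""
        if self.kind != "insertion":
            return None
        return (self.position - 1, self.position)

    def hgvs(self) -> str:
        if self.kind == "deletion":
            return f"c.{self.position}del{self.bases}"
        return f"c.{self.position}ins{self.bases}"


_HGVS_RE = re.compile(
    r"^c\.(?P<p1>\d+)(?:_(?P<p2>\d+))?(?P<op>del|ins|dup|delins|inv)(?P<bases>[ACGTacgt]*)$"
)


def parse_hgvs_c(text: str) -> FrameshiftVariant:
    """Parse a variant in the supported c. grammar.

    Supported forms: ``c.<pos>del<base(s)>``, ``c.<pos>ins<base(s)>`` and the
    anchor form ``c.<pos>_<pos+1>ins<base(s)>`` (converted to the occupied-
    position dialect). At most 3 deleted/inserted bases are supported.
    """
    m = _HGVS_RE.match(text.strip())
    if m is None:
        raise HgvsParseError(f"cannot parse variant text {text!r}")
    op = m.group("op")
    if op not in ("del", "ins"):
        raise HgvsParseError(f"unsupported operator {op!r} in {text!r}")
    bases = m.group("bases").upper()
    if not bases:
        raise HgvsParseError(f"missing explicit bases in {text!r}")
    if len(bases) > 3:
        raise UnsupportedVariantError(
            f"{len(bases)}-base {op} not supported (max 3): {text!r}"
        )
    p1 = int(m.group("p1"))
    p2 = m.group("p2")
    if op == "del":
        if p2 is not None:
            raise HgvsParseError(f"ranged deletions not supported: {text!r}")
        return FrameshiftVariant("deletion", p1, bases)
    if p2 is not None:
        if int(p2) != p1 + 1:
            raise HgvsParseError(
                f"insertion anchor must be adjacent positions, got {text!r}"
            )
        # c.(N-1)_Nins -> inserted bases occupy position N
        return FrameshiftVariant("insertion", int(p2), bases)
    return FrameshiftVariant("insertion", p1, bases)


def apply_variant(cds: str, v: FrameshiftVariant) -> str:
    """Apply a variant to a CDS string, validating the reference bases."""
    n = len(cds)
    i = v.position - 1
    if v.kind == "deletion":
        if i < 0 or i + len(v.bases) > n:
            raise CoordinateError(f"c.{v.position} outside CDS of length {n}")
        ref = cds[i:i + len(v.bases)]
        if ref != v.bases:
            raise ReferenceMismatchError(
                f"expected {v.bases!r} at c.{v.position}, reference has {ref!r}"
            )
        return cds[:i] + cds[i + len(v.bases):]
    # insertion: bases occupy positions [position, position+len) after editing
    if not 1 <= v.position <= n + 1:
        raise CoordinateError(f"c.{v.position} outside CDS of length {n}")
    return cds[:i] + v.bases + cds[i:]


def revert_variant(cds_edited: str, v: FrameshiftVariant) -> str:
    """Invert :func:`apply_variant`."""
    i = v.position - 1
    if v.kind == "deletion":
        return cds_edited[:i] + v.bases + cds_edited[i:]
    obs = cds_edited[i:i + len(v.bases)]
    if obs != v.bases:
        raise ReferenceMismatchError(
            f"edited sequence has {obs!r} at c.{v.position}, expected {v.bases!r}"
        )
    return cds_edited[:i] + cds_edited[i + len(v.bases):]


def normalize_3prime(v: FrameshiftVariant, t: Transcript) -> FrameshiftVariant:
    """Shift a variant to its 3'-most equivalent position (HGVS convention).

    A deletion or insertion of base B inside a run of B can be written at any
    position within the run; all placements produce the same edited sequence.
    The normalized representative is the 3'-most one (e.g. a single-A deletion
    anywhere in an (A)9 run ending at c.4467 normalizes to c.4467delA).
    Idempotent; multi-base variants are shifted only when the edited sequence
    is provably identical.
    """
    cds = t.cds
    t.c_to_index(v.position)  # coordinate check
    edited = apply_variant(cds, v)
    pos = v.position
    # slide one position 3' while the result is unchanged
    while True:
        cand = replace(v, position=pos + 1, normalized=True)
        try:
            if cand.position - 1 + (len(v.bases) if v.kind == "deletion" else 0) > len(cds):
                break
            if v.kind == "insertion" and cand.position > len(cds) + 1:
                break
            if apply_variant(cds, cand) != edited:
                break
        except (CoordinateError, ReferenceMismatchError):
            break
        pos += 1
    return replace(v, position=pos, normalized=True)


# standard nuclear code via biopython; N-containing codons -> 'X'
def translate(cds: str) -> str:
    """Translate a CDS under the standard nuclear genetic code.

    The stop codon is rendered as ``*``; any codon containing N becomes ``X``.
    Raises ``ValueError`` if the length is not a multiple of 3.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate(table=1))


def read_transcript(path: str | Path, format: str | None = None) -> Transcript:
    """Read a transcript from FASTA or GenBank.

    A FASTA record is treated as a bare CDS with no genomic context. A GenBank
    record must carry exactly one ``CDS`` feature; the feature's span defines
    the CDS and the whole record sequence is kept as genomic context.
    """
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    records = list(SeqIO.parse(str(path), format))
    if len(records) != 1:
        raise ValueError(f"expected exactly one record in {path}, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if format == "fasta":
        return Transcript(id=rec.id, cds=seq)
    cds_feats = [f for f in rec.features if f.type == "CDS"]
    if not cds_feats:
        raise ValueError(f"no CDS feature in {path}")
    if len(cds_feats) > 1:
        locs = ", ".join(str(f.location) for f in cds_feats)
        raise ValueError(f"multiple CDS features in {path}: {locs}")
    loc = cds_feats[0].location
    start, end = int(loc.start), int(loc.end)
    return Transcript(id=rec.id, cds=seq[start:end], genomic_context=seq, cds_offset=start)


def write_transcript(t: Transcript, path: str | Path, format: str | None = None) -> None:
    """Write a transcript to FASTA (CDS only) or GenBank (context + CDS feature)."""
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    if format == "fasta":
        rec = SeqRecord(Seq(t.cds), id=t.id, description="")
        SeqIO.write([rec], str(path), "fasta")
        return
    context = t.genomic_context if t.genomic_context is not None else t.cds
    offset = t.cds_offset if t.genomic_context is not None else 0
    rec = SeqRecord(Seq(context), id=t.id, name=t.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.features.append(
        SeqFeature(FeatureLocation(offset, offset + len(t.cds)), type="CDS")
    )
    SeqIO.write([rec], str(path), "genbank")
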