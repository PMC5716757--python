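"""rAAV Gateway targeting-construct design around a stabilizing edit.

Layout follows the classic promoterless knock-in scheme: a left homology arm
(HA1) carrying the corrective, repeat-splitting insertion; a selection
cassette (splice acceptor - IRES - Neo - polyA) flanked by loxP sites so it
can be excised by Cre after targeting; and a right homology arm (HA2). Arms
are amplified with attB-tailed primers for MultiSite Gateway BP cloning
(HA1 into pDONR P1-P2, HA2 into pDONR P3-P4).

Screening follows junction-PCR logic: each junction assay pairs one primer
outside the homology arm with one inside the cassette, so a product appears
only on a correctly targeted allele; a wild-type-allele assay spans the
insertion point and only amplifies when no cassette sits between the primers;
a post-Cre assay spans the loxP scar; and an RT assay spans the inserted base
on the spliced transcript for sequencing the expressed allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp as _mt
from Bio.SeqUtils import gc_fraction

from .seqmodel import Transcript, apply_variant
from .stabilize import StabilizingEdit

__all__ = [
    "ArmSpec",
    "Primer",
    "TargetingConstruct",
    "ScreeningAssay",
    "PrimerDesignError",
    "ArmDesignError",
    "extract_homology_arms",
    "make_gateway_arm_primers",
    "melting_temperature",
    "design_screening_assays",
    "emit_construct_genbank",
    "build_targeting_construct",
    "check_construct_feasibility",
    "in_silico_pcr",
]

# Canonical MultiSite Gateway attB tails (Invitrogen Gateway definitions);
# overridable per call for custom donor systems.
ATTB_TAILS = {
    "attB1": "GGGGACAAGTTTGTACAAAAAAGCAGGCT",
    "attB2": "GGGGACCACTTTGTACAAGAAAGCTGGGT",
    "attB3": "GGGGACAACTTTGTATAATAAAGTTG",
    "attB4": "GGGGACAACTTTGTATAGAAAAGTTG",
}

#: 34-nt loxP site (13-8-13 inverted repeat / spacer)
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

ASSAY_NAMES = ("WT_ALLELE", "HA1_JUNCTION", "HA2_JUNCTION", "POST_CRE", "RT_ACROSS_EDIT")


class PrimerDesignError(ValueError):
    """No primer core satisfies the Tm/GC/length constraints."""


class ArmDesignError(ValueError):
    """Genomic context cannot supply the requested homology arms."""


@dataclass(frozen=True)
class ArmSpec:
    """Homology-arm and construct sizing parameters.

    Defaults: 1,000-nt arms (accepted range 800-1,300), a 2.4-kb cassette and
    a 4.7-kb rAAV payload capacity.
    """

    arm_len: int = 1000
    arm_min: int = 800
    arm_max: int = 1300
    cassette_core_len: int = 2400 - 2 * len(LOXP)
    rna_capacity: int = 4700

    @property
    def cassette_len(self) -> int:
        """Total inserted cassette length including both loxP sites."""
        return self.cassette_core_len + 2 * len(LOXP)


@dataclass(frozen=True)
class Primer:
    name: str
    core: str
    tail: str = ""
    tm: float = 0.0
    gc: float = 0.0
    start: int = 0  # 0-based half-open binding window on the template
    end: int = 0
    strand: int = 1  # +1 forward, -1 reverse

    def __post_init__(self) -> None:
        if not 15 <= len(self.core) <= 35:
            raise ValueError(f"primer core length {len(self.core)} outside 15..35")

    @property
    def sequence(self) -> str:
        return self.tail + self.core


@dataclass(frozen=True)
class TargetingConstruct:
    ha1: str
    cassette_core: str
    ha2: str
    edit: StabilizingEdit
    edit_offset_in_ha1: int  # 0-based index of the inserted base within HA1
    insertion_point: int  # 0-based context coordinate of the HA1/HA2 junction

    @property
    def cassette(self) -> str:
        """Full cassette payload between the arms: loxP + core + loxP."""
        return LOXP + self.cassette_core + LOXP

    @property
    def payload(self) -> str:
        return self.ha1 + self.cassette + self.ha2

    @property
    def payload_len(self) -> int:
        return len(self.payload)

    def feature_table(self) -> list[tuple[str, int, int, int]]:
        """(name, start, end, strand) features, 0-based half-open."""
        feats = []
        pos = 0
        for name, seg in (
            ("HA1", self.ha1),
            ("loxP", LOXP),
            ("SA_IRES_Neo_pA", self.cassette_core),
            ("loxP", LOXP),
            ("HA2", self.ha2),
        ):
            feats.append((name, pos, pos + len(seg), 1))
            pos += len(seg)
        feats.append(
            ("stabilizing_insertion", self.edit_offset_in_ha1, self.edit_offset_in_ha1 + 1, 1)
        )
        return feats


@dataclass(frozen=True)
class ScreeningAssay:
    name: str
    forward: Primer
    reverse: Primer
    #: expected amplicon length per template; None = no product
    expected: dict  # {"parental": int|None, "targeted": int|None, "post_cre": int|None}


def melting_temperature(
    seq: str,
    Na: float = 50.0,
    dnac1: float = 500.0,
    dnac2: float = 0.0,
) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Unified NN parameter set (SantaLucia & Hicks 2004), monovalent salt
    ``Na`` mM, primer concentration ``dnac1`` nM against trace template.
    Accepts unambiguous sequences of 8-60 nt.
    """
    seq = seq.upper()
    if not 8 <= len(seq) <= 60:
        raise ValueError(f"sequence length {len(seq)} outside 8..60")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in {seq!r}")
    return float(
        _mt.Tm_NN(Seq(seq), nn_table=_mt.DNA_NN4, Na=Na, dnac1=dnac1, dnac2=dnac2)
    )


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _pick_core(
    template: str,
    anchor: int,
    strand: int,
    tm_window: tuple[float, float] = (57.0, 63.0),
    gc_bounds: tuple[float, float] = (0.35, 0.65),
) -> tuple[str, int, int, float, float]:
    """Extend a primer core from a terminus until Tm and GC constraints hold.

    For ``strand=+1`` the core grows 3'-ward from ``anchor``; for ``strand=-1``
    it grows 5'-ward ending at ``anchor`` (exclusive) and is reverse-
    complemented. Returns (core, start, end, tm, gc).
    """
    last_fail = "no candidate length"
    for length in range(15, 36):
        if strand == 1:
            start, end = anchor, anchor + length
        else:
            start, end = anchor - length, anchor
        if start < 0 or end > len(template):
            last_fail = "template exhausted"
            break
        window = template[start:end]
        core = window if strand == 1 else _revcomp(window)
        if set(core) - set("ACGT"):
            last_fail = "ambiguous bases"
            continue
        tm = melting_temperature(core)
        gc = gc_fraction(core)
        if tm < tm_window[0]:
            last_fail = f"Tm {tm:.1f} below window"
            continue
        if tm > tm_window[1]:
            last_fail = f"Tm {tm:.1f} above window"
            break  # Tm only grows with length
        if not gc_bounds[0] <= gc <= gc_bounds[1]:
            last_fail = f"GC {gc:.2f} outside bounds"
            continue
        return core, start, end, tm, gc
    raise PrimerDesignError(f"no primer core satisfies constraints: {last_fail}")


def extract_homology_arms(
    t: Transcript,
    e: StabilizingEdit,
    spec: ArmSpec = ArmSpec(),
    insertion_point: int | None = None,
) -> tuple[str, str]:
    """Cut HA1/HA2 out of the genomic context around the cassette junction.

    HA1 is the ``spec.arm_len`` window ending at the insertion point with the
    stabilizing edit applied (so the arm carries the split-repeat allele);
    HA2 is the wild-type-downstream window starting there. By default the
    junction sits immediately 3' of the edited exon segment (end of the CDS
    in the context).
    """
    if not spec.arm_min <= spec.arm_len <= spec.arm_max:
        raise ArmDesignError(
            f"arm length {spec.arm_len} outside accepted range "
            f"{spec.arm_min}..{spec.arm_max}"
        )
    if t.genomic_context is None:
        raise ArmDesignError("transcript has no genomic context")
    ctx = t.genomic_context
    if insertion_point is None:
        insertion_point = t.cds_offset + len(t.cds)
    # the corrective insertion shifts context coordinates at/after the edit
    edit_ctx = t.cds_offset + (e.insertion.position - 1)
    if not (insertion_point - spec.arm_len) <= edit_ctx < insertion_point:
        raise ArmDesignError("stabilizing edit does not fall inside HA1")
    # arms come from the corrected context; the length-neutral correction
    # keeps downstream context coordinates unshifted
    corrected_ctx = ctx[: t.cds_offset] + e.edited_cds + ctx[t.cds_offset + len(t.cds):]
    ha1_start = insertion_point - spec.arm_len
    ha2_end = insertion_point + spec.arm_len
    if ha1_start < 0 or ha2_end > len(corrected_ctx):
        raise ArmDesignError(
            f"context too short for {spec.arm_len}-nt arms: need "
            f"[{ha1_start}, {ha2_end}), have [0, {len(corrected_ctx)})"
        )
    ha1 = corrected_ctx[ha1_start:insertion_point]
    ha2 = corrected_ctx[insertion_point:ha2_end]
    return ha1, ha2


def build_targeting_construct(
    t: Transcript,
    e: StabilizingEdit,
    spec: ArmSpec = ArmSpec(),
    insertion_point: int | None = None,
) -> TargetingConstruct:
    """Assemble the HA1 / loxP-cassette-loxP / HA2 payload and check capacity."""
    if insertion_point is None:
        if t.genomic_context is None:
            raise ArmDesignError("transcript has no genomic context")
        insertion_point = t.cds_offset + len(t.cds)
    ha1, ha2 = extract_homology_arms(t, e, spec, insertion_point)
    payload = len(ha1) + spec.cassette_len + len(ha2)
    if payload > spec.rna_capacity:
        raise ArmDesignError(
            f"payload {payload} nt exceeds rAAV capacity {spec.rna_capacity} nt"
        )
    edit_ctx = t.cds_offset + (e.insertion.position - 1)
    cassette_core = _neutral_filler(spec.cassette_core_len)
    return TargetingConstruct(
        ha1=ha1,
        cassette_core=cassette_core,
        ha2=ha2,
        edit=e,
        edit_offset_in_ha1=edit_ctx - (insertion_point - len(ha1)),
        insertion_point=insertion_point,
    )


def _neutral_filler(n: int) -> str:
    """Deterministic homopolymer-free stand-in for the cassette interior.

    The real splice-acceptor/IRES/Neo/polyA sequence is vendor material; only
    its length and loxP flanks matter to the design logic, so the core is an
    opaque synthetic placeholder: fixed-seed non-repetitive sequence, unique
    enough for in-silico primer placement.
    """
    import numpy as np

    rng = np.random.default_rng(0xCA55E77E % 2**31)
    bases = "ACGT"
    out: list[str] = []
    prev = ""
    for _ in range(n):
        choices = [b for b in bases if b != prev]
        out.append(choices[rng.integers(len(choices))])
        prev = out[-1]
    return "".join(out)


def make_gateway_arm_primers(
    arm: str,
    site_pair: str,
    name_prefix: str = "HA",
    tails: dict[str, str] = ATTB_TAILS,
) -> tuple[Primer, Primer]:
    """attB-tailed forward/reverse primers at the arm termini.

    ``site_pair`` selects the donor vector: ``"P1-P2"`` puts attB1 on the
    forward and attB2 on the reverse primer (HA1 convention), ``"P3-P4"``
    uses attB3/attB4 (HA2).
    """
    if len(arm) < 100:
        raise ValueError(f"arm too short for amplification primers: {len(arm)} nt")
    pair_tails = {
        "P1-P2": ("attB1", "attB2"),
        "P3-P4": ("attB3", "attB4"),
    }
    if site_pair not in pair_tails:
        raise ValueError(f"unknown donor pair {site_pair!r}")
    fwd_key, rev_key = pair_tails[site_pair]
    core_f, s_f, e_f, tm_f, gc_f = _pick_core(arm, 0, +1)
    core_r, s_r, e_r, tm_r, gc_r = _pick_core(arm, len(arm), -1)
    fwd = Primer(
        name=f"{name_prefix}_F_{fwd_key}", core=core_f, tail=tails[fwd_key],
        tm=tm_f, gc=gc_f, start=s_f, end=e_f, strand=+1,
    )
    rev = Primer(
        name=f"{name_prefix}_R_{rev_key}", core=core_r, tail=tails[rev_key],
        tm=tm_r, gc=gc_r, start=s_r, end=e_r, strand=-1,
    )
    return fwd, rev


def in_silico_pcr(
    template: str, fwd: Primer, rev: Primer, max_amplicon: int = 2000
) -> int | None:
    """Expected amplicon length of a primer pair on a template, or None.

    The forward core must occur on the plus strand and the reverse core's
    reverse complement downstream of it; products longer than ``max_amplicon``
    are treated as not amplifiable under screening PCR conditions. Ambiguous
    (multi-site) binding yields the first productive pairing.
    """
    f = template.find(fwd.core)
    if f < 0:
        return None
    site = _revcomp(rev.core)
    r = template.find(site, f + len(fwd.core))
    if r < 0:
        return None
    length = r + len(site) - f
    return length if length <= max_amplicon else None


def _primer_at(template: str, anchor: int, strand: int, name: str, slide: int = 60) -> Primer:
    """Design a screening primer near ``anchor``, sliding up to ``slide`` nt.

    Unlike Gateway arm primers, screening primers are not pinned to a
    terminus, so the anchor may shift a few nt to satisfy the Tm/GC window.
    """
    offsets = [0]
    for k in range(5, slide + 1, 5):
        offsets += [k, -k]
    last: Exception | None = None
    for off in offsets:
        try:
            core, s, e, tm, gc = _pick_core(template, anchor + off, strand)
            return Primer(name=name, core=core, tm=tm, gc=gc, start=s, end=e, strand=strand)
        except PrimerDesignError as exc:
            last = exc
    raise PrimerDesignError(f"{name}: {last}")


def screening_templates(
    t: Transcript,
    c: TargetingConstruct,
    parental_cds: str,
) -> dict[str, str]:
    """Genomic templates for the three allele states.

    ``parental`` carries the uncorrected (frameshifted) allele; ``targeted``
    carries the corrected allele with the full loxP-cassette-loxP inserted at
    the junction; ``post_cre`` is the targeted allele after Cre excision,
    leaving a single loxP scar.
    """
    ctx = t.genomic_context
    if ctx is None:
        raise ArmDesignError("transcript has no genomic context")
    parental = ctx[: t.cds_offset] + parental_cds + ctx[t.cds_offset + len(t.cds):]
    corrected = (
        ctx[: t.cds_offset] + c.edit.edited_cds + ctx[t.cds_offset + len(t.cds):]
    )
    ip = c.insertion_point
    # context coordinates are preserved by the length-neutral correction
    targeted = corrected[:ip] + c.cassette + corrected[ip:]
    post_cre = corrected[:ip] + LOXP + corrected[ip:]
    return {"parental": parental, "targeted": targeted, "post_cre": post_cre}


def design_screening_assays(
    c: TargetingConstruct,
    t: Transcript,
    parental_cds: str,
    outside_margin: int = 120,
    max_amplicon: int = 2000,
) -> tuple[list[ScreeningAssay], dict[str, str]]:
    """The five-assay screening panel with per-template expected amplicons.

    Returns the designable assays plus a name->reason map for any assay that
    could not be designed on this construct.
    """
    templates = screening_templates(t, c, parental_cds)
    ctx = t.genomic_context
    ip = c.insertion_point
    ha1_start = ip - len(c.ha1)
    ha2_end = ip + len(c.ha2)
    cassette = c.cassette

    assays: list[ScreeningAssay] = []
    failures: dict[str, str] = {}

    def _try(name, make):
        try:
            assays.append(make())
        except (PrimerDesignError, ValueError) as exc:
            failures[name] = str(exc)

    def _expected(fwd, rev):
        return {
            k: in_silico_pcr(tpl, fwd, rev, max_amplicon)
            for k, tpl in templates.items()
        }

    def wt_allele():
        # spans the insertion point within the arms: product only when no
        # cassette sits between the primers
        fwd = _primer_at(ctx, ip - 150, +1, "WT_F")
        rev = _primer_at(ctx, ip + 150, -1, "WT_R")
        return ScreeningAssay("WT_ALLELE", fwd, rev, _expected(fwd, rev))

    def ha1_junction():
        # one primer genomic, outside/5' of HA1; the mate inside the cassette
        fwd = _primer_at(ctx, ha1_start - outside_margin, +1, "HA1J_F")
        rev = _primer_at(cassette, min(len(cassette), 400), -1, "HA1J_R")
        # shift the cassette-local primer onto the targeted template
        rev_t = templates["targeted"].find(_revcomp(rev.core))
        if rev_t < 0:
            raise PrimerDesignError("cassette primer not found on targeted template")
        return ScreeningAssay("HA1_JUNCTION", fwd, rev, _expected(fwd, rev))

    def ha2_junction():
        fwd = _primer_at(cassette, max(0, len(cassette) - 400), +1, "HA2J_F")
        rev = _primer_at(ctx, ha2_end + outside_margin, -1, "HA2J_R")
        return ScreeningAssay("HA2_JUNCTION", fwd, rev, _expected(fwd, rev))

    def post_cre():
        # flanks the junction just inside the arms; resolves parental vs scar
        fwd = _primer_at(ctx, ip - 80, +1, "CRE_F")
        rev = _primer_at(ctx, ip + 80, -1, "CRE_R")
        return ScreeningAssay("POST_CRE", fwd, rev, _expected(fwd, rev))

    def rt_across_edit():
        # on the spliced transcript, spanning the inserted base (sequencing
        # the expressed allele); templates are the two CDS alleles
        cds = c.edit.edited_cds
        i = c.edit.insertion.position - 1
        fwd = _primer_at(cds, max(0, i - 100), +1, "RT_F")
        rev = _primer_at(cds, min(len(cds), i + 100), -1, "RT_R")
        expected = {
            "parental": in_silico_pcr(parental_cds, fwd, rev, max_amplicon),
            "targeted": in_silico_pcr(cds, fwd, rev, max_amplicon),
            "post_cre": in_silico_pcr(cds, fwd, rev, max_amplicon),
        }
        return ScreeningAssay("RT_ACROSS_EDIT", fwd, rev, expected)

    for name, make in (
        ("WT_ALLELE", wt_allele),
        ("HA1_JUNCTION", ha1_junction),
        ("HA2_JUNCTION", ha2_junction),
        ("POST_CRE", post_cre),
        ("RT_ACROSS_EDIT", rt_across_edit),
    ):
        _try(name, make)
    return assays, failures


def check_construct_feasibility(
    t: Transcript, e: StabilizingEdit, spec: ArmSpec = ArmSpec()
) -> tuple[bool, str]:
    """Arm extraction + payload + Gateway primer design on the top edit."""
    try:
        c = build_targeting_construct(t, e, spec)
        make_gateway_arm_primers(c.ha1, "P1-P2", name_prefix="HA1")
        make_gateway_arm_primers(c.ha2, "P3-P4", name_prefix="HA2")
    except (ArmDesignError, PrimerDesignError, ValueError) as exc:
        return False, str(exc)
    return True, "OK"


def emit_construct_genbank(c: TargetingConstruct, path: str | Path, record_id: str = "targeting_construct") -> None:
    """Write the construct payload as an annotated GenBank record."""
    rec = SeqRecord(Seq(c.payload), id=record_id, name=record_id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    for name, start, end, strand in c.feature_table():
        ftype = "variation" if name == "stabilizing_insertion" else "misc_feature"
        feat = SeqFeature(FeatureLocation(start, end, strand=strand), type=ftype)
        feat.qualifiers["label"] = [name]
        rec.features.append(feat)
    SeqIO.write([rec], str(path), "genbank")


def read_construct_features(path: str | Path) -> list[tuple[str, int, int, int]]:
    """Read back the feature table emitted by :func:`emit_construct_genbank`."""
    rec = next(SeqIO.parse(str(path), "genbank"))
    out = []
    for f in rec.features:
        label = f.qualifiers.get("label", ["?"])[0]
        out.append((label, int(f.location.start), int(f.location.end), f.location.strand or 1))
    return out
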