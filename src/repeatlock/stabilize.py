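"""Repeat-stabilizing knock-in design.

Frameshift deletions in long coding mononucleotide runs (e.g. the (A)9 Lys
tract mutated in mismatch-repair-deficient colorectal tumors) can be corrected
by re-inserting a base — but re-inserting the run base recreates the unstable
run, which is prone to slippage re-mutation. The designer instead enumerates
synonymous insertions that restore the reading frame while *splitting* the run
into two shorter runs: switching one codon of the tract to a synonymous
alternative (AAA -> AAG for lysine) keeps the protein identical and caps the
longest residual homopolymer.

Candidates are validated by full re-translation of the edited CDS against the
wild-type protein, and ranked by (longest residual run, run balance, 5'-most
coordinate), so the most stabilized, most balanced design wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqmodel import (
    CoordinateError,
    FrameshiftVariant,
    Transcript,
    apply_variant,
    normalize_3prime,
    translate,
)

__all__ = [
    "CodingRepeat",
    "StabilizingEdit",
    "AmenabilityVerdict",
    "find_coding_repeats",
    "enumerate_stabilizing_edits",
    "rank_edits",
    "assess_amenability",
    "stability_report",
]

#: verdict reason codes
OK = "OK"
NO_SYNONYMOUS_SPLIT = "NO_SYNONYMOUS_SPLIT"
RUN_BELOW_THRESHOLD = "RUN_BELOW_THRESHOLD"
AMBIGUOUS_SEQUENCE = "AMBIGUOUS_SEQUENCE"
ARM_DESIGN_FAIL = "ARM_DESIGN_FAIL"

#: how far beyond the run, in nt, insertion positions are enumerated — covers
#: synonymous edits landing in run-flanking codon positions
ENUMERATION_FLANK = 3


@dataclass(frozen=True)
class CodingRepeat:
    """A maximal mononucleotide run inside a CDS.

    ``start_c``/``end_c`` are 1-based inclusive c. coordinates;
    ``frame_offset`` is the 0..2 position of the run start within its codon.
    """

    base: str
    start_c: int
    end_c: int
    frame_offset: int

    @property
    def length(self) -> int:
        return self.end_c - self.start_c + 1

    @property
    def codon_indices(self) -> tuple[int, ...]:
        """1-based indices of the codons the run touches."""
        first = (self.start_c - 1) // 3 + 1
        last = (self.end_c - 1) // 3 + 1
        return tuple(range(first, last + 1))


@dataclass(frozen=True)
class StabilizingEdit:
    """A frame-restoring insertion that splits the mutant run.

    ``residual_runs`` are the run-base tallies immediately 5' and 3' of the
    inserted base(s) within the corrected tract; their sum equals the mutant
    run length. ``rank_score`` sorts ascending: shortest longest-residual
    first, then most balanced, then 5'-most.
    """

    insertion: FrameshiftVariant
    residual_runs: tuple[int, int]
    protein_identical: bool
    edited_cds: str = field(repr=False, default="")

    @property
    def longest_residual(self) -> int:
        return max(self.residual_runs)

    @property
    def rank_score(self) -> tuple[int, int, int]:
        a, b = self.residual_runs
        return (max(a, b), abs(a - b), self.insertion.position)


@dataclass(frozen=True)
class AmenabilityVerdict:
    amenable: bool
    reasons: tuple[str, ...]
    best_edit: StabilizingEdit | None = None

    def __post_init__(self) -> None:
        ok = self.reasons == (OK,)
        if self.amenable != ok or self.amenable != (self.best_edit is not None):
            raise ValueError("inconsistent verdict")


def find_coding_repeats(t: Transcript, min_len: int = 6) -> list[CodingRepeat]:
    """All maximal single-base runs of length >= ``min_len``, sorted by start.

    N is never a run base; runs are annotated with their codon frame.
    """
    cds = t.cds
    out: list[CodingRepeat] = []
    i, n = 0, len(cds)
    while i < n:
        j = i
        while j < n and cds[j] == cds[i]:
            j += 1
        if cds[i] in "ACGT" and j - i >= min_len:
            out.append(
                CodingRepeat(
                    base=cds[i],
                    start_c=i + 1,
                    end_c=j,
                    frame_offset=i % 3,
                )
            )
        i = j
    return out


def _run_lengths_around(
    seq: str, lo: int, hi: int, ins_idx: int, base: str
) -> tuple[int, int]:
    """Maximal runs of ``base`` overlapping the closed region [lo, hi].

    The region spans the mutant run together with the inserted segment, so
    an insertion of the run base (which merges the flanks into one run) and
    an insertion beyond the run (which leaves the whole mutant run intact)
    are both measured correctly. Returned as a (5', 3') pair relative to the
    insertion point; a single surviving run is reported on the side where it
    starts.
    """
    n = len(seq)
    runs: list[tuple[int, int]] = []  # (start, length) of runs intersecting [lo, hi]
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] == base and i <= hi and j - 1 >= lo:
            runs.append((i, j - i))
        i = j
    if not runs:
        return (0, 0)
    if len(runs) == 1:
        return (runs[0][1], 0) if runs[0][0] < ins_idx else (0, runs[0][1])
    return (runs[0][1], runs[-1][1])


def enumerate_stabilizing_edits(
    t: Transcript,
    r: CodingRepeat,
    m: FrameshiftVariant,
    include_non_splitting: bool = False,
) -> list[StabilizingEdit]:
    """Enumerate frame-restoring insertions that preserve the protein.

    ``m`` must be a deletion of d bases (d in {1, 2}) inside run ``r``; it is
    3'-normalized internally, so any equivalent placement within the run is
    accepted. Every candidate d-base insertion with its occupied position in
    the window [r.start_c - 3, r.end_c + 3] (mutant coordinates, clipped to
    the CDS) is applied to the mutant CDS and kept iff

    * the edited CDS translates identically to the wild type, and
    * the longest residual run of the repeat base is shorter than the
      wild-type run (the split requirement; dropped only when
      ``include_non_splitting`` is set, for comparison output).

    Candidates yielding byte-identical edited sequences are deduplicated to
    the 3'-most representative. Results are in coordinate order.
    """
    if m.kind != "deletion":
        raise ValueError("correction design requires a deletion variant")
    d = len(m.bases)
    if d not in (1, 2):
        raise ValueError(f"only 1-2 base deletions supported, got {d}")
    m = normalize_3prime(m, t)
    if not (r.start_c <= m.position and m.position + d - 1 <= r.end_c):
        raise ValueError(
            f"deletion at c.{m.position} is not inside the run "
            f"c.{r.start_c}-c.{r.end_c}"
        )
    if set(m.bases) != {r.base}:
        raise ValueError("deletion bases differ from the run base")

    wt_cds = t.cds
    lo = max(1, r.start_c - ENUMERATION_FLANK)
    hi = min(len(wt_cds), r.end_c + ENUMERATION_FLANK)
    if "N" in wt_cds[lo - 1:hi]:
        raise ValueError("AMBIGUOUS_SEQUENCE: N within the repeat/edit window")

    wt_protein = translate(wt_cds)
    mut_cds = apply_variant(wt_cds, m)
    # mutant run boundaries (deletion is inside the run, so the run shrinks)
    mut_run_start = r.start_c
    mut_run_end = r.end_c - d

    import itertools

    seen: dict[str, StabilizingEdit] = {}
    bases_alphabet = ["A", "C", "G", "T"]
    for pos in range(lo, min(len(mut_cds) + 1, hi) + 1):
        for combo in itertools.product(bases_alphabet, repeat=d):
            ins = FrameshiftVariant("insertion", pos, "".join(combo))
            edited = apply_variant(mut_cds, ins)
            if len(edited) != len(wt_cds):
                continue
            if translate(edited) != wt_protein:
                continue
            # region of interest in the edited sequence: the mutant run
            # (indices shifted by the insertion where applicable) plus the
            # inserted bases themselves
            run_s = mut_run_start - 1 + (d if pos - 1 <= mut_run_start - 1 else 0)
            run_e = mut_run_end - 1 + (d if pos - 1 <= mut_run_end - 1 else 0)
            lo_idx = min(run_s, pos - 1)
            hi_idx = max(run_e, pos - 1 + d - 1)
            runs = _run_lengths_around(edited, lo_idx, hi_idx, pos - 1, r.base)
            edit = StabilizingEdit(
                insertion=ins,
                residual_runs=runs,
                protein_identical=True,
                edited_cds=edited,
            )
            # dedupe identical outcomes to the 3'-most (HGVS-style) placement
            prev = seen.get(edited)
            if prev is None or ins.position > prev.insertion.position:
                seen[edited] = edit
    edits = [
        e
        for e in seen.values()
        if include_non_splitting or e.longest_residual < r.length
    ]
    edits.sort(key=lambda e: e.insertion.position)
    return edits


def rank_edits(edits: list[StabilizingEdit]) -> list[StabilizingEdit]:
    """Deterministic total order: ascending (longest residual, imbalance, position)."""
    return sorted(edits, key=lambda e: e.rank_score)


def assess_amenability(
    t: Transcript,
    r: CodingRepeat,
    m: FrameshiftVariant,
    arm_spec=None,
    min_len: int = 6,
) -> AmenabilityVerdict:
    """Full go/no-go verdict for a repeat-stabilizing knock-in design.

    Checks, in order: run length threshold, sequence ambiguity in the edit
    window, existence of a synonymous splitting insertion, and — when
    ``arm_spec`` (a :class:`repeatlock.construct.ArmSpec`) is given —
    construct-level feasibility (homology arms, payload, primers) on the
    top-ranked edit. Failures accumulate as reason codes.
    """
    reasons: list[str] = []
    best: StabilizingEdit | None = None
    if r.length < min_len:
        reasons.append(RUN_BELOW_THRESHOLD)
    try:
        edits = enumerate_stabilizing_edits(t, r, m)
    except ValueError as exc:
        if "AMBIGUOUS_SEQUENCE" in str(exc):
            reasons.append(AMBIGUOUS_SEQUENCE)
            edits = []
        else:
            raise
    if not edits:
        if AMBIGUOUS_SEQUENCE not in reasons:
            reasons.append(NO_SYNONYMOUS_SPLIT)
    else:
        best = rank_edits(edits)[0]
        if arm_spec is not None:
            from .construct import check_construct_feasibility

            ok, _why = check_construct_feasibility(t, best, arm_spec)
            if not ok:
                reasons.append(ARM_DESIGN_FAIL)
    if reasons:
        return AmenabilityVerdict(False, tuple(reasons), None)
    return AmenabilityVerdict(True, (OK,), best)


def stability_report(r: CodingRepeat, e: StabilizingEdit) -> dict:
    """Qualitative stability summary for one emitted edit."""
    mutant_len = sum(e.residual_runs)
    return {
        "run_base": r.base,
        "wild_type_run": r.length,
        "mutant_run": mutant_len,
        "residual_runs": e.residual_runs,
        "longest_residual": e.longest_residual,
        "reduction_of_longest_run": r.length - e.longest_residual,
        "insertion": e.insertion.hgvs(),
    }
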