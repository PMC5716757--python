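"""Deterministic synthetic-data generators.

Every generator takes explicit size/effect parameters plus a seed, emits the
data together with a truth record naming the planted effects, and is
byte-reproducible: the same parameters and seed always produce identical
output. The flagship transcript generator plants an in-frame lysine
(A)-tract whose 3'-most base sits at a requested coding coordinate, modeled
on a tumor-suppressor transcript carrying an (A)9 tract whose single-base
deletion is 3'-anchored at c.4467.

The synthetic data emulate structure, not biology: expression tables carry
exactly the planted concordant/discordant genes, peak sets draw their genic
placement from a Bernoulli scheme, and Ct tables invert the ΔΔCt formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqmodel import Transcript, write_transcript

__all__ = [
    "TranscriptFixtureSpec",
    "make_repeat_transcript",
    "make_expression_fixture",
    "make_peak_fixture",
    "make_ct_fixture",
    "write_fixture",
]

@dataclass(frozen=True)
class TranscriptFixtureSpec:
    """Parameters of the repeat-transcript fixture.

    Defaults pin a 1,500-codon CDS (4,503 nt with the stop) carrying an (A)9
    run whose 3'-most base is c.4467, i.e. codons 1487-1489 = AAA AAA AAA,
    with 2-kb non-repetitive genomic flanks.
    """

    seed: int = 0
    codon_count: int = 1500  # codons before the stop
    run_base: str = "A"
    run_length: int = 9
    run_end_c: int = 4467  # c. coordinate of the run's 3'-most base
    context_pad: int = 2000
    transcript_id: str = "SYN_PRDM2_LIKE"


def _flank(rng: np.random.Generator, n: int, forbid_first: str = "", forbid_last: str = "") -> str:
    """Random sequence with no two equal adjacent bases (no runs >= 2)."""
    bases = "ACGT"
    out: list[str] = []
    prev = ""
    for i in range(n):
        choices = [b for b in bases if b != prev]
        if i == 0 and forbid_first:
            choices = [b for b in choices if b != forbid_first]
        if i == n - 1 and forbid_last:
            choices = [b for b in choices if b != forbid_last]
        out.append(choices[rng.integers(len(choices))])
        prev = out[-1]
    return "".join(out)


def make_repeat_transcript(spec: TranscriptFixtureSpec = TranscriptFixtureSpec()) -> tuple[Transcript, dict]:
    """Build the repeat-carrying transcript and its truth record.

    The CDS is ATG + non-repetitive filler + stop (TGA, adenine-free), with
    ``run_length`` copies of ``run_base`` overwriting positions
    ``run_end_c - run_length + 1 .. run_end_c``. The filler never repeats a
    base twice in a row, so the planted run is the only run of length >= 2 in
    the entire molecule and every primer-length window is unique with
    overwhelming probability. For an A-run, the base immediately 3' of the
    run is constrained to a pyrimidine: a G there would let the 3'-terminal
    AAG candidate shift past the annotated run end, relabeling the design
    coordinate.
    """
    n_codons = spec.codon_count
    run_start_c = spec.run_end_c - spec.run_length + 1
    cds_len = 3 * (n_codons + 1)
    if run_start_c < 4:
        raise ValueError("run overlaps the start codon")
    if spec.run_end_c > 3 * n_codons:
        raise ValueError("run overlaps the stop codon")

    rng = np.random.default_rng(spec.seed)
    filler = _flank(rng, cds_len - 6, forbid_first="G", forbid_last="T")
    cds = list("ATG" + filler + "TGA")
    assert len(cds) == cds_len
    for c_pos in range(run_start_c, spec.run_end_c + 1):
        cds[c_pos - 1] = spec.run_base

    def _fix_neighbor(idx: int, forbidden: set[str]) -> None:
        """Redraw cds[idx] avoiding ``forbidden`` and its current neighbors."""
        if not 0 <= idx < cds_len or cds[idx] not in forbidden:
            return
        avoid = set(forbidden)
        if idx > 0:
            avoid.add(cds[idx - 1])
        if idx + 1 < cds_len:
            avoid.add(cds[idx + 1])
        choices = [b for b in "ACGT" if b not in avoid]
        cds[idx] = choices[rng.integers(len(choices))]

    three_prime_forbid = {spec.run_base, "G"} if spec.run_base == "A" else {spec.run_base}
    _fix_neighbor(run_start_c - 2, {spec.run_base})
    _fix_neighbor(spec.run_end_c, three_prime_forbid)
    cds = "".join(cds)
    # maximality of the planted run
    if run_start_c >= 2 and cds[run_start_c - 2] == spec.run_base:
        raise ValueError("planted run not maximal on its 5' side")
    if spec.run_end_c < cds_len and cds[spec.run_end_c] == spec.run_base:
        raise ValueError("planted run not maximal on its 3' side")

    left = _flank(rng, spec.context_pad, forbid_last=cds[0])
    right = _flank(rng, spec.context_pad, forbid_first=cds[-1])
    t = Transcript(
        id=spec.transcript_id,
        cds=cds,
        genomic_context=left + cds + right,
        cds_offset=len(left),
    )
    truth = {
        "seed": spec.seed,
        "cds_length": cds_len,
        "run_base": spec.run_base,
        "run_start_c": run_start_c,
        "run_end_c": spec.run_end_c,
        "run_length": spec.run_length,
        "frameshift_variant": f"c.{spec.run_end_c}del{spec.run_base}",
    }
    return t, truth


# ----------------------------------------------------------- expression

def make_expression_fixture(
    seed: int = 0,
    n_up: int = 20,
    n_down: int = 30,
    n_discordant: int = 50,
    n_null: int = 900,
    n_clones: int = 3,
    threshold: float = 1.5,
    fold_max: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Three-clone fold-change table with planted concordant genes.

    Planted "up" genes draw per-clone folds log-uniformly in
    [threshold, fold_max]; "down" genes in [1/fold_max, 1/threshold];
    discordant genes cross the threshold in some but not all clones; null
    genes stay strictly inside (1/threshold, threshold) in every clone.
    Recovery by the strict all-clone intersection is therefore exact.
    """
    rng = np.random.default_rng(seed)
    ids = [f"GENE{i:05d}" for i in range(n_up + n_down + n_discordant + n_null)]
    rows = []
    i = 0
    lo, hi = np.log(threshold), np.log(fold_max)
    eps = 1e-3

    def draw(n, a, b):
        return np.exp(rng.uniform(a, b, size=n))

    for _ in range(n_up):
        rows.append((ids[i], draw(n_clones, lo, hi)))
        i += 1
    for _ in range(n_down):
        rows.append((ids[i], 1.0 / draw(n_clones, lo, hi)))
        i += 1
    for _ in range(n_discordant):
        folds = np.exp(rng.uniform(-(lo - eps), lo - eps, size=n_clones))
        k = rng.integers(n_clones)  # one clone beyond the threshold
        sign = 1 if rng.random() < 0.5 else -1
        folds[k] = np.exp(sign * rng.uniform(lo, hi))
        rows.append((ids[i], folds))
        i += 1
    for _ in range(n_null):
        rows.append((ids[i], np.exp(rng.uniform(-(lo - eps), lo - eps, size=n_clones))))
        i += 1
    df = pd.DataFrame(
        {f"clone{j + 1}": [r[1][j] for r in rows] for j in range(n_clones)},
        index=pd.Index([r[0] for r in rows], name="gene"),
    )
    truth = {
        "seed": seed,
        "threshold": threshold,
        "up": sorted(ids[:n_up]),
        "down": sorted(ids[n_up:n_up + n_down]),
    }
    return df, truth


# ----------------------------------------------------------------- peaks

def make_peak_fixture(
    seed: int = 0,
    n_genes: int = 200,
    gene_len: int = 2000,
    exon_len: int = 300,
    chrom_len: int = 1_000_000,
    n_peaks: int = 2000,
    n_reference_peaks: int = 2000,
    peak_width: int = 200,
    reference_genic_prob: float = 0.25,
    enrichment_factor: float = 3.0,
    tss_concentration: float = 0.0,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Synthetic peak/gene-model pairs with a planted genic enrichment.

    Genes of ``gene_len`` bp (terminal ``exon_len``-bp exons, alternating
    strand) are laid on a regular grid. Reference peaks fall in a gene with
    probability ``reference_genic_prob``; test peaks with that probability
    scaled by ``enrichment_factor``. ``tss_concentration`` is the fraction of
    genic test peaks centered exactly on a TSS (for metaprofile shape).

    Returns (peaks, reference_peaks, gene_models, truth); interval frames use
    0-based half-open Chromosome/Start/End (+ Strand/Feature for models).
    """
    test_genic_prob = enrichment_factor * reference_genic_prob
    if not 0 < test_genic_prob <= 1:
        raise ValueError("enrichment_factor * reference_genic_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pitch = chrom_len // n_genes
    if pitch < 2 * gene_len:
        raise ValueError("genes do not fit the chromosome")
    genes = []
    for g in range(n_genes):
        start = g * pitch + (pitch - gene_len) // 2
        end = start + gene_len
        strand = "+" if g % 2 == 0 else "-"
        genes.append((chrom, start, end, strand, "gene", f"gene{g:04d}"))
        genes.append((chrom, start, start + exon_len, strand, "exon", f"gene{g:04d}.e1"))
        genes.append((chrom, end - exon_len, end, strand, "exon", f"gene{g:04d}.e2"))
    models = pd.DataFrame(
        genes, columns=["Chromosome", "Start", "End", "Strand", "Feature", "Name"]
    )
    gene_rows = models[models["Feature"] == "gene"].reset_index(drop=True)

    def _one_peak(genic: bool, at_tss: bool) -> tuple[int, int]:
        if genic:
            gi = int(rng.integers(n_genes))
            gs, ge = int(gene_rows.loc[gi, "Start"]), int(gene_rows.loc[gi, "End"])
            if at_tss:
                tss = gs if gene_rows.loc[gi, "Strand"] == "+" else ge - 1
                mid = tss
            else:
                mid = int(rng.integers(gs + peak_width // 2, ge - peak_width // 2))
        else:
            # gap midpoints: stay clear of every gene body
            while True:
                gi = int(rng.integers(n_genes))
                gap_lo = gi * pitch
                gap_hi = gap_lo + (pitch - gene_len) // 2
                mid = int(rng.integers(gap_lo + peak_width, gap_hi - peak_width))
                break
        return max(0, mid - peak_width // 2), mid + peak_width // 2

    def _peak_set(n: int, p_genic: float, tss_frac: float) -> pd.DataFrame:
        rows = []
        for _ in range(n):
            genic = bool(rng.random() < p_genic)
            at_tss = genic and bool(rng.random() < tss_frac)
            s, e = _one_peak(genic, at_tss)
            rows.append((chrom, s, e))
        return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])

    peaks = _peak_set(n_peaks, test_genic_prob, tss_concentration)
    reference = _peak_set(n_reference_peaks, reference_genic_prob, 0.0)
    truth = {
        "seed": seed,
        "enrichment_factor": enrichment_factor,
        "reference_genic_prob": reference_genic_prob,
        "test_genic_prob": test_genic_prob,
        "n_peaks": n_peaks,
    }
    return peaks, reference, models, truth


# ------------------------------------------------------------------- qPCR

def make_ct_fixture(
    seed: int = 0,
    folds: dict[str, float] | None = None,
    target: str = "PRDM2",
    references: tuple[str, ...] = ("PGK", "TBP", "ACTB"),
    calibrator: str = "parental",
    replicates: int = 3,
    noise_sd: float = 0.0,
    target_baseline: float = 26.0,
    reference_baseline: float = 18.0,
) -> tuple[pd.DataFrame, dict]:
    """Ct table generated by inverting the ΔΔCt model.

    Ct = baseline − log2(quantity) + N(0, noise_sd); reference quantities are
    1 everywhere, the target's quantity in each clone is its planted fold
    (1 in the calibrator). Zero noise makes recovery exact.
    """
    if folds is None:
        folds = {"clone1": 1.7, "clone2": 2.5, "clone3": 5.0}
    rng = np.random.default_rng(seed)
    rows = []
    samples = [calibrator] + list(folds)
    for s in samples:
        quantities = {g: 1.0 for g in references}
        quantities[target] = folds.get(s, 1.0)
        for g, q in quantities.items():
            base = target_baseline if g == target else reference_baseline
            for r in range(replicates):
                ct = base - np.log2(q) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                rows.append((s, g, r + 1, ct))
    df = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    truth = {
        "seed": seed,
        "target": target,
        "references": list(references),
        "calibrator": calibrator,
        "planted_folds": dict(folds),
    }
    return df, truth


# ------------------------------------------------------------------- I/O

def _write_gff3(models: pd.DataFrame, path: Path) -> None:
    lines = ["##gff-version 3"]
    for _, r in models.iterrows():
        # 0-based half-open -> 1-based inclusive
        attrs = f"ID={r['Name']}"
        if r["Feature"] == "exon":
            attrs += f";Parent={r['Name'].rsplit('.', 1)[0]}"
        lines.append(
            "\t".join(
                [
                    str(r["Chromosome"]), "repeatlock", str(r["Feature"]),
                    str(int(r["Start"]) + 1), str(int(r["End"])), ".",
                    str(r["Strand"]), ".", attrs,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_bed(peaks: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for _, r in peaks.iterrows():
            fh.write(f"{r['Chromosome']}\t{int(r['Start'])}\t{int(r['End'])}\n")


def write_fixture(kind: str, out_dir: str | Path, seed: int = 0, **params) -> dict:
    """Emit one fixture family to ``out_dir`` and return its truth record.

    ``kind`` is one of transcript/expression/peaks/ct. Files are plain text
    (GenBank+FASTA, TSV, BED+GFF3) plus a JSON truth record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "transcript":
        spec = TranscriptFixtureSpec(seed=seed, **params)
        t, truth = make_repeat_transcript(spec)
        write_transcript(t, out / "transcript.gb")
        write_transcript(t, out / "transcript.fasta")
    elif kind == "expression":
        df, truth = make_expression_fixture(seed=seed, **params)
        df.to_csv(out / "fold_changes.tsv", sep="\t")
    elif kind == "peaks":
        peaks, reference, models, truth = make_peak_fixture(seed=seed, **params)
        _write_bed(peaks, out / "peaks.bed")
        _write_bed(reference, out / "reference_peaks.bed")
        _write_gff3(models, out / "genes.gff3")
    elif kind == "ct":
        df, truth = make_ct_fixture(seed=seed, **params)
        df.to_csv(out / "ct.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    (out / f"{kind}.truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
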