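"""Clone-validation statistics for edited cell lines.

Four independent computations used to validate knock-in clones against their
parental line:

* ΔΔCt relative quantification of RT-qPCR Ct tables against a panel of
  reference genes (PGK/TBP/ACTB style) and a calibrator sample;
* the strict all-clone fold-change intersection (a gene counts as regulated
  only if it passes the threshold, default 1.5-fold, in *every* clone);
* hypergeometric gene-set overlap against GMT collections (MSigDB hallmark
  style) with Benjamini-Hochberg adjustment over an explicit family size;
* ChIP peak-to-feature classification and TSS metaprofiles with a genic
  enrichment factor against a reference peak set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

__all__ = [
    "CtTable",
    "GeneSetOverlapResult",
    "PeakSummary",
    "read_ct_table",
    "relative_quantity",
    "clone_intersection",
    "hypergeometric_overlap",
    "bh_adjust",
    "read_gmt",
    "overlap_table",
    "peak_feature_summary",
    "read_bed_intervals",
    "read_gene_models",
]


# ---------------------------------------------------------------- qPCR ΔΔCt

@dataclass(frozen=True)
class CtTable:
    """Long-format qPCR table: one row per (sample, gene, replicate)."""

    data: pd.DataFrame  # columns: sample, gene, replicate, ct

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"]
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise ValueError("Ct values must be finite and positive")

    def mean_ct(self, sample: str, gene: str) -> float:
        sel = self.data[(self.data["sample"] == sample) & (self.data["gene"] == gene)]
        if sel.empty:
            raise KeyError(f"no Ct rows for sample {sample!r}, gene {gene!r}")
        return float(sel["ct"].mean())

    def ct_range(self, sample: str, gene: str) -> tuple[float, float]:
        sel = self.data[(self.data["sample"] == sample) & (self.data["gene"] == gene)]
        if sel.empty:
            raise KeyError(f"no Ct rows for sample {sample!r}, gene {gene!r}")
        return float(sel["ct"].min()), float(sel["ct"].max())

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))


def read_ct_table(path: str | Path, sep: str = "\t") -> CtTable:
    return CtTable(pd.read_csv(path, sep=sep))


def relative_quantity(
    ct: CtTable,
    target: str,
    references: list[str],
    calibrator: str,
) -> pd.DataFrame:
    """Per-sample relative quantity by the ΔΔCt method.

    ΔCt(sample) = mean Ct(target) − mean over reference genes of their mean
    Cts (equivalently, normalization by the geometric mean of reference
    quantities); RQ = 2^−(ΔCt_sample − ΔCt_calibrator), so the calibrator's
    RQ is 1. Replicate spread of the target Ct propagates to rq_min/rq_max
    bounds (references held at their means); with a single replicate the
    bounds collapse onto the point estimate.
    """
    if not references:
        raise ValueError("at least one reference gene required")
    rows = []
    ref_means = {}
    for s in ct.samples:
        ref_means[s] = float(np.mean([ct.mean_ct(s, g) for g in references]))
    dct_cal = ct.mean_ct(calibrator, target) - ref_means[calibrator]
    for s in ct.samples:
        dct = ct.mean_ct(s, target) - ref_means[s]
        lo_ct, hi_ct = ct.ct_range(s, target)
        rq = 2.0 ** (-(dct - dct_cal))
        rq_max = 2.0 ** (-((lo_ct - ref_means[s]) - dct_cal))
        rq_min = 2.0 ** (-((hi_ct - ref_means[s]) - dct_cal))
        rows.append(
            {"sample": s, "delta_ct": dct, "rq": rq, "rq_min": rq_min, "rq_max": rq_max}
        )
    return pd.DataFrame(rows).set_index("sample")


# ------------------------------------------------- cross-clone intersection

def clone_intersection(
    folds: pd.DataFrame, threshold: float = 1.5
) -> tuple[list[str], list[str]]:
    """Genes concordantly regulated >= ``threshold``-fold in every clone.

    ``folds`` is genes x clones on the linear scale (fold change of each
    clone versus the parental line). A gene is "up" iff its fold is >=
    threshold in all clones, "down" iff <= 1/threshold in all clones
    (inclusive comparisons); everything else is excluded. Lists are sorted
    by gene id.
    """
    if threshold <= 1:
        raise ValueError(f"fold threshold must exceed 1, got {threshold}")
    if folds.shape[1] < 1:
        raise ValueError("at least one clone column required")
    if (folds.to_numpy() <= 0).any():
        raise ValueError("fold changes must be positive")
    up = folds.index[(folds >= threshold).all(axis=1)]
    down = folds.index[(folds <= 1.0 / threshold).all(axis=1)]
    return sorted(up), sorted(down)


# ------------------------------------------------------- gene-set overlap

@dataclass(frozen=True)
class GeneSetOverlapResult:
    """One gene set's overlap record: (K, k, k/K, p[, q])."""

    name: str
    K: int
    k: int
    p: float
    universe: int
    query: int
    q: float | None = None

    @property
    def ratio(self) -> float:
        return self.k / self.K if self.K else 0.0

    @property
    def ratio_display(self) -> float:
        """k/K rounded to 2 decimals, the conventional report format."""
        return round(self.ratio, 2)


def hypergeometric_overlap(
    query: set[str], gene_set: set[str], universe: int, name: str = ""
) -> GeneSetOverlapResult:
    """Upper-tail hypergeometric overlap probability.

    p = P[X >= k] where X counts gene-set members in a size-n draw from a
    universe of N genes containing K set members. k = 0 gives p = 1.
    """
    n, K = len(query), len(gene_set)
    if universe < n or universe < K:
        raise ValueError(
            f"universe {universe} smaller than query {n} or set {K}"
        )
    k = len(query & gene_set)
    p = float(hypergeom.sf(k - 1, universe, K, n))
    return GeneSetOverlapResult(name=name, K=K, k=k, p=p, universe=universe, query=n)


def bh_adjust(p_sorted: list[float], family_size: int) -> list[float]:
    """Benjamini-Hochberg step-up q-values over an explicit family size.

    ``p_sorted`` must be the m' smallest p-values of a family of
    ``family_size`` = m tests, in ascending order (an unsorted list is an
    error, never silently sorted). q_i = min_{i <= j <= m'} (p_j * m / j),
    clipped to 1. Exact whenever the unobserved m − m' p-values are large
    enough that their BH terms never enter a minimum — true by construction
    when the supplied values are the top of a ranked report.
    """
    m_prime = len(p_sorted)
    if family_size < m_prime:
        raise ValueError("family_size smaller than number of p-values supplied")
    if any(p_sorted[i] > p_sorted[i + 1] for i in range(m_prime - 1)):
        raise ValueError("p-values must be supplied in ascending order")
    if any(not 0.0 <= p <= 1.0 for p in p_sorted):
        raise ValueError("p-values must lie in [0, 1]")
    q = [0.0] * m_prime
    running = math.inf
    for i in range(m_prime - 1, -1, -1):
        running = min(running, p_sorted[i] * family_size / (i + 1))
        q[i] = min(running, 1.0)
    return q


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def overlap_table(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: int,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Overlap stats for every set, BH-adjusted across the whole collection.

    ``family_size`` defaults to the number of sets in the collection (e.g. 50
    for the hallmark collection). Rows are sorted by p ascending.
    """
    m = family_size if family_size is not None else len(gene_sets)
    results = [
        hypergeometric_overlap(query, s, universe, name)
        for name, s in gene_sets.items()
    ]
    results.sort(key=lambda r: (r.p, r.name))
    qs = bh_adjust([r.p for r in results], m)
    return pd.DataFrame(
        {
            "gene_set": [r.name for r in results],
            "K": [r.K for r in results],
            "k": [r.k for r in results],
            "k_over_K": [r.ratio_display for r in results],
            "p": [r.p for r in results],
            "q": qs,
        }
    ).set_index("gene_set")


# ---------------------------------------------------- peak/feature summary

@dataclass(frozen=True)
class PeakSummary:
    """Peak classification counts, TSS metaprofile and genic enrichment."""

    counts: dict  # {"exonic": int, "genic": int, "intergenic": int}
    tss_profile: np.ndarray
    tss_bin_edges: np.ndarray
    enrichment_factor: float | None  # None when the reference genic fraction is 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def genic_fraction(self) -> float:
        t = self.total
        return (self.counts["genic"] + self.counts["exonic"]) / t if t else 0.0


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read BED intervals (0-based half-open) into Chromosome/Start/End."""
    import pyranges as pr

    return pr.read_bed(str(path), as_df=True)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene models from GFF3 (1-based inclusive, converted internally).

    Returns a frame with Chromosome/Start/End (0-based half-open), Strand and
    Feature columns; ``gene`` rows define gene bodies and TSSs, ``exon`` rows
    the exonic category.
    """
    import pyranges as pr

    df = pr.read_gff3(str(path), as_df=True)
    return df


def _interval_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("Chromosome", observed=True):
        tree = IntervalTree()
        for s, e in zip(sub["Start"], sub["End"]):
            if e > s:
                tree.addi(int(s), int(e))
        trees[str(chrom)] = tree
    return trees


def _classify(peaks: pd.DataFrame, exon_trees, gene_trees) -> dict:
    counts = {"exonic": 0, "genic": 0, "intergenic": 0}
    for chrom, s, e in zip(peaks["Chromosome"], peaks["Start"], peaks["End"]):
        chrom = str(chrom)
        if exon_trees.get(chrom) and exon_trees[chrom].overlap(int(s), int(e)):
            counts["exonic"] += 1
        elif gene_trees.get(chrom) and gene_trees[chrom].overlap(int(s), int(e)):
            counts["genic"] += 1
        else:
            counts["intergenic"] += 1
    return counts


def peak_feature_summary(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    reference_peaks: pd.DataFrame,
    tss_halfwidth: int = 2000,
    tss_binwidth: int = 200,
) -> PeakSummary:
    """Classify peaks against gene models and summarize TSS concentration.

    Classification is by any-bp overlap with priority exon > gene body >
    intergenic. The TSS metaprofile counts peak midpoints in strand-oriented
    bins of ``tss_binwidth`` bp within ±``tss_halfwidth`` of each TSS. The
    enrichment factor is the genic (gene-body or exon) fraction of ``peaks``
    divided by the genic fraction of ``reference_peaks``; it is None when the
    reference genic fraction is 0 or either set is empty.
    """
    gene_rows = genes[genes["Feature"] == "gene"] if "Feature" in genes else genes
    exon_rows = genes[genes["Feature"] == "exon"] if "Feature" in genes else genes.iloc[0:0]
    known = set(map(str, gene_rows["Chromosome"].unique()))
    for frame in (peaks, reference_peaks):
        unknown = set(map(str, frame["Chromosome"].unique())) - known
        if unknown and known:
            raise ValueError(f"peaks on unknown sequences: {sorted(unknown)}")
    gene_trees = _interval_trees(gene_rows)
    exon_trees = _interval_trees(exon_rows)
    counts = _classify(peaks, exon_trees, gene_trees)
    ref_counts = _classify(reference_peaks, exon_trees, gene_trees)

    nbins = (2 * tss_halfwidth) // tss_binwidth
    profile = np.zeros(nbins, dtype=int)
    edges = np.arange(-tss_halfwidth, tss_halfwidth + 1, tss_binwidth)
    # TSS per gene: Start on +, End on - (half-open: last base is End-1)
    tss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, strand in zip(
        gene_rows["Chromosome"], gene_rows["Start"], gene_rows["End"], gene_rows["Strand"]
    ):
        sign = -1 if str(strand) == "-" else 1
        tss = int(s) if sign == 1 else int(e) - 1
        tss_by_chrom.setdefault(str(chrom), []).append((tss, sign))
    for chrom, s, e in zip(peaks["Chromosome"], peaks["Start"], peaks["End"]):
        mid = (int(s) + int(e)) // 2
        for tss, sign in tss_by_chrom.get(str(chrom), ()):
            rel = (mid - tss) * sign
            if -tss_halfwidth <= rel < tss_halfwidth:
                profile[(rel + tss_halfwidth) // tss_binwidth] += 1

    def _gfrac(c):
        t = sum(c.values())
        return (c["genic"] + c["exonic"]) / t if t else 0.0

    ref_frac = _gfrac(ref_counts)
    test_frac = _gfrac(counts)
    factor = test_frac / ref_frac if ref_frac > 0 and sum(counts.values()) else None
    return PeakSummary(
        counts=counts,
        tss_profile=profile,
        tss_bin_edges=edges,
        enrichment_factor=factor,
    )
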