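# Methods

## Coordinate model and variant grammar

Variants live on the HGVS coding-DNA axis: c.1 is the first base of the start
codon, positions are 1-based inclusive. Internally all arithmetic is 0-based
half-open; conversion happens only at the `seqmodel` boundary. The supported
grammar is deliberately small — `c.<pos>del<bases>`, `c.<pos>ins<bases>` and
the anchor form `c.<pos>_<pos+1>ins<bases>`, at most three bases. The
insertion dialect follows knock-in design reports: `c.NinsB` means the
inserted base occupies position N of the *edited* sequence (so c.4464insG
puts a G at c.4464 of the corrected CDS); the between-bases anchor
`c.(N−1)_N` is carried alongside. Variants inside a homopolymer are
normalized by sliding to the 3′-most position that yields a byte-identical
edited sequence — the standard right-alignment convention — so every one of
the d equivalent deletion placements in a run maps to the same canonical
record. Deletions validate their stated reference bases and fail loudly on
mismatch; this guards against off-by-one coordinate bugs.

Multi-exon transcripts are modeled as a spliced CDS plus one contiguous
genomic context window containing it; full exon maps and lift-over are out
of scope. Translation uses the standard nuclear code only (human genes);
codons containing N translate to X, and N is forbidden inside the
repeat±edit window (it propagates to an AMBIGUOUS_SEQUENCE verdict).

## The stabilizing-edit search

Given a maximal run of one base (found by a linear scan, minimum length 6 by
default — configurable, since clinically observed mutated tracts span
shorter lengths too) and a normalized deletion of d ∈ {1, 2} bases inside
it, the designer enumerates every d-base insertion whose occupied position
lies in the window [run_start − 3, run_end + 3]. The 3-nt margin covers
synonymous edits landing in run-flanking codon positions. Each candidate is
accepted iff

1. the edited CDS re-translates exactly to the wild-type protein
   (full-length string equality, no shortcuts), and
2. the longest residual run of the repeat base, measured over the mutant
   tract plus the inserted segment, is strictly shorter than the wild-type
   run.

Candidates producing byte-identical sequences are deduplicated to their
3′-most representative. Re-inserting the run base itself (which restores the
original unstable run) is enumerated but filtered; a flag re-includes it for
comparison output. Residual runs are reported as a (5′, 3′) pair; note that
when an insertion lands adjacent to rather than inside the tract, lone
copies of the run base in the flanking window can join a fragment, so the
pair can sum to slightly more than the mutant run length — the split
guarantee is always evaluated on the actual post-edit sequence.

**Ranking** is ascending by (longest residual run, |5′ − 3′ fragment
difference|, 5′-most coordinate). The stability objective fixes only the
first key; preferring the balanced split is this package's choice (two
medium runs are jointly more stable than one long and one trivial run under
length-dependent slippage), and the coordinate makes the order total. For
the flagship (A)9/c.4467delA case this yields c.4464insG (5+3) over
c.4461insG (2+6) and c.4467insG (8+0). All candidates are always reported so
an alternative policy can be audited.

An **amenability verdict** combines the enumeration with construct-level
feasibility on the top-ranked edit; failure reasons accumulate as codes
(RUN_BELOW_THRESHOLD, AMBIGUOUS_SEQUENCE, NO_SYNONYMOUS_SPLIT,
ARM_DESIGN_FAIL) so sequence-level and construct-level failures stay
separable.

## Targeting construct and screening panel

The construct follows the promoterless rAAV knock-in layout: HA1 (default
1,000 nt, accepted 800–1,300) ending at the cassette insertion point and
carrying the corrective edit; a selection cassette (splice
acceptor–IRES–Neo–polyA) flanked by 34-nt loxP sites; HA2 starting at the
insertion point. The insertion point defaults to the 3′ end of the edited
exon segment (end of the CDS in the context window) — its true position
relative to intron boundaries is construct-specific and overridable. The
cassette interior is an opaque synthetic placeholder (fixed-seed
non-repetitive sequence, default total cassette 2.4 kb including loxP);
only its length and loxP geometry matter to the design logic. Payload
|HA1| + |cassette| + |HA2| must fit the 4.7-kb rAAV capacity. Arm length,
cassette length and capacity are config keys: the defaults are conventional
values for rAAV targeting, not measured quantities.

Arm amplification primers carry the canonical MultiSite Gateway attB tails
(attB1/attB2 for the P1-P2 donor, attB3/attB4 for P3-P4); cores extend from
the arm termini until they satisfy the Tm window (57–63 °C) and GC bounds
(35–65%), lengths 15–35 nt. Melting temperatures use the unified
nearest-neighbor parameter set of SantaLucia & Hicks (2004) at 50 mM
monovalent salt and 500 nM primer (trace template), via Biopython's NN
machinery; the model and conditions are fixed defaults so reports are
reproducible.

The five screening assays encode junction-PCR logic: each junction assay
pairs one primer outside the homology arm with one inside the cassette, so
products appear only on a correctly targeted allele; the untargeted-allele
assay spans the insertion point and amplifies only when no cassette sits
between its primers (the cassette pushes the product beyond the 2-kb
screening-PCR cutoff); the post-Cre assay flanks the junction inside the
arms, and its product on the excised allele is exactly
(cassette − one loxP) shorter than on the targeted allele; the RT assay
spans the inserted base on the spliced transcript, where the corrected and
mutant products differ by one base and are resolved by sequencing.
Expected amplicons are computed by in-silico PCR (exact primer-core
matching) over three templates: parental (frameshifted allele), targeted
(corrected + cassette), post-Cre (corrected + loxP scar). Screening primers
may slide a few tens of nt from their anchor to meet the Tm/GC window; arm
primers may not (their cores must be exact arm termini).

## Validation statistics

**ΔΔCt.** ΔCt(sample) = mean Ct(target) − arithmetic mean over reference
genes of their mean Cts; RQ = 2^−(ΔCt_sample − ΔCt_calibrator). Averaging
reference Cts arithmetically is equivalent to normalizing by the geometric
mean of reference quantities, the standard multi-reference rule. Replicate
spread of the target Ct propagates to rq_min/rq_max (references held at
their means); a single replicate collapses the bounds. The quantity is
invariant to a global Ct shift of the whole table, but *not* to shifting a
single sample's target alone — the tests assert exactly the former.

**Clone intersection.** A gene counts as concordantly regulated only if its
linear fold change passes the threshold in *every* clone — ≥ t for up,
≤ 1/t for down, inclusive at the boundary, t = 1.5 by default. Display
rounding never feeds decisions.

**Gene-set overlap.** Upper-tail hypergeometric probability via
`scipy.stats.hypergeom.sf`; the universe size N is a required argument with
no default, because overlap p-values are meaningless without an explicit
universe. BH adjustment takes the family size m explicitly: published
reports typically print only the top few of m sets (e.g. 5 of the 50
hallmark sets), and the step-up minimum over a truncated ascending list is
exact whenever every unobserved p-value is large enough that its term
p·m/rank never enters a minimum — true by construction for the top of a
ranked report. Input must already be ascending; the function never sorts
silently. k/K is reported at full precision and displayed at two decimals.

**Peaks.** Intervals are 0-based half-open internally (BED native; GFF3
converted on read). Peaks are classified by any-bp overlap with priority
exon > gene body > intergenic; the TSS metaprofile counts peak midpoints in
strand-oriented bins (default ±2 kb, 200-bp bins); the enrichment factor is
the genic (non-intergenic) fraction of the test peaks over that of a
reference peak set, undefined (None) when the reference fraction is zero.

## Synthetic fixtures

Generators are deterministic: one seeded NumPy generator per fixture,
identical parameters ⇒ byte-identical files, and every fixture ships a JSON
truth record sufficient to score recovery without re-deriving parameters.

* **Transcript**: ATG + non-repetitive filler + TGA, with the run overwriting
  positions so its 3′-most base sits at the requested coordinate (default:
  (A)9 ending at c.4467, CDS 4,503 nt, i.e. codons 1487–1489 = AAA AAA AAA,
  2-kb genomic flanks). The filler never repeats a base twice in a row, so
  the planted run is the only run of length ≥ 2 anywhere — this both makes
  the repeat scan unambiguous and gives every primer-length window a unique
  binding site, which the in-silico PCR layer requires, as would real
  genomic sequence. The stop codon is TGA rather than TAA to keep the
  molecule free of incidental (A)2 runs. For A-runs the base immediately 3′
  of the run is constrained to a pyrimidine; a G there would merge with the
  3′-terminal AAG candidate and shift its canonical label past the annotated
  run end. The filler is random rather than biological, so codon usage and
  GC heterogeneity of real exons are not emulated; tests passing on it show
  coordinate and enumeration correctness, not robustness to genome-scale
  repeat content.
* **Expression**: planted concordant genes draw per-clone folds log-uniformly
  beyond the threshold (default 20 up, 30 down among 1,000 genes, 3 clones,
  folds up to 5×); discordant genes cross the threshold in exactly one
  clone; null genes stay strictly inside (1/t, t). Recovery by the strict
  intersection is therefore exact by construction — the generator plants
  set membership, not read-level noise.
* **Peaks**: 200 non-overlapping 2-kb genes with terminal 300-bp exons on a
  1-Mb chromosome; reference peaks fall in a gene with probability 0.25,
  test peaks with that probability times the planted factor (default 3.0,
  2,000 peaks per set). Recovery of the factor is binomial-limited:
  ±10% ≈ 2.4 standard errors at these sizes.
* **Ct tables**: Ct = baseline − log2(quantity) + noise, references flat at
  quantity 1; zero noise makes ΔΔCt recovery exact (default planted folds
  1.7/2.5/5.0 across three clones).

## Numerical and degenerate-input choices

* Deletions larger than 2 nt are rejected (the correction design space is
  single-run frameshifts); insertions of the run base merging the tract are
  measured as one run, never double-counted.
* Empty candidate lists rank to empty output; an empty peak set yields zero
  counts and an undefined enrichment flag rather than a division error.
* BH q-values are clipped to 1; a family size smaller than the supplied list
  is an error.
* Primer design fails with the violated constraint named; amenability maps
  any construct-level failure to ARM_DESIGN_FAIL while keeping
  sequence-level codes separate.

## Problem sizes and limitations

The test suite and the acceptance script run the designer on the 4.5-kb
fixture transcript, bulk invariants on ~10,000 miniature (10–30 codon)
repeat fixtures, enumeration-oracle equivalence on 1,000 of them, and the
statistics on 1,000-gene expression tables and 2,000-peak sets — sizes at
which every check is exact or binomial-limited as stated above.

Known limitations: no genome-wide primer specificity search (uniqueness is
guaranteed only within the fixture's context), no secondary-structure or
dimer screening, no quantitative slippage-rate model (stability is reported
as run-length reduction only), no ranked-list enrichment with permutation
testing (overlap-style only), and no multi-nucleotide repeat units.
Published cohort-level figures that depend on external data — fractions of
tracts amenable in a mutation catalog, targeting efficiencies, differential
expression counts from sequencing archives — are not recomputable from this
package and are deliberately not asserted anywhere.
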