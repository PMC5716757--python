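# repeatlock

Design toolkit for **repeat-stabilizing knock-in corrections** of frameshift
mutations in coding mononucleotide repeats, plus the statistics used to
validate the resulting edited clones.

## The problem

Mismatch-repair-deficient tumors (microsatellite-instable colorectal, gastric
and endometrial cancers) accumulate single-base deletions in long coding
homopolymer tracts — for example the (A)9 lysine tract in the C-terminal
region of the *PRDM2* tumor suppressor, where c.4467delA truncates the
protein. Correcting such a mutation by simply re-inserting the deleted base
restores the long repeat, which remains a slippage hotspot and can re-mutate.

`repeatlock` implements the alternative: restore the reading frame with a
**synonymous insertion that splits the run**. Because the genetic code is
degenerate (AAA and AAG both encode lysine), a G inserted inside the
truncated (A)8 tract can restore the wild-type protein exactly while dividing
the homopolymer into two shorter, more stable runs:

```
wild type   ... AAA AAA AAA ...   K K K      (A)9  — slippage-prone
mutant      ... AAA AAA AA. ...   frameshift
corrected   ... AAA AAG AAA ...   K K K      (A)5 + (A)3 — stabilized
```

The designer enumerates every candidate insertion in a window around the run,
keeps exactly those whose re-translated CDS equals the wild-type protein and
whose longest residual run is shorter than the original, and ranks them by
(longest residual run, run balance, 5′ position). It then designs the rAAV
Gateway targeting construct around the top pick: homology arms HA1 (carrying
the edit) and HA2, an attB-tailed primer set for BP cloning into pDONR P1-P2
and P3-P4, a loxP-flanked selection cassette, and a five-assay PCR screening
panel (untargeted allele, both junctions, post-Cre scar, RT across the edit)
with expected amplicon sizes per allele state.

The `validate` module covers the downstream clone-validation statistics:

* **ΔΔCt** relative expression against a multi-reference panel
  (RQ = 2^−ΔΔCt with PGK/TBP/ACTB-style reference genes),
* the strict **all-clone fold-change intersection** (≥1.5-fold in every
  clone),
* **hypergeometric gene-set overlap** for GMT collections with
  Benjamini–Hochberg adjustment over an explicit family size
  (p = Σ_{x≥k} C(K,x)·C(N−K,n−x)/C(N,n); q_i = min_{j≥i} p_j·m/j),
* **ChIP peak classification** (exon > gene body > intergenic), TSS
  metaprofiles and a genic enrichment factor against a reference peak set.

`fixtures` generates deterministic synthetic inputs for all of the above —
a PRDM2-like transcript with the (A)9 tract 3′-anchored at c.4467, expression
tables with planted concordant genes, peak/gene-model pairs with a planted
enrichment factor, and Ct tables with known folds — each with a JSON truth
record.

## Worked example

```
$ repeatlock fixtures transcript --seed 3 --out fx
$ repeatlock scan fx/transcript.gb --min-len 8
SYN_PRDM2_LIKE  (A)9    c.4459-c.4467   frame=0
$ repeatlock design fx/transcript.gb --variant c.4467delA
[
  {"run_base": "A", "wild_type_run": 9, "mutant_run": 8,
   "residual_runs": [5, 3], "longest_residual": 5,
   "reduction_of_longest_run": 4, "insertion": "c.4464insG"},
  {"... residual_runs": [2, 6], "insertion": "c.4461insG"},
  {"... residual_runs": [8, 0], "insertion": "c.4467insG"}
]
```

Exactly three single-G insertions restore the wild-type protein; the ranking
selects **c.4464insG**, the balanced (A)5+(A)3 split that reduces the longest
run from 9 to 5. The construct step then prints the attB-tailed arm primers
and the 4,400-nt payload (1,000-nt arms + 2.4-kb cassette):

```
$ repeatlock construct fx/transcript.gb --variant c.4467delA --out construct.gb
HA1_F_attB1  GGGGACAAGTTTGTACAAAAAAGCAGGCTTACGCATGCGAGCGTATG  Tm=57.9  GC=0.56
...
payload  4400 nt  -> construct.gb
```

In the same way, `repeatlock validate overlap` reports (K, k, k/K, p, q) per
gene set; e.g. a 4-gene overlap with a 54-gene set displays k/K = 0.07, and
BH over a 50-set family turns the p-value column of a five-row report into
its q column.

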