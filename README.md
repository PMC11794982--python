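# utarscan

Discovery and spot-level analysis of **unannotated transcriptionally
active regions (uTARs)** — candidate lncRNA loci — in spot-barcoded
spatial transcriptomics data, with a degradation-aware synthetic-data
generator so every stage can be verified against planted ground truth.

Poly(A)-capture spatial protocols read out any polyadenylated
transcript, annotated or not, which makes them a practical instrument
for mapping long non-coding RNA expression onto tissue — including
archival FFPE material whose RNA is fragmented (quality summarised by
DV200, the percentage of fragments longer than 200 bases).  `utarscan`
implements the downstream computational side of that experiment for
people who want a tested, reusable, scriptable version of it:
spatial-omics analysts hunting unannotated transcription, and method
developers who need a controllable simulation to benchmark against.

## The method

1. **Binned coverage.** Reads are assigned by their 5′ end to
   non-overlapping 50-bp genomic bins, one track per (contig, strand).
2. **Segmentation.** A two-state hidden Markov model with Gaussian
   emissions on log(count+1) is fitted by Baum–Welch across all tracks
   of a sample and decoded by Viterbi; state 1 (higher emission mean) is
   "transcriptionally active".  A literal presence rule (a bin is active
   iff any read was detected in it) is available as `mode="presence"`.
3. **Merging.** Active runs no more than 500 bp apart (same contig and
   strand) are merged transitively into transcriptionally active
   regions (TARs).
4. **Classification.** TARs overlapping a reference gene (≥1 base,
   strand-matched by default) are **aTARs**; the rest are **uTARs**.
   uTARs are labelled `novel / db1 / db2 / both` by strand-specific
   overlap against two curated lncRNA sets (e.g. FANTOM and LncExpDB),
   and can be grouped across samples into shared units (connected
   components of the overlap graph).
5. **Quantification + QC.** Genes and uTARs are counted per spot by
   5′-end interval assignment (conservation identity:
   assigned + unassigned + ambiguous + off-tissue = input reads), with
   reads/spot and features/spot QC metrics and median-scaling log1p
   normalisation.
6. **Cell-type analysis.** Spots are scored by the mean normalised
   expression of a marker panel (default: the keratinocyte markers
   KRT5, KRT1, KRT10, DSP, LOR), labelled by a strict upper-quantile
   rule (default Q75), and each uTAR is tested for differential
   expression between labelled and unlabelled spots with a two-sided
   Wilcoxon rank-sum test and Benjamini–Hochberg adjustment (q < 0.05).
   Spatial concordance of a uTAR with the marker signature is measured
   by Spearman rank correlation across spots.

The simulator plants annotated genes and unannotated lncRNA-like loci
on a small multi-contig genome, draws negative-binomial counts (mean
μ = base_mean × fold in the marker-positive domain, size = dispersion,
var = μ + μ²/size), and places reads with either uniform (probe-capture)
or 3′-biased exponential (poly(A)-capture of degraded RNA) geometry.
Everything is seeded and deterministic.

## Worked example

```python
from utarscan import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo_out")
cfg.sim.seed = 1
res = run_pipeline(cfg)
print("reads:", len(res.reads))
print("classification:", res.report)
print("recovery: precision=%.2f recall=%.2f db_agreement=%.2f"
      % (res.recovery.precision, res.recovery.recall,
         res.recovery.db_agreement))
print("de_confusion:", res.recovery.de_confusion)
```

prints

```
reads: 40123
classification: {'n_total': 60, 'n_atar': 40, 'n_utar': 20,
 'db_counts': {'novel': 4, 'db1': 6, 'db2': 4, 'both': 6},
 'frac_utar_in_db': 0.8}
recovery: precision=1.00 recall=1.00 db_agreement=1.00
de_confusion: {'tp': 20, 'fn': 0, 'fp': 0, 'tn': 0}
```

Reading: the default simulation plants 40 genes and 20 unannotated
loci; all 60 are recovered as TARs, the 20 unannotated ones are
classified as uTARs, and their database labels all match the planted
membership flags (16/20 in at least one database here).  Every planted
cell-type-specific uTAR reaches q < 0.05 in the Wilcoxon test against
the marker-labelled spots with no false positives.  The head of the DE
table for this run:

```
feature  n1  n2      U            p            q   log2fc
 sim1:0  50 150 5338.0 7.347209e-06 1.103450e-05 0.282607
 sim1:2  50 150 5608.5 1.478787e-07 3.286194e-07 0.327774
 sim1:6  50 150 5334.0 7.724153e-06 1.103450e-05 0.273801
```

(`U` is the rank-sum statistic for the 50 labelled spots; `log2fc` is
the log2 ratio of group means of normalised values with pseudocount 1.)
`demo_out/` additionally holds the SAM reads, GTF annotation, BED
databases, the MTX count-matrix triplet, QC and concordance tables, the
JSON-lines run log, and spatial maps of the marker signature and the
top uTAR.  The DV200 of the simulated fragments is printed by
`utarscan simulate` (83.6 % at the default mean fragment length of
1,000 bases).

The same workflow is available from the shell:

```bash
utarscan run --seed 1 --outdir demo_out
utarscan simulate --outdir sim && utarscan call-tars \
    --sam sim/reads.sam --chrom-sizes sim/genome.chrom.sizes --out tars.bed
```

## Documentation

`docs/methods.md` describes the model, its assumptions, all tunable
parameters with defaults and rationale, what the simulator does and
does not emulate, and known limitations.
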