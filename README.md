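# loopshift

Differential chromatin-loop and compartment analysis for two-condition Hi-C
experiments, with the surrounding fragment-coverage statistics
(CUT&RUN/ATAC-style) needed to interpret the changes — built as a reusable
library plus a sequence of analysis drivers, and exercised end-to-end on
synthetic data with planted ground truth.

## Who this is for

Acute perturbations of architectural proteins (e.g. targeted degradation via
a dTAG degron) rewire focal chromatin loops within hours while leaving A/B
compartments largely intact. Detecting that rewiring requires statistics that
work at the level of *replicated* contact maps: a loop present in three
control replicates and absent in three treatment replicates is a finding; a
bright pixel in one map is not. This package implements that replicate-aware
analysis chain for anyone who wants to quantify loop gains/losses,
compartment stability, and their relationship to differential protein
occupancy — without depending on a particular aligner or peak-caller stack.

## The statistics at the core

**Loop scoring.** On each smoothed O/E (observed-over-expected) contact map,
a candidate pixel (i, j) is scored against its local background in the
donut-filter tradition:

    score(i, j) = P / max(D, H, V, BL)

where P is the mean O/E in the (2p+1)² peak window and D, H, V, BL are the
donut ring, horizontal stripe, vertical stripe and lower-left quadrant
neighborhoods within the (2w+1)² outer window. Calling additionally requires
the observed peak count to beat a Poisson background at FDR 0.1, so
low-count far-diagonal noise is not called.

**Differential loops.** Per-sample scores over the union of loop calls are
z-normalized within each sample across all candidates; replicate differences

    DS = { z_ctrl,x(i,j) − z_treat,y(i,j) }   (all replicate combinations)

are combined with Stouffer's method, Z(i,j) = ΣDS / √k with k = |DS|, and
two-sided normal P < 0.05 defines significant rearrangements (Z > 0 = lost
in treatment, Z < 0 = gained).

**Compartments.** PC1 of the Pearson correlation matrix of the O/E map,
sign-oriented by TSS density ('+' = gene-dense A compartment); saddle plots
drop the 1% lowest-coverage bins per chromosome, rank bins by PC1, and
coarse-grain the O/E map into a 100×100 percentile matrix whose 25×25 corner
blocks give AA, BB and AB interaction strengths.

**Coverage normalization and differential binding.** Fragment samples are
depth-equalized on background: peaks are called on the pooled samples
(Poisson tail + BH), peak-flanking regions provide counts for
median-of-ratios size factors, and each sample is binomially thinned by
r_j = min(sf)/sf_j. Differential occupancy on the common region catalog uses
a negative-binomial Wald test with trend-shrunken moment dispersions and BH
correction. Integration statistics: (1/n)·(−10·log₁₀P) peak-to-gene scores
in a 25 kb TSS window, one-sided hypergeometric overlap tests,
enhancer/promoter anchor annotation with gain/loss bias ratios and one-sided
rank-sum comparisons, and Welch's t for locus-class rearrangement enrichment.

## Worked example

The bundled demo simulates the standard synthetic experiment — one 2 Mb
chromosome at 5 kb bins, 3 replicates per condition, compartment
checkerboard at strength 0.3, and 30 planted loops at 5-fold enrichment (10
shared, 10 control-specific, 10 treatment-specific) — and runs every stage:

```bash
python analysis/01_simulate.py --seed 0
python analysis/05_differential_loops.py --seed 0
python analysis/06_compartments.py --seed 0
```

prints (numbers from this exact invocation):

```
planted cond1_only loops: sensitivity 1.00 (direction 'lost')
planted cond2_only loops: sensitivity 0.90 (direction 'gained')
shared loops falsely called significant: 0/10
significant differential interactions per chromosome: {'chrS': 32}
top rearrangement hotspot: chrS:1125000-1375000 (18 anchors)
PC1 sign agreement with planted compartments: 99.5%
cond1: AA=1.371 BB=1.354 AB=0.742
compartment switching fraction between conditions: 0.5%
```

Reading this: 19 of the 20 planted condition-specific loops are recovered
with the correct direction at P < 0.05 while none of the 10 shared loops is
falsely called; the compartment eigenvector matches the planted checkerboard
on 99.5% of bins, same-compartment contacts are ~1.8× enriched over
cross-compartment contacts (AA/AB), and <1% of bins switch compartment
between conditions — loops rewire, compartments hold.

The same chain is available as a single orchestrated run with a manifest:

```bash
loopshift run analysis/demo_config.yaml        # or: loopshift run --demo
```

Numbered drivers `analysis/01_simulate.py` … `07_integration.py` cover
simulation, normalization, differential binding, loop calling, differential
loops, compartments, and the integration statistics; each writes its tables
under `results/`.

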